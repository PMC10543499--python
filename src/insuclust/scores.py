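"""Partitioned polygenic scores from genotype dosages and cluster weights.

A cluster's partitioned polygenic score (pPS) for an individual is the sum of
the cluster's variant weights multiplied by the dosage of each variant's
FI-increasing allele.  Scoring a real panel requires resolving each cluster
variant against the panel: direct use when present and allele-reconcilable,
proxy substitution by maximal LD (r^2 >= 0.8) when not, and a frequency guard
for strand-ambiguous (A/T, C/G) variants whose orientation cannot be read off
the allele labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bnmf import ClusterDefinitions

__all__ = [
    "GenotypePanel",
    "LDReference",
    "ResolvedWeights",
    "PPSTable",
    "resolve_variants",
    "compute_pps",
    "reference_cutoffs",
    "decile_flag",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T or C/G pairs: strand cannot be resolved from allele labels."""
    return complement(a1) == a2


def orient_pair(effect: str, other: str, ref_effect: str, ref_other: str) -> int | None:
    """Sign relating an allele pair to a reference pair of the same variant.

    +1 when ``effect`` corresponds to ``ref_effect``, -1 when the pair is
    swapped, ``None`` when the pairs are irreconcilable.  Strand complements
    are accepted only when neither pair is palindromic.
    """
    if (effect, other) == (ref_effect, ref_other):
        return 1
    if (effect, other) == (ref_other, ref_effect):
        return -1
    if is_palindromic(effect, other) or is_palindromic(ref_effect, ref_other):
        return None
    if (complement(effect), complement(other)) == (ref_effect, ref_other):
        return 1
    if (complement(effect), complement(other)) == (ref_other, ref_effect):
        return -1
    return None


def orient_allele(target: str, effect: str, other: str) -> int | None:
    """Sign with which ``effect`` counts toward ``target``.

    +1 when the effect allele is the target allele, -1 when the other allele
    is, ``None`` when the pair is irreconcilable.  Strand complements are
    accepted only for non-palindromic pairs (complement matching is
    undecidable for palindromes).
    """
    if target == effect:
        return 1
    if target == other:
        return -1
    if is_palindromic(effect, other):
        return None
    if target == complement(effect):
        return 1
    if target == complement(other):
        return -1
    return None


@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix with per-variant allele metadata.

    ``variants`` is indexed by variant_id with columns chromosome, position,
    effect_allele, other_allele, frequency (observed effect-allele frequency).
    Dosages count the effect allele, lie in [0, 2], and may be NaN (missing).
    """

    individuals: list
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError("dosage matrix shape does not match individuals x variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2] or be missing")

    @classmethod
    def from_dosages(cls, individuals, variants: pd.DataFrame, dosages) -> "GenotypePanel":
        """Build a panel, computing observed frequencies from the dosages."""
        dosages = np.asarray(dosages, dtype=float)
        variants = variants.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            variants["frequency"] = np.nanmean(dosages, axis=0) / 2.0
        return cls(list(individuals), variants, dosages)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id) -> np.ndarray:
        return self.dosages[:, self.variants.index.get_loc(variant_id)]


class LDReference:
    """Symmetric r^2 lookup plus reference allele frequencies.

    ``frequencies`` map each variant to the reference-population frequency of
    its FI-increasing allele (the allele the cluster weights count).
    """

    def __init__(
        self,
        frequencies: Mapping[str, float],
        pairs: Iterable[tuple] = (),
    ):
        self._freq = dict(frequencies)
        self._r2: dict = {}
        self._linked: dict = {}
        for a, b, r2 in pairs:
            r2 = float(r2)
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"r2 for pair ({a}, {b}) outside [0, 1]: {r2}")
            self._r2[(a, b)] = r2
            self._r2[(b, a)] = r2
            self._linked.setdefault(a, []).append((b, r2))
            self._linked.setdefault(b, []).append((a, r2))

    @property
    def variants(self) -> list:
        return list(self._freq)

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b), 0.0)

    def frequency(self, variant) -> float | None:
        return self._freq.get(variant)

    def linked(self, variant) -> list:
        """Variants in LD with ``variant`` as (other, r2), excluding itself."""
        return list(self._linked.get(variant, []))


@dataclass
class ResolvedWeights:
    """Outcome of mapping cluster variants onto a panel.

    One row per original cluster variant with columns cluster, variant_id,
    used_variant, sign, weight, provenance, detail.  provenance is one of
    direct / proxy / dropped; dropped rows carry the reason in ``detail``.
    """

    table: pd.DataFrame

    def used(self) -> pd.DataFrame:
        return self.table[self.table["provenance"] != "dropped"]

    def dropped(self) -> pd.DataFrame:
        return self.table[self.table["provenance"] == "dropped"]

    def for_cluster(self, cluster) -> pd.DataFrame:
        return self.used()[self.used()["cluster"] == cluster]

    @property
    def clusters(self) -> list:
        return list(dict.fromkeys(self.table["cluster"]))


def _palindrome_guard(panel_fi_freq: float, ref_freq: float | None, freq_tol: float) -> str | None:
    """Reason the palindromic variant is unusable, or None when it passes."""
    if ref_freq is None:
        return "no_reference_frequency"
    if 0.5 - freq_tol < panel_fi_freq < 0.5 + freq_tol:
        return "ambiguous_frequency"
    if abs(panel_fi_freq - ref_freq) > freq_tol:
        return "frequency_mismatch"
    return None


def _resolve_direct(vid, fi_allele, panel, ld, freq_tol):
    """(sign, reason): sign of the panel effect allele toward the FI allele."""
    row = panel.variants.loc[vid]
    ea, oa = row["effect_allele"], row["other_allele"]
    if is_palindromic(ea, oa):
        if fi_allele == ea:
            panel_fi_freq = float(row["frequency"])
            sign = 1
        elif fi_allele == oa:
            panel_fi_freq = 1.0 - float(row["frequency"])
            sign = -1
        else:
            return None, "irreconcilable_alleles"
        reason = _palindrome_guard(panel_fi_freq, ld.frequency(vid), freq_tol)
        if reason is not None:
            return None, reason
        return sign, None
    sign = orient_allele(fi_allele, ea, oa)
    if sign is None:
        return None, "irreconcilable_alleles"
    return sign, None


def _best_proxy(vid, panel, ld, r2_min, original_position=None):
    """Panel variant with maximal r2 >= r2_min; ties by position then ID."""
    candidates = [
        (proxy, r2)
        for proxy, r2 in ld.linked(vid)
        if r2 >= r2_min and proxy in panel.variants.index
    ]
    if not candidates:
        return None, None

    def key(item):
        proxy, r2 = item
        if original_position is not None:
            dist = abs(int(panel.variants.loc[proxy, "position"]) - int(original_position))
        else:
            dist = 0
        return (-r2, dist, str(proxy))

    proxy, r2 = min(candidates, key=key)
    return proxy, r2


def resolve_variants(
    defs: ClusterDefinitions,
    panel: GenotypePanel,
    ld: LDReference,
    r2_min: float = 0.8,
    freq_tol: float = 0.05,
) -> ResolvedWeights:
    """Map every cluster variant to a usable panel variant or drop it with a reason.

    Direct use when the variant is in the panel and its alleles reconcile with
    the FI-increasing allele; palindromic variants additionally require the
    panel FI-allele frequency to match the reference within ``freq_tol`` and
    to stay away from 0.5.  Unavailable variants fall back to the panel proxy
    with maximal r^2 >= ``r2_min`` (ties broken by distance, then ID); proxy
    orientation counts the proxy allele whose frequency matches the reference
    frequency of the original FI-increasing allele (r^2 carries no phase).
    """
    rows = []
    has_pos = "position" in defs.variant_weights.columns
    for rec in defs.variant_weights.itertuples(index=False):
        vid, fi_allele, weight = rec.variant_id, rec.fi_increasing_allele, rec.weight
        position = getattr(rec, "position", None) if has_pos else None
        sign = reason = None
        if vid in panel.variants.index:
            sign, reason = _resolve_direct(vid, fi_allele, panel, ld, freq_tol)
        else:
            reason = "not_in_panel"
        if sign is not None:
            rows.append(
                dict(cluster=rec.cluster, variant_id=vid, used_variant=vid, sign=sign,
                     weight=weight, provenance="direct", detail="")
            )
            continue
        proxy, r2 = _best_proxy(vid, panel, ld, r2_min, position)
        if proxy is not None:
            prow = panel.variants.loc[proxy]
            ref_freq = ld.frequency(vid)
            # frequency-matched pairing: count the proxy allele whose frequency
            # tracks the original FI-increasing allele in the reference
            if ref_freq is None or abs(prow["frequency"] - ref_freq) <= abs(
                (1.0 - prow["frequency"]) - ref_freq
            ):
                psign = 1
            else:
                psign = -1
            rows.append(
                dict(cluster=rec.cluster, variant_id=vid, used_variant=proxy, sign=psign,
                     weight=weight, provenance="proxy", detail=f"{vid}->{proxy}, r2={r2:g}")
            )
        else:
            drop_reason = reason if reason not in (None, "not_in_panel") else "no_proxy"
            rows.append(
                dict(cluster=rec.cluster, variant_id=vid, used_variant=None, sign=0,
                     weight=weight, provenance="dropped", detail=drop_reason)
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "variant_id", "used_variant", "sign", "weight", "provenance", "detail"],
    )
    for cluster in defs.clusters:
        sub = table[table["cluster"] == cluster]
        if len(sub) and (sub["provenance"] == "dropped").all():
            warnings.warn(f"cluster {cluster!r} fully unresolvable in this panel", stacklevel=2)
    return ResolvedWeights(table)


@dataclass
class PPSTable:
    """Per-individual, per-cluster partitioned polygenic scores."""

    scores: pd.DataFrame  # individuals x clusters
    n_variants: dict = field(default_factory=dict)  # contributing variants per cluster
    missing_fraction: pd.Series | None = None  # per-individual imputed fraction

    @property
    def clusters(self) -> list:
        return list(self.scores.columns)

    def __getitem__(self, cluster) -> pd.Series:
        return self.scores[cluster]


def compute_pps(panel: GenotypePanel, resolved: ResolvedWeights) -> PPSTable:
    """score(i, c) = sum_v weight_v * oriented dosage(i, v).

    Oriented dosage is the dosage itself when the panel effect allele is the
    counted allele (sign +1) and ``2 - dosage`` otherwise; missing dosages are
    imputed as twice the oriented effect-allele frequency.
    """
    used = resolved.used()
    n = panel.n_individuals
    clusters = resolved.clusters
    scores = np.zeros((n, len(clusters)))
    n_contrib = {}
    imputed = np.zeros(n)
    total_entries = 0
    for j, cluster in enumerate(clusters):
        sub = used[used["cluster"] == cluster]
        n_contrib[cluster] = len(sub)
        for rec in sub.itertuples(index=False):
            d = panel.column(rec.used_variant)
            freq = float(panel.variants.loc[rec.used_variant, "frequency"])
            if rec.sign == 1:
                oriented, ofreq = d, freq
            else:
                oriented, ofreq = 2.0 - d, 1.0 - freq
            miss = np.isnan(oriented)
            oriented = np.where(miss, 2.0 * ofreq, oriented)
            imputed += miss
            total_entries += 1
            scores[:, j] += rec.weight * oriented
    frame = pd.DataFrame(scores, index=panel.individuals, columns=clusters)
    miss_frac = pd.Series(
        imputed / max(total_entries, 1), index=panel.individuals, name="missing_fraction"
    )
    return PPSTable(scores=frame, n_variants=n_contrib, missing_fraction=miss_frac)


def reference_cutoffs(scores: PPSTable, quantile: float = 0.9) -> dict:
    """Per-cluster nearest-rank quantile of a reference cohort's scores."""
    cutoffs = {}
    for cluster in scores.clusters:
        vals = np.sort(scores.scores[cluster].to_numpy())
        rank = int(np.ceil(quantile * len(vals)))  # nearest-rank method
        cutoffs[cluster] = float(vals[max(rank - 1, 0)])
    return cutoffs


def decile_flag(scores: PPSTable, cutoffs: Mapping) -> pd.DataFrame:
    """flag(i, c) = 1 iff score(i, c) > cutoff_c (ties fall below)."""
    flags = {}
    for cluster in scores.clusters:
        if cluster not in cutoffs:
            raise ValueError(f"no cutoff supplied for cluster {cluster!r}")
        flags[cluster] = (scores.scores[cluster] > cutoffs[cluster]).astype(int)
    return pd.DataFrame(flags, index=scores.scores.index)
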