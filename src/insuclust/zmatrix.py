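"""From multi-trait summary statistics to the non-negative clustering input.

Pipeline: select variants by their fasting-insulin p-value, align every
trait's Z-score to the FI-increasing allele, greedily prune traits whose
Z-score columns are nearly collinear (|r| >= 0.85 with a retained trait), and
double each signed trait column into a non-negative positive/negative pair so
the matrix can enter NMF while preserving effect direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import orient_pair

__all__ = [
    "AlignedZMatrix",
    "NonNegMatrix",
    "select_variants",
    "align_to_risk_allele",
    "prune_traits",
    "build_nonnegative_matrix",
]

REQUIRED_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "standard_error",
    "p_value",
    "trait",
]


def _check_stats(stats: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics lack required columns: {missing}")
    if stats.duplicated(["variant_id", "trait"]).any():
        dup = stats[stats.duplicated(["variant_id", "trait"])]["variant_id"].unique()[:5]
        raise ValueError(f"duplicate (variant_id, trait) records, e.g. {list(dup)}")
    if (stats["standard_error"] <= 0).any():
        raise ValueError("standard_error must be > 0 for every record")


@dataclass
class AlignedZMatrix:
    """Signed variant x trait Z-scores, rows oriented to the FI-increasing allele.

    ``Z`` holds NaN where a (variant, trait) association is missing;
    ``variants`` is indexed by variant_id with chromosome, position and
    fi_increasing_allele columns.
    """

    variants: pd.DataFrame
    Z: pd.DataFrame
    fi_trait: str

    @property
    def traits(self) -> list:
        return list(self.Z.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.Z.isna()

    @property
    def fi_increasing_allele(self) -> pd.Series:
        return self.variants["fi_increasing_allele"]


@dataclass
class NonNegMatrix:
    """Positive/negative column-doubled matrix, ``X >= 0`` everywhere.

    ``X[v, t_pos] = max(Z, 0)``, ``X[v, t_neg] = max(-Z, 0)``; missing Z
    entries contribute zero to both halves.
    """

    X: pd.DataFrame
    traits: list
    variants: pd.DataFrame
    fi_trait: str


def select_variants(
    stats: pd.DataFrame,
    fi_trait: str,
    p_threshold: float = 5e-5,
    union_traits: list | None = None,
) -> list:
    """Variants whose FI association has p strictly below ``p_threshold``.

    De-duplicated by variant_id and ordered by (chromosome, position).
    ``union_traits`` optionally names additional discovery traits (e.g. a
    BMI-adjusted FI GWAS) whose sub-threshold hits are unioned in.
    """
    _check_stats(stats)
    if stats.empty:
        return []
    available = stats["trait"].unique()
    if fi_trait not in available:
        raise ValueError(
            f"trait {fi_trait!r} absent from summary statistics; available: {sorted(available)}"
        )
    discovery = [fi_trait] + [t for t in (union_traits or []) if t != fi_trait]
    fi = stats[stats["trait"].isin(discovery)]
    hits = fi[fi["p_value"] < p_threshold].drop_duplicates("variant_id")
    if "chromosome" in hits.columns and "position" in hits.columns:
        key = hits[["chromosome", "position"]].copy()
        key["chromosome"] = pd.to_numeric(key["chromosome"], errors="coerce").fillna(99)
        hits = hits.loc[key.sort_values(["chromosome", "position"], kind="stable").index]
    return list(hits["variant_id"])


def align_to_risk_allele(
    stats: pd.DataFrame, variants: list, fi_trait: str
) -> AlignedZMatrix:
    """Orient every trait Z-score to the FI risk-increasing allele.

    The FI-increasing allele is the FI record's effect allele when its beta is
    >= 0 and the other allele otherwise.  A trait record's Z is flipped when
    its effect allele resolves (by label, or strand complement for
    unambiguous pairs) to the non-FI-increasing allele; irreconcilable allele
    pairs raise an error listing the offending variants.
    """
    _check_stats(stats)
    sub = stats[stats["variant_id"].isin(set(variants))]
    fi = sub[sub["trait"] == fi_trait].set_index("variant_id")
    missing_fi = [v for v in variants if v not in fi.index]
    if missing_fi:
        raise ValueError(f"variants without an FI record: {missing_fi[:10]}")

    traits = list(dict.fromkeys(sub["trait"]))
    if fi_trait in traits:
        traits.remove(fi_trait)
    traits = [fi_trait] + traits

    fi_sign = {}
    rows = []
    for v in variants:
        rec = fi.loc[v]
        # FI-increasing allele: the FI record's effect allele when beta >= 0
        fi_sign[v] = 1.0 if rec["beta"] >= 0 else -1.0
        allele = rec["effect_allele"] if rec["beta"] >= 0 else rec["other_allele"]
        rows.append(
            dict(
                variant_id=v,
                chromosome=rec.get("chromosome", 0),
                position=rec.get("position", 0),
                fi_increasing_allele=allele,
            )
        )
    vinfo = pd.DataFrame(rows).set_index("variant_id")

    Z = pd.DataFrame(np.nan, index=list(variants), columns=traits)
    bad = []
    for rec in sub.itertuples(index=False):
        v = rec.variant_id
        fi_rec = fi.loc[v]
        pair_sign = orient_pair(
            rec.effect_allele, rec.other_allele,
            fi_rec["effect_allele"], fi_rec["other_allele"],
        )
        if pair_sign is None:
            bad.append(v)
            continue
        Z.loc[v, rec.trait] = pair_sign * fi_sign[v] * rec.beta / rec.standard_error
    if bad:
        raise ValueError(
            "allele pairs irreconcilable with the FI record for variants: "
            f"{sorted(set(bad))[:10]}"
        )
    return AlignedZMatrix(variants=vinfo, Z=Z, fi_trait=fi_trait)


def prune_traits(zmat: AlignedZMatrix, r_threshold: float = 0.85) -> AlignedZMatrix:
    """Greedy correlation pruning of trait columns, FI anchored first.

    Traits are visited in input order (FI first); a trait is dropped when the
    absolute Pearson correlation of its Z column with any already-retained
    column (over pairwise-complete rows) reaches ``r_threshold``.
    Zero-variance columns are retained with a warning and excluded from the
    correlation comparisons.
    """
    if len(zmat.traits) < 2:
        raise ValueError("trait pruning needs at least 2 traits")
    order = [zmat.fi_trait] + [t for t in zmat.traits if t != zmat.fi_trait]
    retained: list = []
    comparators: list = []
    for t in order:
        col = zmat.Z[t]
        if col.dropna().nunique() <= 1:
            warnings.warn(f"trait {t!r} has zero variance; retained, not compared", stacklevel=2)
            retained.append(t)
            continue
        keep = True
        for other in comparators:
            pair = zmat.Z[[t, other]].dropna()
            if len(pair) < 2:
                continue
            r = pair[t].corr(pair[other])
            if np.isfinite(r) and abs(r) >= r_threshold:
                keep = False
                break
        if keep:
            retained.append(t)
            comparators.append(t)
    return AlignedZMatrix(
        variants=zmat.variants.copy(), Z=zmat.Z[retained].copy(), fi_trait=zmat.fi_trait
    )


def build_nonnegative_matrix(zmat: AlignedZMatrix, scale_columns: bool = False) -> NonNegMatrix:
    """Double each signed trait column into non-negative pos/neg halves.

    ``scale_columns`` divides each trait's Z column by its standard deviation
    first (off by default: Z-scores enter the factorization unscaled).
    """
    Z = zmat.Z
    if scale_columns:
        sd = Z.std(ddof=0).replace(0.0, 1.0)
        Z = Z / sd
    pos = Z.clip(lower=0).fillna(0.0)
    neg = (-Z).clip(lower=0).fillna(0.0)
    pos.columns = [f"{t}_pos" for t in Z.columns]
    neg.columns = [f"{t}_neg" for t in Z.columns]
    X = pd.concat([pos, neg], axis=1)
    return NonNegMatrix(X=X, traits=list(Z.columns), variants=zmat.variants.copy(), fi_trait=zmat.fi_trait)
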