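"""Synthetic GWAS summary statistics, LD references, and cohorts.

The generator plants a known low-rank structure: a non-negative variant x
factor loading matrix and a signed factor x trait matrix whose product, plus
Gaussian noise, is the variant x trait Z-score matrix.  Emitted per-trait
summary statistics randomize the effect-allele orientation so downstream
allele alignment is exercised.  Individual-level cohorts draw Hardy-Weinberg
dosages and binary outcomes from a logistic model whose linear predictor
carries configured per-10-unit odds ratios for each cluster score, so the
association stage has known ground truth to recover.

Two shipped fixture configurations mirror the study conditions: SUMSTATS-A
(230 variants x 43 traits, 7 planted factors) for clustering, and COHORT-A
(50,000 individuals, one binary T2D outcome with per-cluster odds ratios)
for association recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit

from .bnmf import ClusterDefinitions
from .scores import GenotypePanel, LDReference, compute_pps, resolve_variants

__all__ = [
    "OutcomeSpec",
    "SimConfig",
    "TrueStructure",
    "generate_summary_stats",
    "generate_ld_reference",
    "generate_cohort",
    "planted_cluster_definitions",
    "load_sim_config",
    "SUMSTATS_A",
    "COHORT_A",
]

_NONPALINDROMIC_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_P_MIN = 1e-300
# two-sided |Z| for the p < 5e-5 inclusion threshold used at variant selection
_Z_SELECT = float(sps.norm.isf(5e-5 / 2.0))


@dataclass
class OutcomeSpec:
    """One simulated outcome and its per-cluster generative effects.

    ``effects`` maps cluster name to the per-10-unit odds ratio (binary
    outcomes) or the per-10-unit slope on the outcome's native scale
    (quantitative outcomes).  ``baseline`` is the prevalence for binary
    outcomes and the intercept for quantitative ones.
    """

    name: str
    kind: str = "binary"  # binary | quantitative
    baseline: float = 0.15
    effects: dict = field(default_factory=dict)
    noise_sd: float = 15.0  # residual SD, quantitative outcomes only

    def validate(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ValueError(f"outcome_specs[{self.name}].kind must be binary|quantitative")
        if self.kind == "binary" and not 0.0 < self.baseline < 1.0:
            raise ValueError(
                f"outcome_specs[{self.name}].baseline prevalence must lie strictly in (0, 1)"
            )
        if self.kind == "binary" and any(v <= 0 for v in self.effects.values()):
            raise ValueError(f"outcome_specs[{self.name}].effects odds ratios must be > 0")


@dataclass
class SimConfig:
    """Generator settings; defaults are the SUMSTATS-A / COHORT-A study conditions."""

    n_variants: int = 230
    n_traits: int = 43
    k_true: int = 7
    weight_scale: float = 8.0
    noise_sd: float = 1.0
    sparsity: float = 0.8
    seed: int = 20230919
    maf_range: tuple = (0.05, 0.5)
    n_individuals: int = 50_000
    outcome_specs: list = field(default_factory=list)
    fi_trait: str = "FI"
    se: float = 0.01  # fixed SE converting Z to beta; only Z = beta/SE matters
    palindrome_fraction: float = 0.1
    flip_fraction: float = 0.5
    fi_ascertainment: bool = False  # condition FI Z on passing the 5e-5 screen
    cluster_names: list | None = None
    confounded: bool = False  # couple age to the total score for robustness tests
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.10, "pc": 0.02}
    )

    def validate(self) -> None:
        if self.k_true < 1 or self.k_true > min(self.n_variants, self.n_traits):
            raise ValueError("k_true must satisfy 1 <= k_true <= min(n_variants, n_traits)")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")
        if self.weight_scale < 0:
            raise ValueError("weight_scale must be >= 0 (0 plants a pure-noise matrix)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for spec in self.outcome_specs:
            spec.validate()


@dataclass
class TrueStructure:
    """Planted ground truth behind a simulated summary-statistics set."""

    planted_variant_weights: pd.DataFrame  # n_variants x k_true, >= 0
    planted_trait_weights: pd.DataFrame  # k_true x n_traits, signed
    fi_increasing_allele: pd.Series  # variant_id -> allele
    alleles: pd.DataFrame  # variant_id -> a1 (FI-increasing), a2
    primary_factor: pd.Series  # variant_id -> factor with the largest loading
    variant_info: pd.DataFrame  # variant_id -> chromosome, position

    @property
    def variant_ids(self) -> list:
        return list(self.planted_variant_weights.index)

    @property
    def traits(self) -> list:
        return list(self.planted_trait_weights.columns)

    @property
    def factors(self) -> list:
        return list(self.planted_variant_weights.columns)


def _factor_names(config: SimConfig) -> list:
    if config.cluster_names:
        if len(config.cluster_names) != config.k_true:
            raise ValueError("cluster_names length must equal k_true")
        return list(config.cluster_names)
    return [f"factor_{i + 1}" for i in range(config.k_true)]


def _variant_frequencies(config: SimConfig, variant_ids: Sequence[str]) -> pd.Series:
    """Reference frequency of each variant's FI-increasing allele.

    Drawn from a dedicated stream keyed on the config seed so the LD
    reference and cohort panels agree on the same frequencies.
    """
    rng = np.random.default_rng([config.seed, 7])
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=len(variant_ids))
    return pd.Series(freqs, index=list(variant_ids), name="frequency")


def _plant_structure(config: SimConfig, rng: np.random.Generator) -> TrueStructure:
    n, m, k = config.n_variants, config.n_traits, config.k_true
    names = _factor_names(config)
    traits = [config.fi_trait] + [f"trait_{i + 1}" for i in range(m - 1)]

    # variant loadings: one guaranteed primary membership per variant; extra
    # memberships with probability chosen so the overall zero fraction of the
    # planted factors equals `sparsity`
    primary = rng.integers(0, k, size=n) if k > 1 else np.zeros(n, dtype=int)
    if k > 1:
        q = max(0.0, (k * (1.0 - config.sparsity) - 1.0) / (k - 1.0))
        member = rng.random((n, k)) < q
    else:
        member = np.zeros((n, k), dtype=bool)
    member[np.arange(n), primary] = True
    V = np.where(member, rng.uniform(0.7, 1.0, size=(n, k)) * config.weight_scale, 0.0)
    # every factor needs at least one member variant
    for j in range(k):
        if not member[:, j].any():
            i = int(rng.integers(0, n))
            V[i, j] = rng.uniform(0.7, 1.0) * config.weight_scale
            primary[i] = j

    # trait loadings: the FI anchor loads positively (weight 1) on every
    # factor -- all clusters raise fasting insulin by construction.  The
    # remaining traits draw their signed supports from a diversified catalog
    # of one- and two-factor combinations (no two traits share the same
    # signed support), keeping the planted trait columns mutually below the
    # |r| = 0.85 pruning threshold, as the study's trait set already is.
    T = np.zeros((k, m))
    T[:, 0] = 1.0
    if m > 1:
        catalog = [((j,), (1.0,)) for j in range(k)]
        for sa, sb in ((1.0, 1.0), (1.0, -1.0)):
            for a in range(k):
                for b in range(a + 1, k):
                    catalog.append(((a, b), (sa, sb)))
        order = rng.permutation(len(catalog))
        for t_idx in range(m - 1):
            support, signs = catalog[order[t_idx % len(catalog)]]
            for f, s in zip(support, signs):
                T[f, t_idx + 1] = s * rng.uniform(0.7, 1.0)

    chroms = (np.arange(n) % 22) + 1
    positions = 10_000 + 1_000 * np.arange(n)
    variant_ids = [f"{c}:{p}" for c, p in zip(chroms, positions)]

    pal = rng.random(n) < config.palindrome_fraction
    pairs = []
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _NONPALINDROMIC_PAIRS
        a1, a2 = pool[int(rng.integers(0, len(pool)))]
        if rng.random() < 0.5:
            a1, a2 = a2, a1
        pairs.append((a1, a2))
    alleles = pd.DataFrame(pairs, index=variant_ids, columns=["a1", "a2"])

    # re-derive primary as argmax so downstream disjoint assignment is exact
    primary_series = pd.Series(np.argmax(V, axis=1), index=variant_ids).map(
        dict(enumerate(names))
    )
    return TrueStructure(
        planted_variant_weights=pd.DataFrame(V, index=variant_ids, columns=names),
        planted_trait_weights=pd.DataFrame(T, index=names, columns=traits),
        fi_increasing_allele=alleles["a1"].rename("fi_increasing_allele"),
        alleles=alleles,
        primary_factor=primary_series,
        variant_info=pd.DataFrame(
            {"chromosome": chroms, "position": positions}, index=variant_ids
        ),
    )


def generate_summary_stats(config: SimConfig):
    """Simulate per-trait association records with planted factor structure.

    Returns a long-format summary-statistics table (one row per variant-trait
    pair) and the :class:`TrueStructure` behind it.  The Z matrix is
    ``planted_variant_weights @ planted_trait_weights`` plus element-wise
    Gaussian noise; beta = Z * SE for a fixed SE, with two-sided normal
    p-values.  About ``flip_fraction`` of variants are emitted with the
    non-FI-increasing allele as effect allele, flipping the sign of every
    emitted beta for that variant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _plant_structure(config, rng)
    n, m = config.n_variants, config.n_traits

    Z = truth.planted_variant_weights.to_numpy() @ truth.planted_trait_weights.to_numpy()
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=(n, m))
        if config.fi_ascertainment:
            # variants are ascertained as FI-associated: the FI-column noise is
            # drawn conditional on the emitted FI Z clearing the 5e-5 screen
            lo = (_Z_SELECT - Z[:, 0]) / config.noise_sd
            noise[:, 0] = sps.truncnorm.rvs(
                lo, np.inf, scale=config.noise_sd, size=n, random_state=rng
            )
        Z = Z + noise

    flipped = rng.random(n) < config.flip_fraction
    fi_freq = _variant_frequencies(config, truth.variant_ids)

    records = []
    se = config.se
    for i, vid in enumerate(truth.variant_ids):
        a1, a2 = truth.alleles.loc[vid, "a1"], truth.alleles.loc[vid, "a2"]
        if flipped[i]:
            ea, oa, sign, eaf = a2, a1, -1.0, 1.0 - fi_freq[vid]
        else:
            ea, oa, sign, eaf = a1, a2, 1.0, fi_freq[vid]
        info = truth.variant_info.loc[vid]
        for j, trait in enumerate(truth.traits):
            z = sign * Z[i, j]
            records.append(
                (
                    vid,
                    int(info["chromosome"]),
                    int(info["position"]),
                    ea,
                    oa,
                    eaf,
                    z * se,
                    se,
                    max(float(2.0 * sps.norm.sf(abs(z))), _P_MIN),
                    100_000,
                    trait,
                )
            )
    stats = pd.DataFrame(
        records,
        columns=[
            "variant_id",
            "chromosome",
            "position",
            "effect_allele",
            "other_allele",
            "effect_allele_frequency",
            "beta",
            "standard_error",
            "p_value",
            "sample_size",
            "trait",
        ],
    )
    return stats, truth


def generate_ld_reference(
    config: SimConfig,
    proxy_spec: Sequence[tuple] = (),
    variant_ids: Sequence[str] | None = None,
) -> LDReference:
    """LD/frequency reference over the config's variants plus any named proxies.

    ``proxy_spec`` lists (index_variant, proxy_variant, r2) triples; the
    lookup is symmetric with unit diagonal.  Frequencies come from the same
    seeded stream the cohort generator uses.
    """
    config.validate()
    for a, b, r2 in proxy_spec:
        if not 0.0 <= float(r2) <= 1.0:
            raise ValueError(f"r2 for pair ({a}, {b}) outside [0, 1]: {r2}")
    if variant_ids is None:
        rng = np.random.default_rng(config.seed)
        variant_ids = _plant_structure(config, rng).variant_ids
    ids = list(dict.fromkeys(list(variant_ids)))
    extra = [v for pair in proxy_spec for v in pair[:2] if v not in ids]
    ids += list(dict.fromkeys(extra))
    freqs = _variant_frequencies(config, ids)
    return LDReference(frequencies=freqs.to_dict(), pairs=proxy_spec)


def planted_cluster_definitions(truth: TrueStructure, cutoff: float = 0.84) -> ClusterDefinitions:
    """Cluster definitions read off the planted structure.

    Each variant is assigned to its largest-loading factor only (disjoint
    clusters, so the cluster scores of unrelated individuals are mutually
    independent) with scoring weight ``sqrt(planted loading)`` -- the balanced
    square-root factorization scale an ARD factorization of the planted
    matrix converges to.  Trait weights are the signed square-root-scaled
    planted trait loadings.
    """
    v_rows = []
    for vid in truth.variant_ids:
        factor = truth.primary_factor[vid]
        w = float(np.sqrt(truth.planted_variant_weights.loc[vid, factor]))
        if w < cutoff:
            continue
        info = truth.variant_info.loc[vid]
        v_rows.append(
            dict(
                cluster=factor,
                variant_id=vid,
                fi_increasing_allele=truth.fi_increasing_allele[vid],
                weight=w,
                chromosome=int(info["chromosome"]),
                position=int(info["position"]),
            )
        )
    scale = float(np.sqrt(truth.planted_variant_weights.to_numpy().max()))
    t_rows = []
    for factor in truth.factors:
        row = truth.planted_trait_weights.loc[factor]
        for trait, t in row.items():
            if t == 0:
                continue
            signed = float(np.sign(t) * np.sqrt(abs(t)) * scale)
            if abs(signed) >= cutoff:
                t_rows.append(dict(cluster=factor, trait=trait, signed_weight=signed))
    v_frame = pd.DataFrame(
        v_rows,
        columns=["cluster", "variant_id", "fi_increasing_allele", "weight", "chromosome", "position"],
    )
    order = [f for f in truth.factors]
    v_frame["cluster"] = pd.Categorical(v_frame["cluster"], categories=order, ordered=True)
    v_frame = v_frame.sort_values(["cluster", "position"], kind="stable").reset_index(drop=True)
    v_frame["cluster"] = v_frame["cluster"].astype(str)
    empty = [f for f in order if f not in set(v_frame["cluster"])]
    return ClusterDefinitions(
        variant_weights=v_frame,
        trait_weights=pd.DataFrame(t_rows, columns=["cluster", "trait", "signed_weight"]),
        cutoff=cutoff,
        empty_clusters=empty,
    )


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept making the mean simulated risk equal the target prevalence."""

    def gap(alpha):
        return float(expit(alpha + eta).mean()) - prevalence

    return brentq(gap, -40.0, 40.0, xtol=1e-10)


def generate_cohort(
    config: SimConfig,
    defs: ClusterDefinitions,
    ld: LDReference | None = None,
    seed: int | None = None,
):
    """Simulate a genotype panel and phenotype table with known score effects.

    Dosages are binomial(2, frequency) per variant (Hardy-Weinberg); the
    panel's effect allele is randomly the FI-increasing allele or its partner,
    so orientation handling is exercised.  Outcomes are drawn from logistic
    (binary) or linear (quantitative) models whose linear predictor is
    ``intercept + sum_c log(OR10_c)/10 * pPS_c`` plus small age/sex/PC
    effects; the pPS entering the model is computed through the same
    resolution/scoring engine the analysis stage uses.

    Returns ``(panel, cohort)`` where ``cohort`` carries individual_id, the
    outcomes, age, sex, PC1..PC10, ancestry, and t2d_status.
    """
    config.validate()
    if len(defs.variant_weights) == 0 and not defs.empty_clusters:
        raise ValueError("defs must define at least one cluster")
    known = set(defs.clusters)
    for spec in config.outcome_specs:
        missing = set(spec.effects) - known
        if missing:
            raise ValueError(
                f"outcome_specs[{spec.name}] references clusters absent from defs: {sorted(missing)}"
            )

    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 11])
    n = config.n_individuals

    variant_ids = defs.all_variant_ids()
    fi_alleles = (
        defs.variant_weights.drop_duplicates("variant_id")
        .set_index("variant_id")["fi_increasing_allele"]
    )
    if ld is None:
        ld = generate_ld_reference(config, variant_ids=variant_ids)
    fi_freq = pd.Series({v: ld.frequency(v) for v in variant_ids})
    if fi_freq.isna().any():
        raise ValueError("LD reference lacks frequencies for some cluster variants")

    has_pos = "position" in defs.variant_weights.columns
    meta = defs.variant_weights.drop_duplicates("variant_id").set_index("variant_id")

    swap = rng.random(len(variant_ids)) < 0.5
    rows = []
    dosages = np.empty((n, len(variant_ids)))
    for j, vid in enumerate(variant_ids):
        fi = fi_alleles[vid]
        partner = {"A": "G", "G": "A", "C": "T", "T": "C"}[fi]  # non-palindromic partner
        f = float(fi_freq[vid])
        d_fi = rng.binomial(2, f, size=n).astype(float)
        if swap[j]:
            ea, oa, d = partner, fi, 2.0 - d_fi
        else:
            ea, oa, d = fi, partner, d_fi
        dosages[:, j] = d
        rows.append(
            dict(
                variant_id=vid,
                chromosome=int(meta.loc[vid, "chromosome"]) if has_pos else 0,
                position=int(meta.loc[vid, "position"]) if has_pos else j + 1,
                effect_allele=ea,
                other_allele=oa,
            )
        )
    variants = pd.DataFrame(rows).set_index("variant_id")
    individuals = [f"I{i + 1:06d}" for i in range(n)]
    panel = GenotypePanel.from_dosages(individuals, variants, dosages)

    resolved = resolve_variants(defs, panel, ld)
    pps = compute_pps(panel, resolved)

    age = rng.normal(60.0, 8.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    pcs = rng.normal(size=(n, 10))
    if config.confounded:
        total = pps.scores.sum(axis=1).to_numpy()
        sd = total.std() or 1.0
        age = age + 2.0 * (total - total.mean()) / sd

    ce = config.covariate_effects
    covar_eta = ce["age"] * (age - 60.0) + ce["sex"] * sex + ce["pc"] * pcs.sum(axis=1)

    cohort = pd.DataFrame({"individual_id": individuals})
    for spec in config.outcome_specs:
        eta = covar_eta.copy()
        for cluster, effect in spec.effects.items():
            if cluster not in pps.scores.columns:
                continue  # cluster emptied by the cutoff contributes nothing
            per_unit = np.log(effect) / 10.0 if spec.kind == "binary" else effect / 10.0
            eta = eta + per_unit * pps.scores[cluster].to_numpy()
        if spec.kind == "binary":
            alpha = _calibrate_intercept(eta, spec.baseline)
            y = rng.binomial(1, expit(alpha + eta)).astype(int)
        else:
            y = spec.baseline + eta + rng.normal(0.0, spec.noise_sd, size=n)
        cohort[spec.name] = y

    cohort["age"] = age
    cohort["sex"] = sex
    for p in range(10):
        cohort[f"PC{p + 1}"] = pcs[:, p]
    cohort["ancestry"] = rng.choice(
        ["EUR", "AFR", "AMR", "EAS", "SAS"], size=n, p=[0.6, 0.1, 0.1, 0.1, 0.1]
    )
    if "T2D" in cohort.columns:
        cohort["t2d_status"] = cohort["T2D"].astype(int)
    else:
        cohort["t2d_status"] = rng.binomial(1, 0.2, size=n)
    return panel, cohort


# -- shipped fixture configurations ------------------------------------------


def _config_from_mapping(data: dict) -> SimConfig:
    data = dict(data)
    specs = []
    for item in data.pop("outcome_specs", []) or []:
        specs.append(OutcomeSpec(**item))
    if "maf_range" in data:
        data["maf_range"] = tuple(data["maf_range"])
    cfg = SimConfig(outcome_specs=specs, **data)
    cfg.validate()
    return cfg


def load_sim_config(source) -> SimConfig:
    """Load a SimConfig from a YAML path or a shipped fixture name.

    Shipped names: ``sumstats_a`` and ``cohort_a``.
    """
    name = str(source)
    if name in ("sumstats_a", "cohort_a"):
        text = resources.files("insuclust").joinpath(f"fixtures/{name}.yaml").read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    return _config_from_mapping(yaml.safe_load(text))


def SUMSTATS_A() -> SimConfig:
    """The 230 x 43, seven-factor summary-statistics fixture."""
    return load_sim_config("sumstats_a")


def COHORT_A() -> SimConfig:
    """The n=50,000 cohort fixture with per-cluster T2D odds ratios."""
    return load_sim_config("cohort_a")
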