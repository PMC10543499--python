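"""Cluster-score association models and fixed-effects meta-analysis.

Per cohort, each cluster's partitioned polygenic score is regressed against
each outcome -- logistic for binary outcomes, ordinary least squares for
quantitative ones (eGFR) -- adjusted for age, sex and ten genetic principal
components, with estimates expressed per 10 score units.  Study-level
coefficients are pooled by inverse-variance-weighted fixed-effects
meta-analysis with Cochran's Q and the I^2 heterogeneity statistic, and
flagged against a Bonferroni-corrected significance threshold (the study
family: 8 outcomes x 7 clusters = 56 tests, alpha 0.05/56, printed 0.0008).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scores import PPSTable, decile_flag, reference_cutoffs

__all__ = [
    "AssociationResult",
    "MetaResult",
    "OutcomeModel",
    "FixedEffectsMeta",
    "fit_outcome_model",
    "stratify",
    "ivw_fixed_effects",
    "heterogeneity",
    "bonferroni_threshold",
    "format_threshold",
]

DEFAULT_COVARIATES = ["age", "sex"] + [f"PC{i}" for i in range(1, 11)]


@dataclass
class AssociationResult:
    """One cohort-level fit: per-10-unit log-odds (binary) or slope (quantitative)."""

    cohort: str
    cluster: str
    outcome: str
    stratum: str
    estimate: float
    se: float
    p: float
    n: int
    n_cases: int
    model: str  # logistic | linear
    exposure: str  # continuous_per10 | top_decile
    usable: bool = True
    reason: str = ""

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate) if self.model == "logistic" else float("nan")


def _is_binary(y: pd.Series) -> bool:
    vals = set(pd.unique(y.dropna()))
    return vals <= {0, 1, 0.0, 1.0, True, False}


def _screen_pcs(y, covars: pd.DataFrame, binary: bool) -> list:
    """PCs nominally associated (p < 0.05) with the outcome in the null model."""
    pcs = [c for c in covars.columns if c.startswith("PC")]
    base = [c for c in covars.columns if not c.startswith("PC")]
    X = sm.add_constant(covars[base + pcs], has_constant="add")
    try:
        if binary:
            null_fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        else:
            null_fit = sm.OLS(y, X).fit()
        return [c for c in pcs if null_fit.pvalues[c] < 0.05]
    except Exception:
        return pcs


def fit_outcome_model(
    cohort: pd.DataFrame,
    scores: PPSTable,
    cluster: str,
    outcome: str,
    exposure: str = "continuous_per10",
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    pc_screen: bool = False,
    decile_cutoffs: Mapping | None = None,
    cohort_name: str = "cohort",
    stratum: str = "all",
    min_cases: int = 10,
    min_obs: int = 30,
) -> AssociationResult:
    """Regress one outcome on one cluster score, adjusted for covariates.

    ``exposure='continuous_per10'`` uses score/10 as the predictor so the
    coefficient is per 10 score units; ``'top_decile'`` uses the binary
    top-decile flag (cutoffs from ``decile_cutoffs``, or the scored cohort's
    own 90th percentile when not supplied).  Non-convergence or separation
    yields a result flagged unusable rather than an exception.
    """
    if exposure not in ("continuous_per10", "top_decile"):
        raise ValueError("exposure must be continuous_per10 or top_decile")
    data = cohort.set_index("individual_id") if "individual_id" in cohort.columns else cohort
    common = data.index.intersection(scores.scores.index)
    data = data.loc[common]
    score = scores.scores.loc[common, cluster]

    if exposure == "continuous_per10":
        x = score / 10.0
    else:
        cutoffs = dict(decile_cutoffs) if decile_cutoffs is not None else reference_cutoffs(scores)
        x = decile_flag(scores, cutoffs).loc[common, cluster].astype(float)

    y = data[outcome]
    keep = y.notna() & x.notna()
    covars = data.loc[keep, list(covariates)]
    y, x = y[keep], x[keep]
    binary = _is_binary(y)
    n = int(len(y))
    n_cases = int(y.sum()) if binary else n

    def failed(reason):
        return AssociationResult(
            cohort_name, cluster, outcome, stratum, float("nan"), float("nan"),
            float("nan"), n, n_cases, "logistic" if binary else "linear",
            exposure, usable=False, reason=reason,
        )

    if binary and (n_cases < min_cases or n - n_cases < min_cases):
        return failed("too_few_cases")
    if not binary and n < min_obs:
        return failed("too_few_observations")

    if pc_screen:
        kept_pcs = _screen_pcs(y, covars, binary)
        covars = covars[[c for c in covars.columns if not c.startswith("PC")] + kept_pcs]

    X = pd.concat([x.rename("score"), covars], axis=1)
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if binary:
                fit = sm.Logit(y.astype(float), X).fit(disp=0, maxiter=200, method="newton")
                if not fit.mle_retvals.get("converged", False):
                    return failed("non_convergence")
            else:
                fit = sm.OLS(y.astype(float), X).fit()
    except Exception as exc:  # separation, singular design
        return failed(f"fit_error:{type(exc).__name__}")
    est, se_, p = float(fit.params["score"]), float(fit.bse["score"]), float(fit.pvalues["score"])
    if not (np.isfinite(est) and np.isfinite(se_) and se_ > 0):
        return failed("separation")
    return AssociationResult(
        cohort_name, cluster, outcome, stratum, est, se_, max(p, 1e-320), n, n_cases,
        "logistic" if binary else "linear", exposure,
    )


class OutcomeModel:
    """Model-object wrapper over :func:`fit_outcome_model`."""

    def __init__(self, cohort: pd.DataFrame, scores: PPSTable, cluster: str, outcome: str, **kwargs):
        self.cohort = cohort
        self.scores = scores
        self.cluster = cluster
        self.outcome = outcome
        self.kwargs = kwargs

    def fit(self) -> AssociationResult:
        return fit_outcome_model(self.cohort, self.scores, self.cluster, self.outcome, **self.kwargs)


def stratify(
    cohort: pd.DataFrame,
    by: str,
    min_size: int = 500,
    allowed: Sequence[str] | None = None,
):
    """Partition a cohort by ancestry or T2D status.

    Returns a list of (label, subtable, flagged_small) triples.  Labels
    outside ``allowed`` (when given) are grouped under ``"other"`` with a
    warning.
    """
    column = {"ancestry": "ancestry", "t2d_status": "t2d_status"}.get(by, by)
    if column not in cohort.columns:
        raise ValueError(f"stratification column {column!r} absent from cohort table")
    labels = cohort[column].astype(str)
    if allowed is not None:
        unknown = sorted(set(labels) - set(map(str, allowed)))
        if unknown:
            warnings.warn(f"unknown stratum labels grouped under 'other': {unknown}", stacklevel=2)
            labels = labels.where(labels.isin(list(map(str, allowed))), "other")
    out = []
    for label in dict.fromkeys(labels):
        sub = cohort[ (labels == label).to_numpy() ]
        out.append((label, sub, len(sub) < min_size))
    return out


@dataclass
class MetaResult:
    """Pooled effect for one (cluster, outcome, stratum) across cohorts."""

    cluster: str
    outcome: str
    stratum: str
    exposure: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    i2: float  # percent, NaN when k < 2
    k: int
    model: str
    significant: bool | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate) if self.model == "logistic" else float("nan")

    def summary(self) -> str:
        or_part = f"  OR:        {self.odds_ratio:.4f}\n" if self.model == "logistic" else ""
        i2 = "n/a" if not np.isfinite(self.i2) else f"{self.i2:.1f}%"
        return (
            f"IVW fixed-effects meta-analysis ({self.k} studies)\n"
            f"  cluster:   {self.cluster}\n"
            f"  outcome:   {self.outcome} ({self.stratum}, {self.exposure})\n"
            f"  estimate:  {self.estimate:.4f} (SE {self.se:.4f}) per 10 units\n"
            + or_part
            + f"  95% CI:    [{self.ci_low:.4f}, {self.ci_high:.4f}]\n"
            f"  p:         {self.p:.3g}\n"
            f"  Q:         {self.q:.3f}   I^2: {i2}"
        )


def ivw_fixed_effects(results: Sequence[AssociationResult]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling of cohort estimates.

    weights w_i = 1/se_i^2; pooled beta = sum(w_i b_i)/sum(w_i); pooled SE =
    1/sqrt(sum w_i); two-sided normal p; 95% CI at +/- 1.96 SE.  Unusable
    cohort fits are excluded.
    """
    from scipy import stats as sps

    usable = [r for r in results if r.usable]
    if not usable:
        raise ValueError("no usable association results to pool")
    keys = {(r.cluster, r.outcome, r.stratum, r.exposure) for r in usable}
    if len(keys) > 1:
        raise ValueError(f"results mix several (cluster, outcome, stratum, exposure): {keys}")
    betas = np.array([r.estimate for r in usable])
    ws = np.array([1.0 / r.se**2 for r in usable])
    pooled = float((ws * betas).sum() / ws.sum())
    se = float(1.0 / math.sqrt(ws.sum()))
    z = pooled / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    q, i2 = heterogeneity(usable, pooled)
    r0 = usable[0]
    return MetaResult(
        cluster=r0.cluster, outcome=r0.outcome, stratum=r0.stratum, exposure=r0.exposure,
        estimate=pooled, se=se, ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se,
        p=max(p, 1e-320), q=q, i2=i2, k=len(usable), model=r0.model,
    )


def heterogeneity(results: Sequence[AssociationResult], pooled: float):
    """Cochran's Q and I^2 = max(0, (Q - (k-1))/Q) x 100; I^2 is NaN for k < 2."""
    usable = [r for r in results if r.usable]
    k = len(usable)
    if k < 2:
        return 0.0, float("nan")
    betas = np.array([r.estimate for r in usable])
    ws = np.array([1.0 / r.se**2 for r in usable])
    q = float((ws * (betas - pooled) ** 2).sum())
    i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, i2


class FixedEffectsMeta:
    """Model-object wrapper over :func:`ivw_fixed_effects`."""

    def __init__(self, results: Sequence[AssociationResult]):
        self.results = list(results)

    def fit(self, alpha_threshold: float | None = None) -> MetaResult:
        meta = ivw_fixed_effects(self.results)
        if alpha_threshold is not None:
            meta.significant = meta.p < alpha_threshold
        return meta


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test two-sided alpha after Bonferroni adjustment."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def format_threshold(threshold: float, decimals: int = 4) -> str:
    """Reporting mode: threshold truncated (not rounded) to ``decimals`` places."""
    scale = 10**decimals
    return f"{math.floor(threshold * scale) / scale:.{decimals}f}"


def meta_table(metas: Sequence[MetaResult], alpha_threshold: float | None = None) -> pd.DataFrame:
    """Flat table of meta-analysis rows, one per (cluster, outcome, stratum)."""
    rows = []
    for m in metas:
        sig = m.significant if alpha_threshold is None else (m.p < alpha_threshold)
        rows.append(
            dict(
                cluster=m.cluster, outcome=m.outcome, stratum=m.stratum, exposure=m.exposure,
                k=m.k, estimate=m.estimate, se=m.se, OR=m.odds_ratio,
                ci_low=m.ci_low, ci_high=m.ci_high, p=m.p, Q=m.q, I2=m.i2,
                significant=bool(sig) if sig is not None else None,
            )
        )
    return pd.DataFrame(rows)
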