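"""Bayesian non-negative matrix factorization with automatic relevance determination.

Fits ``X ~ W H`` under a Gaussian likelihood with half-normal priors on the
columns of ``W`` and rows of ``H``.  Column ``k`` of ``W`` and row ``k`` of
``H`` share a relevance (prior-variance) parameter ``lambda_k`` carrying an
inverse-gamma(a, b) hyperprior; maximizing the posterior drives the relevance
of unused components toward the hyperprior floor, shrinking their weights so
the effective rank K is determined by the data.  Across random restarts the
maximum-posterior solution at the modal effective K is selected, and a weight
cutoff (either a fixed value or the elbow of the pooled weight distribution)
turns the factorization into discrete cluster definitions.

The model is presented statsmodels-style: :class:`BayesianNMF` is constructed
from a non-negative matrix, ``fit`` returns a :class:`BNMFResults`, and
``fit_restarts`` runs the multi-start procedure whose output feeds
:func:`select_solution`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BnmfHyperparams",
    "BayesianNMF",
    "BNMFResults",
    "ClusterSolution",
    "ClusterDefinitions",
    "select_solution",
    "long_tail_cutoff",
    "threshold_weights",
]

_EPS = 1e-12
_POS_SUFFIX = "_pos"
_NEG_SUFFIX = "_neg"


@dataclass
class BnmfHyperparams:
    """Hyperparameters of the ARD factorization.

    ``b`` and ``prune_eps`` default to data-dependent values (``mean(X)`` and
    ``1e-6 * ||X||_F`` respectively) when left as ``None``.
    """

    k0: int = 20
    a: float = 25.0
    b: float | None = None
    tol: float = 1e-9
    max_iter: int = 10_000
    prune_eps: float | None = None
    n_restarts: int = 100
    seed: int = 0
    # noise-variance floor as a fraction of mean(X^2): keeps the relevance
    # penalty alive on (near-)noiseless inputs, where the MAP sigma^2 would
    # otherwise collapse and disable component pruning entirely
    sigma2_floor: float = 1e-3
    # optional un-regularized multiplicative warm-up iterations before the
    # relevance prior switches on (off by default: established components
    # are never pruned afterwards, which defeats rank selection)
    warmup: int = 0

    @classmethod
    def noise_free(cls, **overrides) -> "BnmfHyperparams":
        """Settings for (near-)noiseless, exactly low-rank inputs.

        A short un-regularized warm-up lets components reach the signal
        before the relevance prior starts competing them away, and a raised
        noise floor keeps enough pruning pressure to merge duplicate
        components once the residual vanishes.  With the regular defaults a
        noise-free matrix either loses all components at initialization or
        retains redundant duplicates.
        """
        base = dict(warmup=15, sigma2_floor=0.1, tol=1e-10, max_iter=50_000)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.k0 < 2:
            raise ValueError("k0 must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.a <= 0 or (self.b is not None and self.b <= 0):
            raise ValueError("hyperprior shape/scale a, b must be > 0")


class BayesianNMF:
    """ARD non-negative factorization model for a variants x columns matrix.

    Parameters
    ----------
    X : DataFrame or ndarray
        Non-negative input.  When the columns follow the ``<trait>_pos`` /
        ``<trait>_neg`` doubling convention, :func:`select_solution` re-merges
        them into signed trait weights.
    hyperparams : BnmfHyperparams, optional
    """

    def __init__(self, X, hyperparams: BnmfHyperparams | None = None, **kwargs):
        if hasattr(X, "X"):  # NonNegMatrix from insuclust.zmatrix
            X = X.X
        if isinstance(X, pd.DataFrame):
            self.row_labels = list(X.index)
            self.col_labels = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.row_labels = list(range(X.shape[0]))
            self.col_labels = list(range(X.shape[1]))
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite (impute missing entries before fitting)")
        if np.any(X < 0):
            raise ValueError("X must be non-negative")
        self.X = X
        hp = hyperparams or BnmfHyperparams()
        if kwargs:
            hp = BnmfHyperparams(**{**hp.__dict__, **kwargs})
        hp.validate()
        self.hyperparams = hp
        self._b = hp.b if hp.b is not None else max(float(X.mean()), 1e-6)
        self._prune_eps = (
            hp.prune_eps
            if hp.prune_eps is not None
            else max(1e-6 * float(np.linalg.norm(X)), 1e-12)
        )
        self._sigma2_min = max(hp.sigma2_floor * float((X**2).mean()), _EPS)

    # -- single fit ----------------------------------------------------------

    def fit(self, seed: int | None = None, W0=None, H0=None) -> "BNMFResults":
        """Run one multiplicative-update MAP fit from a random (or given) start."""
        hp = self.hyperparams
        X = self.X
        n, m = X.shape
        k0 = hp.k0
        seed = hp.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        if W0 is None or H0 is None:
            W = rng.uniform(size=(n, k0))
            H = rng.uniform(size=(k0, m))
            # scale so mean(WH) matches mean(X), avoiding immediate mass pruning
            mean_wh = float((W @ H).mean())
            mean_x = float(X.mean())
            if mean_x > 0 and mean_wh > 0:
                c = np.sqrt(mean_x / mean_wh)
                W *= c
                H *= c
        else:
            W = np.array(W0, dtype=float, copy=True)
            H = np.array(H0, dtype=float, copy=True)
            if W.shape != (n, k0) or H.shape != (k0, m):
                raise ValueError("W0/H0 shapes do not match (n, k0)/(k0, m)")

        a, b = hp.a, self._b
        for _ in range(hp.warmup):
            W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
            H *= (W.T @ X) / ((W.T @ W) @ H + _EPS)
        lam_denom = (n + m) / 2.0 + a + 1.0
        lam = (0.5 * (W**2).sum(axis=0) + 0.5 * (H**2).sum(axis=1) + b) / lam_denom
        R = X - W @ H
        sigma2 = max(float((R**2).mean()), self._sigma2_min)

        trace = []
        obj_prev = np.inf
        converged = False
        n_iter = hp.max_iter
        for it in range(hp.max_iter):
            # block multiplicative updates (monotone majorize-minimize steps)
            W *= (X @ H.T) / (W @ (H @ H.T) + sigma2 * (W / lam) + _EPS)
            H *= (W.T @ X) / ((W.T @ W) @ H + sigma2 * (H / lam[:, None]) + _EPS)
            w_sq = (W**2).sum(axis=0)
            h_sq = (H**2).sum(axis=1)
            lam = (0.5 * w_sq + 0.5 * h_sq + b) / lam_denom
            rss = float(((X - W @ H) ** 2).sum())
            sigma2 = max(rss / (n * m), self._sigma2_min)
            obj = (
                rss / (2.0 * sigma2)
                + (n * m / 2.0) * np.log(sigma2)
                + float(((0.5 * w_sq + 0.5 * h_sq + b) / lam).sum())
                + lam_denom * float(np.log(lam).sum())
            )
            trace.append(obj)
            if it > 0 and abs(obj_prev - obj) <= hp.tol * abs(obj_prev):
                converged = True
                n_iter = it + 1
                break
            obj_prev = obj

        comp_norm = np.sqrt((W**2).sum(axis=0) + (H**2).sum(axis=1))
        live = comp_norm >= self._prune_eps
        W[:, ~live] = 0.0
        H[~live, :] = 0.0
        return BNMFResults(
            model=self,
            W=W,
            H=H,
            lam=lam,
            sigma2=sigma2,
            objective_trace=np.asarray(trace),
            live=live,
            seed=seed,
            converged=converged,
            n_iter=n_iter,
        )

    def fit_restarts(self, n_restarts: int | None = None, seed: int | None = None):
        """Run independent restarts with per-restart seeds spawned from ``seed``."""
        hp = self.hyperparams
        n_restarts = hp.n_restarts if n_restarts is None else n_restarts
        seed = hp.seed if seed is None else seed
        root = np.random.SeedSequence(seed)
        fits = []
        for child in root.spawn(n_restarts):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            fits.append(self.fit(seed=sub_seed))
        return fits


@dataclass
class BNMFResults:
    """One converged (or max-iteration) factorization run."""

    model: BayesianNMF
    W: np.ndarray
    H: np.ndarray
    lam: np.ndarray
    sigma2: float
    objective_trace: np.ndarray
    live: np.ndarray
    seed: int
    converged: bool
    n_iter: int

    @property
    def effective_k(self) -> int:
        return int(self.live.sum())

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H

    def relative_error(self) -> float:
        norm = np.linalg.norm(self.model.X)
        if norm == 0:
            return 0.0
        return float(np.linalg.norm(self.model.X - self.reconstruction) / norm)

    def summary(self) -> str:
        lines = [
            "Bayesian NMF (ARD) fit",
            f"  shape:          {self.model.X.shape[0]} x {self.model.X.shape[1]}",
            f"  k0:             {self.model.hyperparams.k0}",
            f"  effective K:    {self.effective_k}",
            f"  iterations:     {self.n_iter} (converged={self.converged})",
            f"  final objective {self.objective:.6g}",
            f"  sigma^2:        {self.sigma2:.6g}",
            f"  rel. error:     {self.relative_error():.4g}",
            f"  seed:           {self.seed}",
        ]
        return "\n".join(lines)


# -- solution selection ------------------------------------------------------


@dataclass
class ClusterSolution:
    """Selected factorization with signed trait weights re-merged per trait."""

    fit: BNMFResults
    k: int
    variant_weights: pd.DataFrame  # variants x k, >= 0
    trait_weights: pd.DataFrame  # k x traits, signed

    def summary(self) -> str:
        lines = [self.fit.summary(), f"  clusters:       {self.k}"]
        for c in self.variant_weights.columns:
            top = self.variant_weights[c].nlargest(3)
            lines.append(
                f"  {c}: top variants " + ", ".join(f"{v} ({w:.2f})" for v, w in top.items())
            )
        return "\n".join(lines)


def _merge_signed_traits(H: pd.DataFrame) -> pd.DataFrame:
    """Re-merge ``<trait>_pos`` / ``<trait>_neg`` column pairs into signed weights."""
    cols = list(H.columns)
    pos = [c for c in cols if str(c).endswith(_POS_SUFFIX)]
    if not pos:
        return H.copy()
    traits = [str(c)[: -len(_POS_SUFFIX)] for c in pos]
    out = {}
    for t in traits:
        p = H[f"{t}{_POS_SUFFIX}"]
        n = H.get(f"{t}{_NEG_SUFFIX}", 0.0)
        out[t] = p - n
    return pd.DataFrame(out, index=H.index)


def select_solution(fits: Sequence[BNMFResults]) -> ClusterSolution:
    """Maximum-posterior solution at the most probable effective rank.

    K* is the mode of ``effective_k`` over converged fits (ties broken toward
    the smaller K); among fits at K*, the lowest final negative log-posterior
    wins.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    ks = np.array([f.effective_k for f in usable])
    values, counts = np.unique(ks, return_counts=True)
    k_star = int(values[counts == counts.max()].min())
    candidates = [f for f in usable if f.effective_k == k_star]
    best = min(candidates, key=lambda f: f.objective)

    live_idx = np.flatnonzero(best.live)
    names = [f"cluster_{i + 1}" for i in range(len(live_idx))]
    W = pd.DataFrame(best.W[:, live_idx], index=best.model.row_labels, columns=names)
    H = pd.DataFrame(best.H[live_idx, :], index=names, columns=best.model.col_labels)
    return ClusterSolution(fit=best, k=k_star, variant_weights=W, trait_weights=_merge_signed_traits(H))


# -- cutoff and cluster definitions ------------------------------------------


def long_tail_cutoff(
    variant_weights: pd.DataFrame | "ClusterSolution",
    trait_weights: pd.DataFrame | None = None,
) -> float:
    """Elbow of the pooled weight distribution (start of the long tail).

    Pools all variant weights and absolute trait weights across clusters,
    sorts the distinct values in descending order, and returns the value at
    the point of maximum perpendicular distance to the chord joining the
    largest and smallest values.  With only two distinct values the transition
    itself is the elbow and the larger value is returned; with one distinct
    value that value is returned with a warning.
    """
    if isinstance(variant_weights, ClusterSolution):
        sol = variant_weights
        variant_weights = sol.variant_weights
        trait_weights = sol.trait_weights
    pooled = [np.abs(np.asarray(variant_weights, dtype=float)).ravel()]
    if trait_weights is not None:
        pooled.append(np.abs(np.asarray(trait_weights, dtype=float)).ravel())
    w = np.concatenate(pooled)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("no nonzero weights to locate an elbow in")
    y = np.unique(w)[::-1]  # distinct, descending
    if y.size == 1:
        warnings.warn("all pooled weights equal; no elbow", stacklevel=2)
        return float(y[0])
    if y.size == 2:
        return float(y[0])
    x = np.arange(y.size, dtype=float)
    # perpendicular distance of each point to the chord (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    return float(y[int(np.argmax(dist))])


@dataclass
class ClusterDefinitions:
    """Per-cluster member variants (scoring weights) and signed trait weights.

    ``variant_weights`` has columns cluster, variant_id, fi_increasing_allele,
    weight (plus optional chromosome/position); ``trait_weights`` has columns
    cluster, trait, signed_weight.  Clusters emptied by the cutoff are listed
    in ``empty_clusters`` rather than dropped, so cluster IDs stay stable.
    """

    variant_weights: pd.DataFrame
    trait_weights: pd.DataFrame
    cutoff: float
    empty_clusters: list = field(default_factory=list)

    @property
    def clusters(self) -> list:
        known = list(dict.fromkeys(self.variant_weights["cluster"])) + self.empty_clusters
        return list(dict.fromkeys(known))

    def variants_for(self, cluster) -> pd.DataFrame:
        return self.variant_weights[self.variant_weights["cluster"] == cluster]

    def all_variant_ids(self) -> list:
        return list(dict.fromkeys(self.variant_weights["variant_id"]))

    def __len__(self) -> int:
        return len(self.clusters)


def threshold_weights(
    solution: ClusterSolution,
    cutoff: float = 0.84,
    fi_alleles: Mapping[str, str] | None = None,
    positions: Mapping[str, tuple] | None = None,
    normalize: bool = False,
) -> ClusterDefinitions:
    """Retain variants with weight >= cutoff and traits with \\|weight\\| >= cutoff.

    A variant may belong to several clusters.  ``fi_alleles`` maps variant_id
    to its FI-increasing allele (required downstream for scoring);
    ``positions`` maps variant_id to (chromosome, position).  ``normalize``
    rescales all weights by the largest pooled weight before applying the
    cutoff (off by default: the cutoff applies to raw weights).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    variant_weights = solution.variant_weights
    trait_weights = solution.trait_weights
    if normalize:
        top = max(
            float(np.abs(variant_weights.to_numpy()).max(initial=0.0)),
            float(np.abs(trait_weights.to_numpy()).max(initial=0.0)),
        )
        if top > 0:
            variant_weights = variant_weights / top
            trait_weights = trait_weights / top
    v_rows, t_rows, empty = [], [], []
    for cluster in variant_weights.columns:
        wv = variant_weights[cluster]
        members = wv[wv >= cutoff] if cutoff > 0 else wv[wv > 0]
        wt = trait_weights.loc[cluster]
        t_members = wt[wt.abs() >= cutoff] if cutoff > 0 else wt[wt != 0]
        if members.empty and t_members.empty:
            empty.append(cluster)
        for vid, w in members.items():
            row = {
                "cluster": cluster,
                "variant_id": vid,
                "fi_increasing_allele": (fi_alleles or {}).get(vid, "N"),
                "weight": float(w),
            }
            if positions and vid in positions:
                row["chromosome"], row["position"] = positions[vid]
            v_rows.append(row)
        for trait, w in t_members.items():
            t_rows.append({"cluster": cluster, "trait": trait, "signed_weight": float(w)})
    v_cols = ["cluster", "variant_id", "fi_increasing_allele", "weight"]
    if positions:
        v_cols += ["chromosome", "position"]
    return ClusterDefinitions(
        variant_weights=pd.DataFrame(v_rows, columns=v_cols),
        trait_weights=pd.DataFrame(t_rows, columns=["cluster", "trait", "signed_weight"]),
        cutoff=float(cutoff),
        empty_clusters=empty,
    )
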