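"""Linear mixed model association scans with a realized relationship matrix.

Each locus is tested per environment against the replicate-averaged trait by
a likelihood-ratio test between two linear mixed models

    null:        y = 1*mu                + g + e
    alternative: y = 1*mu + x_locus*beta + g + e

with random genetic background g ~ N(0, sigma_g^2 K) for the realized
relationship matrix K and residual e ~ N(0, sigma_e^2 I). Both models are
fitted by maximum likelihood: the likelihood is profiled analytically over
the fixed effects and the total variance on the eigenbasis of K, leaving a
1-D maximization over the variance ratio delta = sigma_e^2 / sigma_g^2.
The LRT statistic 2*(ll_alt - ll_null) is referred to chi-squared with one
degree of freedom, and per-scan q-values come from the Benjamini-Hochberg
step-up procedure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "relationship_matrix",
    "lmm_loglik",
    "lrt_pvalue",
    "gwas_scan",
    "bh_qvalues",
]

_P_FLOOR = float(np.finfo(float).tiny)  # keeps -log10(p) finite in plots
_LOG10_DELTA_RANGE = (-6.0, 6.0)


@dataclass
class RelationshipMatrix:
    """Symmetric cultivar x cultivar genetic relatedness matrix."""

    matrix: np.ndarray
    cultivars: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.cultivars)
        if self.matrix.shape != (n, n):
            raise ValueError("relationship matrix shape does not match cultivar count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        order = {c: i for i, c in enumerate(self.cultivars)}
        rows = np.array([order[c] for c in ids])
        return RelationshipMatrix(self.matrix[np.ix_(rows, rows)], list(ids))


def relationship_matrix(G: GenotypeMatrix) -> RelationshipMatrix:
    """Realized relationship matrix from standardized genome-wide genotypes.

    Each non-constant genotype column is mean-centred and scaled to unit
    population variance (divide by n); K = Z Z^T / m over the m retained
    columns. Under this standardization mean(diag(K)) is exactly 1.
    """
    if G.n_cultivars < 2:
        raise ValueError("need >= 2 cultivars for a relationship matrix")
    X = G.values.astype(float)
    sd = X.std(axis=0)  # population (divide-by-n) scaling
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genotype columns are constant; relatedness undefined")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    m = int(keep.sum())
    return RelationshipMatrix(Z @ Z.T / m, list(G.cultivars))


# ---------------------------------------------------------------------------
# profiled ML likelihood on the eigenbasis of K


def _eigen(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, U = np.linalg.eigh(K)
    return np.clip(lam, 0.0, None), U


def _profile_loglik(delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Max log-likelihood at fixed variance ratio, with GLS beta and scale
    profiled out analytically."""
    n = len(yt)
    w = 1.0 / (lam + delta)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    rss = float(yt @ (w * yt) - b @ beta)
    rss = max(rss, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * rss / n) + n + np.sum(np.log(lam + delta)))
    return ll, beta


_COARSE_LOG10_DELTA = np.linspace(*_LOG10_DELTA_RANGE, 49)


def _max_loglik(lam, yt, Xt, log10_range=_LOG10_DELTA_RANGE):
    """Maximize the profiled likelihood over log10(delta).

    The profile can be multimodal in the variance ratio, so a coarse grid
    locates the global basin before a bounded scalar search refines it.
    """
    lls = [_profile_loglik(10.0**t, lam, yt, Xt)[0] for t in _COARSE_LOG10_DELTA]
    i = int(np.argmax(lls))
    lo = _COARSE_LOG10_DELTA[max(i - 1, 0)]
    hi = _COARSE_LOG10_DELTA[min(i + 1, len(_COARSE_LOG10_DELTA) - 1)]
    res = minimize_scalar(
        lambda t: -_profile_loglik(10.0**t, lam, yt, Xt)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    delta = 10.0 ** float(res.x)
    ll, beta = _profile_loglik(delta, lam, yt, Xt)
    if lls[i] > ll:  # grid point beat the refinement (flat boundary case)
        delta = 10.0 ** float(_COARSE_LOG10_DELTA[i])
        ll, beta = _profile_loglik(delta, lam, yt, Xt)
    return ll, delta, beta


def lmm_loglik(y, X, K, delta: float | None = None) -> float:
    """Maximum log-likelihood of y ~ N(X beta, sigma_g^2 K + sigma_e^2 I).

    beta and the total variance are profiled out analytically; the variance
    ratio ``delta = sigma_e^2 / sigma_g^2`` is maximized over by 1-D search on
    the eigendecomposition of K unless a fixed value is supplied. At very
    large delta the model degenerates to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    # all-zero covariates carry no contrast at all; drop them rather than
    # treating the design as singular
    X = X[:, np.abs(X).sum(axis=0) > 0]
    if X.shape[1] == 0:
        raise ValueError("fixed-effect design X has no usable columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is singular")
    K = np.asarray(K, dtype=float)
    lam, U = _eigen(K)
    yt = U.T @ y
    Xt = U.T @ X
    if delta is not None:
        return _profile_loglik(float(delta), lam, yt, Xt)[0]
    return _max_loglik(lam, yt, Xt)[0]


def lrt_pvalue(y, K, x_locus) -> float:
    """Likelihood-ratio chi-squared p-value for one locus dummy.

    A constant locus dummy offers zero contrast: the alternative model
    collapses onto the null, the statistic is 0 and p = 1 (association scans
    additionally screen such loci out via the carrier-count filter and report
    them as missing).
    """
    p, _ = _lrt(y, K, x_locus)
    return p


def _lrt(y, K, x_locus):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_locus, dtype=float)
    if np.ptp(x) == 0:
        return 1.0, np.nan
    K = np.asarray(K, dtype=float)
    lam, U = _eigen(K)
    yt = U.T @ y
    ones_t = U.T @ np.ones_like(y)
    ll0, _, _ = _max_loglik(lam, yt, ones_t[:, None])
    ll1, _, beta = _max_loglik(lam, yt, np.column_stack([ones_t, U.T @ x]))
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = max(float(chi2.sf(stat, df=1)), _P_FLOOR)
    return p, float(beta[1])


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def gwas_scan(
    trait: pd.Series,
    G: GenotypeMatrix,
    K: RelationshipMatrix | None = None,
    min_count: int = 2,
    min_phenotyped: int = 10,
) -> pd.DataFrame:
    """Scan every locus against one environment's replicate-averaged trait.

    Parameters
    ----------
    trait
        Trait values indexed by cultivar id; missing values are dropped.
    G
        Genotype dummies for (at least) the phenotyped cultivars.
    K
        Relationship matrix; computed from ``G`` when omitted, and subset to
        the phenotyped cultivars either way.
    min_count
        Loci with fewer than this many carriers or non-carriers among the
        phenotyped cultivars are skipped (reported with NaN p).

    Returns
    -------
    DataFrame indexed by locus id with columns ``chrom, pos, p, q, effect,
    n_used``. q-values are computed per scan over the usable loci.
    """
    y = pd.Series(trait).dropna()
    used = [c for c in G.cultivars if c in y.index]
    if len(used) < min_phenotyped:
        raise ValueError(
            f"only {len(used)} phenotyped cultivars; need >= {min_phenotyped}"
        )
    Gs = G.subset_cultivars(used)
    if K is None:
        K = relationship_matrix(G)
    Ks = K.submatrix(used).matrix
    yv = y.loc[used].to_numpy(dtype=float)
    n = len(used)

    lam, U = _eigen(Ks)
    yt = U.T @ yv
    ones_t = U.T @ np.ones(n)
    ll0, _, _ = _max_loglik(lam, yt, ones_t[:, None])
    Xt_all = U.T @ Gs.values.astype(float)

    counts = Gs.values.sum(axis=0)
    p = np.full(Gs.n_loci, np.nan)
    eff = np.full(Gs.n_loci, np.nan)
    for j in range(Gs.n_loci):
        c = counts[j]
        if c < min_count or n - c < min_count:
            continue
        Xt = np.column_stack([ones_t, Xt_all[:, j]])
        ll1, _, beta = _max_loglik(lam, yt, Xt)
        stat = max(0.0, 2.0 * (ll1 - ll0))
        p[j] = max(float(chi2.sf(stat, df=1)), _P_FLOOR)
        eff[j] = beta[1]

    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_qvalues(p[ok])
    out = pd.DataFrame(
        {
            "chrom": Gs.loci["chrom"].to_numpy(),
            "pos": Gs.loci["pos"].to_numpy(),
            "p": p,
            "q": q,
            "effect": eff,
            "n_used": n,
        },
        index=Gs.loci.index,
    )
    return out
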