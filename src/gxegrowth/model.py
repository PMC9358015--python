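"""Multifactorial G + E + GxE regression models for growth-related traits.

For sample i (a cultivar grown in one environment) the model is

    y_i = c + sum_h alpha_h x_{h,i} + sum_k beta_k z_{k,i}
            + sum_h sum_k gamma_{h,k} x_{h,i} z_{k,i} + eps_i

where x_{h,i} in {0, 1} is the dummy for genetic factor h (presence of a
specific homozygous variant genotype), z_{k,i} the numeric value of
environmental factor k (temperature-window mean, sowing day-of-year,
latitude), and the products x*z carry the genotype-by-environment
interactions. Four nested patterns are supported: P=G, P=E, P=G+E and
P=G+E+GxE. Coefficients are estimated by ordinary least squares
(minimum-norm solution under rank deficiency); concordance between observed
and model values is summarized by Pearson's R and the RMSE on the training
and held-out environment sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq
from scipy.stats import pearsonr

from .containers import GenotypeMatrix

__all__ = [
    "PATTERNS",
    "ModelSpec",
    "FittedModel",
    "EvalResult",
    "build_design_matrix",
    "fit_ols",
    "fit_model",
    "predict",
    "evaluate",
    "factor_count_scan",
]

PATTERNS = ("G", "E", "G+E", "G+E+GxE")


@dataclass(frozen=True)
class ModelSpec:
    """Which trait, pattern, and factors make up one regression model."""

    trait: str
    pattern: str
    g_factors: tuple[str, ...] = ()
    e_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        object.__setattr__(self, "g_factors", tuple(self.g_factors))
        object.__setattr__(self, "e_factors", tuple(self.e_factors))
        if "G" in self.pattern and not self.g_factors:
            raise ValueError(f"pattern {self.pattern} requires >= 1 genetic factor")
        if "E" in self.pattern and not self.e_factors:
            raise ValueError(f"pattern {self.pattern} requires >= 1 environmental factor")

    @property
    def uses_g(self) -> bool:
        return "G" in self.pattern

    @property
    def uses_e(self) -> bool:
        return "E" in self.pattern

    @property
    def uses_interaction(self) -> bool:
        return self.pattern == "G+E+GxE"


@dataclass
class FittedModel:
    """OLS-fitted coefficients for one ModelSpec.

    ``coef`` is indexed by column label: ``intercept``, the genetic factor
    ids, the environmental factor names, and ``<g>:<e>`` interaction labels.
    """

    spec: ModelSpec
    coef: pd.Series
    rank: int
    n_samples: int
    sse: float

    @property
    def intercept(self) -> float:
        return float(self.coef["intercept"])

    @property
    def alpha(self) -> pd.Series:
        return self.coef.reindex(list(self.spec.g_factors)).dropna()

    @property
    def beta(self) -> pd.Series:
        return self.coef.reindex(list(self.spec.e_factors)).dropna()

    @property
    def gamma(self) -> pd.DataFrame:
        """Interaction coefficients as a (g_factor x e_factor) table."""
        if not self.spec.uses_interaction:
            return pd.DataFrame(index=list(self.spec.g_factors), columns=list(self.spec.e_factors))
        out = pd.DataFrame(
            [
                [self.coef[f"{g}:{e}"] for e in self.spec.e_factors]
                for g in self.spec.g_factors
            ],
            index=list(self.spec.g_factors),
            columns=list(self.spec.e_factors),
            dtype=float,
        )
        return out

    def to_dict(self) -> dict:
        return {
            "trait": self.spec.trait,
            "pattern": self.spec.pattern,
            "g_factors": list(self.spec.g_factors),
            "e_factors": list(self.spec.e_factors),
            "coefficients": {k: float(v) for k, v in self.coef.items()},
            "rank": int(self.rank),
            "n_samples": int(self.n_samples),
            "sse": float(self.sse),
        }


@dataclass(frozen=True)
class EvalResult:
    """Concordance between observed and model values on one split."""

    pearson_r: float
    rmse: float
    n_samples: int
    split: str = "train"

    def __post_init__(self) -> None:
        if np.isfinite(self.pearson_r) and not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")
        if self.rmse < 0:
            raise ValueError("RMSE must be >= 0")


def build_design_matrix(
    spec: ModelSpec,
    G: GenotypeMatrix,
    env_factors: pd.DataFrame,
    samples: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for ``samples`` (columns ``cultivar, environment``).

    Columns are [1 | x_1..x_m | z_1..z_n | x_h*z_k for all (h, k)] restricted
    to the terms of the pattern; the interaction cell is the product of the
    binary genotype dummy and the numeric environmental factor.
    """
    cult_pos = {c: i for i, c in enumerate(G.cultivars)}
    bad = [c for c in samples["cultivar"].unique() if c not in cult_pos]
    if bad:
        raise KeyError(f"samples reference cultivars absent from genotypes: {bad[:5]}")
    bad_env = [e for e in samples["environment"].unique() if e not in env_factors.index]
    if bad_env:
        raise KeyError(f"samples reference environments without factors: {bad_env[:5]}")

    n = len(samples)
    rows = samples["cultivar"].map(cult_pos).to_numpy()
    cols = [np.ones(n)]
    labels = ["intercept"]
    if spec.uses_g:
        Gx = G.subset_loci(list(spec.g_factors)).values.astype(float)[rows, :]
        cols.append(Gx)
        labels.extend(spec.g_factors)
    if spec.uses_e:
        missing = [e for e in spec.e_factors if e not in env_factors.columns]
        if missing:
            raise KeyError(f"environmental factors not available: {missing}")
        Z = env_factors.loc[samples["environment"], list(spec.e_factors)].to_numpy(dtype=float)
        cols.append(Z)
        labels.extend(spec.e_factors)
    if spec.uses_interaction:
        inter = Gx[:, :, None] * Z[:, None, :]
        cols.append(inter.reshape(n, -1))
        labels.extend(f"{g}:{e}" for g in spec.g_factors for e in spec.e_factors)
    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return X, labels


def fit_ols(X: np.ndarray, y: np.ndarray, labels: list[str], spec: ModelSpec) -> FittedModel:
    """Minimum-norm least-squares fit; warns on rank deficiency."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0 or len(y) == 0:
        raise ValueError("empty design matrix or response")
    if X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    beta, _, rank, _ = lstsq(X, y, lapack_driver="gelsd")
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{X.shape[1]}); minimum-norm solution used",
            stacklevel=2,
        )
    resid = y - X @ beta
    return FittedModel(
        spec=spec,
        coef=pd.Series(beta, index=labels),
        rank=int(rank),
        n_samples=len(y),
        sse=float(resid @ resid),
    )


def fit_model(
    spec: ModelSpec,
    G: GenotypeMatrix,
    env_factors: pd.DataFrame,
    samples: pd.DataFrame,
    y_column: str = "value",
) -> FittedModel:
    """Build the design for ``samples`` and fit by OLS in one step.

    ``samples`` needs columns ``cultivar, environment, <y_column>``; rows
    with a missing response are dropped.
    """
    use = samples.dropna(subset=[y_column]).reset_index(drop=True)
    X, labels = build_design_matrix(spec, G, env_factors, use)
    return fit_ols(X, use[y_column].to_numpy(dtype=float), labels, spec)


def predict(
    model: FittedModel,
    G: GenotypeMatrix,
    env_factors: pd.DataFrame,
    samples: pd.DataFrame,
) -> np.ndarray:
    """Model values for new samples via the same design construction."""
    X, labels = build_design_matrix(model.spec, G, env_factors, samples)
    return X @ model.coef.loc[labels].to_numpy(dtype=float)


def evaluate(observed, predicted, split: str = "train") -> EvalResult:
    """Pearson R and RMSE between observed and model values.

    R is reported as NaN (with a warning) when either vector is constant;
    the RMSE is always computed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    if len(obs) < 3:
        raise ValueError("need >= 3 samples for evaluation")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        warnings.warn("constant vector; Pearson R undefined", stacklevel=2)
        r = np.nan
    else:
        r = float(pearsonr(obs, pred)[0])
    return EvalResult(pearson_r=r, rmse=rmse, n_samples=len(obs), split=split)


def factor_count_scan(
    trait: str,
    G: GenotypeMatrix,
    env_factors: pd.DataFrame,
    train_samples: pd.DataFrame,
    test_samples: pd.DataFrame | None,
    g_factors: list[str],
    e_factors: list[str],
    patterns: tuple[str, ...] = PATTERNS,
    n_g_max: int = 100,
    y_column: str = "value",
) -> pd.DataFrame:
    """Fit every pattern at 1..n_g_max genetic factors and evaluate both splits.

    Genetic factors enter in priority order (prefixes of ``g_factors``); the
    pattern E does not use them, so its rows are constant across n_g. Returns
    a long DataFrame with columns ``pattern, n_g, split, pearson_r, rmse, n``.
    """
    if n_g_max > len(g_factors):
        warnings.warn(
            f"requested up to {n_g_max} genetic factors but only "
            f"{len(g_factors)} available; truncating",
            stacklevel=2,
        )
        n_g_max = len(g_factors)
    if n_g_max < 1:
        raise ValueError("need >= 1 genetic factor for the scan")
    splits = [("train", train_samples)]
    if test_samples is not None:
        splits.append(("test", test_samples))
    rows = []
    for pattern in patterns:
        for n_g in range(1, n_g_max + 1):
            spec = ModelSpec(
                trait,
                pattern,
                g_factors=tuple(g_factors[:n_g]) if "G" in pattern else (),
                e_factors=tuple(e_factors) if "E" in pattern else (),
            )
            fitted = fit_model(spec, G, env_factors, train_samples, y_column)
            for split, samples in splits:
                use = samples.dropna(subset=[y_column]).reset_index(drop=True)
                pred = predict(fitted, G, env_factors, use)
                res = evaluate(use[y_column].to_numpy(dtype=float), pred, split=split)
                rows.append(
                    {
                        "pattern": pattern,
                        "n_g": n_g,
                        "split": split,
                        "pearson_r": res.pearson_r,
                        "rmse": res.rmse,
                        "n": res.n_samples,
                    }
                )
    return pd.DataFrame(rows)
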