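"""Descriptive field-data statistics: trait correlations and the G/E/GxE
ANOVA partition of plant height.

The ANOVA is the classical two-factor decomposition with interaction,
computed with sequential (Type-I) sums of squares in the order cultivar,
environment, cultivar:environment. Field designs are unbalanced and may
contain empty cultivar x environment cells, so each term's degrees of
freedom come from the realized rank increase of the cumulative design
matrix rather than from textbook (a-1)(b-1) arithmetic.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import lstsq
from scipy.stats import f as f_dist, pearsonr

__all__ = ["trait_correlation", "anova_gxe"]


def trait_correlation(
    table: pd.DataFrame,
    trait_a: str,
    trait_b: str,
    env_column: str = "environment",
) -> pd.DataFrame:
    """Per-environment Pearson correlation between two trait columns.

    Rows with a missing value in either trait are dropped per environment;
    fewer than 3 usable pairs in an environment is an error, and a constant
    vector yields NaN with a warning.
    """
    out = []
    for env, sub in table.groupby(env_column, sort=True):
        pair = sub[[trait_a, trait_b]].dropna()
        if len(pair) < 3:
            raise ValueError(
                f"environment {env!r} has {len(pair)} paired values; need >= 3"
            )
        a = pair[trait_a].to_numpy(dtype=float)
        b = pair[trait_b].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"constant trait in {env!r}; correlation undefined", stacklevel=2)
            r, p = np.nan, np.nan
        else:
            r, p = pearsonr(a, b)
        out.append({"environment": env, "r": float(r), "p": float(p), "n": len(pair)})
    return pd.DataFrame(out).set_index("environment")


def _rank_rss(X: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    # one-hot factor blocks are exactly collinear with the intercept, so use
    # the matrix_rank-style cutoff (eps * max(shape)) rather than lstsq's
    # bare-eps default, which can count numerically-zero singular values
    cond = np.finfo(float).eps * max(X.shape)
    beta, _, rank, _ = lstsq(X, y, cond=cond, lapack_driver="gelsd")
    resid = y - X @ beta
    return int(rank), float(resid @ resid)


def anova_gxe(
    records: pd.DataFrame,
    response: str = "height",
    factors: tuple[str, str] = ("cultivar", "environment"),
) -> pd.DataFrame:
    """Sequential two-factor ANOVA with interaction for individual records.

    Parameters
    ----------
    records
        Long table of individual-level measurements with the response and the
        two factor columns.
    response
        Name of the numeric response column (e.g. terminal plant height).
    factors
        (genotype factor, environment factor); sums of squares are added in
        this order, then the interaction, with F tests against the residual
        mean square.

    Returns
    -------
    DataFrame with rows ``<factor_a>, <factor_b>, <a>:<b>, Residuals`` and
    columns ``df, sum_sq, mean_sq, F, p``.
    """
    fa, fb = factors
    df = records.dropna(subset=[response, fa, fb]).reset_index(drop=True)
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    for name in (fa, fb):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")

    A = pd.get_dummies(df[fa].astype(str), dtype=float).to_numpy()
    B = pd.get_dummies(df[fb].astype(str), dtype=float).to_numpy()
    AB = (A[:, :, None] * B[:, None, :]).reshape(n, -1)
    ones = np.ones((n, 1))

    ranks, rsss = [], []
    X = ones
    for block in (A, B, AB):
        X = np.hstack([X, block])
        r, rss = _rank_rss(X, y)
        ranks.append(r)
        rsss.append(rss)

    ss_total = float(((y - y.mean()) ** 2).sum())
    rss_prev = [ss_total] + rsss[:-1]
    rank_prev = [1] + ranks[:-1]
    term_ss = [rp - rc for rp, rc in zip(rss_prev, rsss)]
    term_df = [rc - rp for rp, rc in zip(rank_prev, ranks)]
    resid_df = n - ranks[-1]
    resid_ss = rsss[-1]
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom; need replication")
    ms_resid = resid_ss / resid_df

    rows = []
    labels = [fa, fb, f"{fa}:{fb}"]
    for label, d, ss in zip(labels, term_df, term_ss):
        ms = ss / d if d > 0 else np.nan
        F = ms / ms_resid if d > 0 else np.nan
        p = float(f_dist.sf(F, d, resid_df)) if d > 0 else np.nan
        rows.append({"term": label, "df": d, "sum_sq": ss, "mean_sq": ms, "F": F, "p": p})
    rows.append(
        {
            "term": "Residuals",
            "df": resid_df,
            "sum_sq": resid_ss,
            "mean_sq": ms_resid,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")
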