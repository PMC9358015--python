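"""Heuristic selection of genetic and environmental model factors.

Genetic factors: per-environment association scans are pooled by taking the
top-N loci of each environment (union without duplication), ranking the pool
by the minimum p-value across environments, greedily enforcing a 100 kb
physical spacing per chromosome, and finally walking the resulting priority
list while rejecting loci that are nearly monomorphic (carrier or
non-carrier count < 2) or correlated (|Pearson r| >= 0.5) with an already
selected factor.

Environmental factors: mean temperatures of the ten 10-day windows after
sowing (T0 ... T90) are considered in chronological order; a window enters
the model only if its absolute correlation with every window already in the
model, computed across the training environments, stays below the threshold.
Sowing day-of-year and field latitude always accompany the temperature
windows as day-length proxies.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EnvironmentSpec, GenotypeMatrix

__all__ = [
    "WINDOW_NAMES",
    "period_temperatures",
    "environment_factor_table",
    "select_env_factors",
    "accumulate_top_n",
    "build_priority_list",
    "select_g_factors",
]

WINDOW_NAMES = tuple(f"T{10 * w}" for w in range(10))


def period_temperatures(env: EnvironmentSpec) -> pd.Series:
    """Mean temperature of each 10-day window after sowing (T0 ... T90).

    Window w covers days [10w, 10w + 9] from sowing; a series shorter than
    100 days cannot fill all ten windows and raises an error naming the
    missing ones.
    """
    t = env.temperatures
    if len(t) < 100:
        missing = [WINDOW_NAMES[w] for w in range(10) if len(t) < 10 * w + 10]
        raise ValueError(
            f"temperature series for {env.name!r} has {len(t)} days (< 100); "
            f"missing windows: {missing}"
        )
    means = [float(t[10 * w : 10 * w + 10].mean()) for w in range(10)]
    return pd.Series(means, index=list(WINDOW_NAMES), name=env.name)


def environment_factor_table(environments: Sequence[EnvironmentSpec]) -> pd.DataFrame:
    """All candidate environmental factors per environment.

    Columns are T0 ... T90 plus ``sowing_doy`` (days from the beginning of
    the year) and ``latitude`` (degrees N); rows are environment names.
    """
    rows = []
    for env in environments:
        s = period_temperatures(env)
        s["sowing_doy"] = float(env.sowing_doy)
        s["latitude"] = float(env.latitude)
        rows.append(s)
    return pd.DataFrame(rows)


def select_env_factors(
    period_temps: pd.DataFrame,
    corr_threshold: float = 0.5,
) -> list[str]:
    """Greedy chronological selection of temperature windows.

    ``period_temps`` is an environments x windows table (columns T0 ... T90,
    extra columns ignored). T0 always enters first; each later window enters
    only if its absolute Pearson correlation with every window already
    selected, across the training environments, is below ``corr_threshold``.
    Windows with zero variance across environments carry no usable signal and
    are treated as blocked.
    """
    if len(period_temps) < 3:
        raise ValueError("need >= 3 training environments to correlate windows")
    cols = [c for c in WINDOW_NAMES if c in period_temps.columns]
    selected = [cols[0]]
    for cand in cols[1:]:
        x = period_temps[cand].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        ok = True
        for s in selected:
            z = period_temps[s].to_numpy(dtype=float)
            if np.ptp(z) == 0:
                ok = False
                break
            r = np.corrcoef(x, z)[0, 1]
            if not np.isfinite(r) or abs(r) >= corr_threshold:
                ok = False
                break
        if ok:
            selected.append(cand)
    return selected


def accumulate_top_n(
    gwas_results: Mapping[str, pd.DataFrame],
    n: int = 100,
) -> set[str]:
    """Union of each environment's top-N loci by ascending p-value.

    Ties in p are broken by (chromosome, position) so the candidate set is
    deterministic. Loci with missing p (skipped in the scan) never qualify.
    """
    if not gwas_results:
        raise ValueError("need results from >= 1 environment")
    out: set[str] = set()
    for env, res in gwas_results.items():
        usable = res.dropna(subset=["p"]).sort_values(
            ["p", "chrom", "pos"], kind="mergesort"
        )
        out.update(usable.index[:n])
    return out


def build_priority_list(
    gwas_results: Mapping[str, pd.DataFrame],
    candidates: set[str] | None = None,
    distance_bp: int = 100_000,
) -> pd.DataFrame:
    """Rank candidate loci by min-p across environments with 100 kb spacing.

    Candidates are sorted by the minimum of their per-environment p-values
    (ties broken by ascending chromosome, position) and admitted greedily: a
    locus is discarded iff its distance to some already-retained locus on the
    same chromosome is strictly less than ``distance_bp``.

    Returns a DataFrame ordered by rank with columns ``chrom, pos, min_p,
    min_q`` plus one ``p_<env>`` column per environment.
    """
    envs = list(gwas_results)
    if not envs:
        raise ValueError("need results from >= 1 environment")
    any_res = gwas_results[envs[0]]
    pmat = pd.DataFrame({f"p_{e}": gwas_results[e]["p"] for e in envs})
    qmat = pd.DataFrame({e: gwas_results[e]["q"] for e in envs})
    if candidates is not None:
        keep = [l for l in pmat.index if l in candidates]
        pmat = pmat.loc[keep]
        qmat = qmat.loc[keep]
    pmat = pmat.dropna(how="all")
    info = any_res.loc[pmat.index, ["chrom", "pos"]]

    tbl = info.copy()
    tbl["min_p"] = pmat.min(axis=1)
    tbl["min_q"] = qmat.loc[pmat.index].min(axis=1)
    tbl = pd.concat([tbl, pmat], axis=1)
    tbl = tbl.sort_values(["min_p", "chrom", "pos"], kind="mergesort")

    retained_pos: dict[str, list[int]] = {}
    keep_rows = []
    for locus, row in tbl.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        near = any(abs(pos - q) < distance_bp for q in retained_pos.get(chrom, ()))
        if near:
            continue
        retained_pos.setdefault(chrom, []).append(pos)
        keep_rows.append(locus)
    out = tbl.loc[keep_rows].copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def select_g_factors(
    priority: pd.DataFrame,
    G: GenotypeMatrix,
    max_n: int,
    corr_threshold: float = 0.5,
    min_count: int = 2,
    n_environments: int = 1,
    sample_index: pd.DataFrame | None = None,
) -> list[str]:
    """Walk the priority list and keep the first ``max_n`` admissible loci.

    A locus is admissible when (a) at least ``min_count`` cultivars carry the
    genotype and at least ``min_count`` do not, and (b) the absolute Pearson
    correlation of its genotype profile with every already-selected factor is
    below ``corr_threshold``. Profiles are the genotype dummies of all
    cultivars replicated over the training environments; when every
    environment covers the same cultivars (``sample_index=None``) this equals
    the correlation over cultivars, so ``n_environments`` only matters for
    an explicitly supplied uneven ``sample_index`` (columns ``cultivar``).
    """
    if priority.empty:
        raise ValueError("priority list is empty")

    def profile(locus: str) -> np.ndarray:
        x = G.column(locus).astype(float)
        if sample_index is not None:
            lut = dict(zip(G.cultivars, x))
            return np.array([lut[c] for c in sample_index["cultivar"]], dtype=float)
        return np.tile(x, max(int(n_environments), 1))

    selected: list[str] = []
    profiles: list[np.ndarray] = []
    for locus in priority.index:
        carriers = int(G.column(locus).sum())
        if carriers < min_count or G.n_cultivars - carriers < min_count:
            continue
        v = profile(locus)
        if np.ptp(v) == 0:
            continue
        admissible = True
        for u in profiles:
            r = np.corrcoef(v, u)[0, 1]
            if not np.isfinite(r) or abs(r) >= corr_threshold:
                admissible = False
                break
        if admissible:
            selected.append(locus)
            profiles.append(v)
        if len(selected) >= max_n:
            break
    if not selected:
        raise ValueError("no locus survives the carrier-count and correlation filters")
    return selected
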