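"""Synthetic multi-environment trial generator with a known ground truth.

The generator emulates the structure of a multi-latitude, multi-sowing-time
soybean trial: inbred cultivars genotyped at binary homozygous variant
dummies on 20 chromosomes, grown in field x year x sowing-time environments,
with weekly S-shaped height trajectories and trait values produced by a
linear G + E + GxE model plus Gaussian replicate noise. Because the
generative coefficients (TruthModel) are known exactly, every downstream
stage — curve fitting, association scans, factor selection, regression — can
be tested for recovery without any external data.

Default desk-scale scenario: 93 cultivars x 2,000 loci, two training fields
(MF at 31.83 N, TF at 38.46 N) over 2018-2019 giving 8 training
environments, and a 2020-style test year adding a third field (KF at
35.33 N) for 9 test environments observed on a 32-cultivar subset.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EnvironmentSpec, GenotypeMatrix, TraitTable, locus_id
from .growth import GrowthSeries, LogisticParams, logistic_height
from .selection import environment_factor_table

__all__ = [
    "TempModel",
    "FieldSite",
    "SimScenario",
    "TruthModel",
    "StudyData",
    "default_scenario",
    "default_truths",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_traits",
    "simulate_growth_series",
    "simulate_study",
]


@dataclass(frozen=True)
class TempModel:
    """Sinusoidal annual temperature model with daily noise.

    ``temp(doy) = mean + amplitude * cos(2 pi (doy - phase_doy) / 365.25)
    + lat_gradient * (reference_latitude - latitude) + year offset + noise``.

    ``phase_doy`` is the day-of-year of peak temperature; the latitude
    gradient makes southern fields warmer; the per-(field, year) offset
    (sd ``year_sd``) injects year-to-year anomalies such as a cold June.
    """

    mean: float = 22.0
    amplitude: float = 8.0
    phase_doy: float = 213.0  # around early August, typical for Japan
    noise_sd: float = 1.5
    lat_gradient: float = 0.55
    year_sd: float = 0.8
    reference_latitude: float = 35.0


@dataclass(frozen=True)
class FieldSite:
    """A trial field: name, latitude (deg N), and sowing days-of-year per year."""

    name: str
    latitude: float
    sowings: Mapping[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [0, 90]")
        object.__setattr__(
            self, "sowings", {int(y): tuple(int(d) for d in ds) for y, ds in self.sowings.items()}
        )


@dataclass(frozen=True)
class SimScenario:
    """Shape and noise parameters of a simulated trial."""

    n_cultivars: int = 93
    n_loci: int = 2000
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    fields: tuple[FieldSite, ...] = ()
    test_fields: tuple[FieldSite, ...] = ()
    n_test_cultivars: int = 32
    temp_model: TempModel = field(default_factory=TempModel)
    obs_weeks: int = 12
    height_noise_sd: float = 2.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_cultivars < 4:
            raise ValueError("need >= 4 cultivars")
        if self.n_loci < 2:
            raise ValueError("need >= 2 loci")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")

    @property
    def years(self) -> tuple[int, ...]:
        ys: set[int] = set()
        for f in self.fields + self.test_fields:
            ys.update(f.sowings)
        return tuple(sorted(ys))

    def cultivar_ids(self) -> list[str]:
        return [f"cv{i:03d}" for i in range(1, self.n_cultivars + 1)]

    def environment_designs(self, split: str) -> list[tuple[FieldSite, int, int]]:
        """(field, year, sowing_doy) triples for one split ('train'/'test')."""
        sites = self.fields if split == "train" else self.test_fields
        out = []
        for site in sites:
            for year in sorted(site.sowings):
                for doy in site.sowings[year]:
                    out.append((site, year, doy))
        return out


def default_scenario() -> SimScenario:
    """The reference desk-scale scenario mirroring a 2-field, 3-year trial."""
    mf = FieldSite("MF", 31.83, {2018: (205,), 2019: (163, 204, 228)})
    tf = FieldSite("TF", 38.46, {2018: (157,), 2019: (153, 183, 211)})
    mf20 = FieldSite("MF", 31.83, {2020: (154, 189, 217)})
    tf20 = FieldSite("TF", 38.46, {2020: (155, 184, 212)})
    kf20 = FieldSite("KF", 35.33, {2020: (161, 191, 217)})
    return SimScenario(fields=(mf, tf), test_fields=(mf20, tf20, kf20))


@dataclass(frozen=True)
class TruthModel:
    """Generative coefficients of the linear G + E + GxE trait model."""

    causal_loci: tuple[str, ...]
    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    gamma: Mapping[tuple[str, str], float]
    intercept: float
    noise_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "causal_loci", tuple(self.causal_loci))
        extra = set(self.alpha) - set(self.causal_loci)
        if extra:
            raise ValueError(f"alpha refers to non-causal loci: {sorted(extra)[:5]}")
        bad = {g for g, _ in self.gamma} - set(self.causal_loci)
        if bad:
            raise ValueError(f"gamma refers to non-causal loci: {sorted(bad)[:5]}")


def simulate_genotypes(scenario: SimScenario, seed: int) -> GenotypeMatrix:
    """Binary homozygous genotype dummies with unique chromosomal positions.

    Loci are spread as evenly as possible over the chromosomes; positions are
    drawn without replacement per chromosome (1-based). Each locus draws a
    carrier frequency uniformly in ``maf_range`` and assigns
    ``round(freq * n_cultivars)`` carriers at random.
    """
    rng = np.random.default_rng(seed)
    n, m = scenario.n_cultivars, scenario.n_loci
    per_chrom = np.full(scenario.n_chromosomes, m // scenario.n_chromosomes)
    per_chrom[: m % scenario.n_chromosomes] += 1
    if (per_chrom > scenario.chrom_length_bp).any():
        raise ValueError("more loci per chromosome than representable unique positions")

    chroms, positions = [], []
    for ci, k in enumerate(per_chrom, start=1):
        name = f"chr{ci:02d}"
        pos = np.sort(rng.choice(scenario.chrom_length_bp, size=int(k), replace=False) + 1)
        chroms.extend([name] * int(k))
        positions.extend(pos.tolist())

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    impact = rng.choice(["MODERATE", "HIGH"], size=m, p=[0.8, 0.2])

    values = np.zeros((n, m), dtype=np.int8)
    freqs = rng.uniform(scenario.maf_range[0], scenario.maf_range[1], size=m)
    for j in range(m):
        k = int(np.clip(round(freqs[j] * n), 0, n))
        carriers = rng.choice(n, size=k, replace=False)
        values[carriers, j] = 1

    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "impact": impact,
        },
        index=[locus_id(c, p) for c, p in zip(chroms, positions)],
    )
    return GenotypeMatrix(values, loci, scenario.cultivar_ids())


def simulate_environment(
    field_name: str,
    latitude: float,
    year: int,
    sowing_doy: int,
    temp_model: TempModel,
    seed: int,
    n_days: int = 150,
) -> EnvironmentSpec:
    """Daily temperature series from sowing for one environment."""
    if not 1 <= sowing_doy <= 365:
        raise ValueError(f"sowing_doy {sowing_doy} outside [1, 365]")
    rng = np.random.default_rng(seed)
    year_offset = rng.normal(0.0, temp_model.year_sd) if temp_model.year_sd > 0 else 0.0
    doy = sowing_doy + np.arange(n_days)
    seasonal = temp_model.amplitude * np.cos(
        2.0 * np.pi * (doy - temp_model.phase_doy) / 365.25
    )
    lat_term = temp_model.lat_gradient * (temp_model.reference_latitude - latitude)
    noise = rng.normal(0.0, temp_model.noise_sd, size=n_days) if temp_model.noise_sd > 0 else 0.0
    temps = temp_model.mean + lat_term + year_offset + seasonal + noise
    name = f"{field_name}-{year}-{sowing_doy:03d}"
    return EnvironmentSpec(
        name=name,
        field=field_name,
        latitude=latitude,
        year=year,
        sowing_doy=sowing_doy,
        temperatures=np.asarray(temps, dtype=float),
    )


def trait_means(
    genotypes: GenotypeMatrix,
    env_factors: pd.DataFrame,
    truth: TruthModel,
) -> pd.DataFrame:
    """Noise-free model value per cultivar x environment (rows x columns)."""
    for (g, e) in truth.gamma:
        if e not in env_factors.columns:
            raise KeyError(f"gamma references undefined environmental factor {e!r}")
    for e in truth.beta:
        if e not in env_factors.columns:
            raise KeyError(f"beta references undefined environmental factor {e!r}")
    for g in truth.causal_loci:
        if g not in genotypes.locus_ids:
            raise KeyError(f"causal locus {g!r} absent from genotypes")

    n_env = len(env_factors)
    g_part = np.zeros(genotypes.n_cultivars)
    for g, a in truth.alpha.items():
        g_part = g_part + a * genotypes.column(g)
    e_part = np.zeros(n_env)
    for e, b in truth.beta.items():
        e_part = e_part + b * env_factors[e].to_numpy(dtype=float)
    mean = truth.intercept + g_part[:, None] + e_part[None, :]
    for (g, e), c in truth.gamma.items():
        mean = mean + c * np.outer(
            genotypes.column(g), env_factors[e].to_numpy(dtype=float)
        )
    return pd.DataFrame(mean, index=genotypes.cultivars, columns=env_factors.index)


def simulate_traits(
    genotypes: GenotypeMatrix,
    environments: Sequence[EnvironmentSpec],
    truth: TruthModel,
    n_replicates: int = 1,
    trait: str = "trait",
) -> TraitTable:
    """Replicate-level trait values from the generative linear model.

    Each replicate draws ``model mean + N(0, noise_sd)``; the returned
    TraitTable exposes the replicate-averaged view via ``.averaged()``.
    Deterministic given ``truth.seed``.
    """
    envf = environment_factor_table(environments)
    mean = trait_means(genotypes, envf, truth)
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(
        0.0, truth.noise_sd, size=(genotypes.n_cultivars, len(envf), n_replicates)
    ) if truth.noise_sd > 0 else np.zeros((genotypes.n_cultivars, len(envf), n_replicates))
    rows = []
    for i, cv in enumerate(genotypes.cultivars):
        for j, env in enumerate(envf.index):
            for rep in range(n_replicates):
                rows.append(
                    {
                        "cultivar": cv,
                        "environment": env,
                        "replicate": f"rep{rep + 1}",
                        "value": mean.iat[i, j] + noise[i, j, rep],
                    }
                )
    return TraitTable(trait, pd.DataFrame(rows))


def simulate_growth_series(
    K: float,
    r: float,
    y0: float,
    obs_weeks: int,
    height_noise_sd: float,
    seed,
    individual: str = "",
    cultivar: str = "",
    environment: str = "",
) -> GrowthSeries:
    """Weekly (day, height) points on a logistic curve plus truncated noise.

    Observations run from day 0 (sowing, height 0 on the curve) to week
    ``obs_weeks``; negative noisy heights are truncated at 0. ``seed`` may be
    an int or an existing Generator (for bulk generation).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = LogisticParams(K=K, r=r, y0=y0)
    days = 7.0 * np.arange(obs_weeks + 1)
    heights = logistic_height(days, params)
    if height_noise_sd > 0:
        heights = heights + rng.normal(0.0, height_noise_sd, size=len(days))
    heights = np.clip(heights, 0.0, None)
    return GrowthSeries(
        days=days,
        heights=heights,
        individual=individual,
        cultivar=cultivar,
        environment=environment,
    )


# ---------------------------------------------------------------------------
# whole-study assembly


def default_truths(genotypes: GenotypeMatrix, seed: int = 0) -> dict[str, TruthModel]:
    """Ground-truth coefficient sets for the three traits FT, K and r.

    Causal loci are drawn from intermediate-frequency loci; the three traits
    share part of their causal architecture (a major locus influencing both
    height and rate), as major maturity and stem-termination loci do in real
    trials. Effect magnitudes put the G, E and GxE contributions on the same
    order as the replicate noise so that recovery is non-trivial.
    """
    rng = np.random.default_rng(seed)
    counts = genotypes.carrier_counts().to_numpy()
    n = genotypes.n_cultivars
    eligible = np.flatnonzero((counts >= 0.2 * n) & (counts <= 0.45 * n))
    if len(eligible) < 8:
        eligible = np.arange(genotypes.n_loci)
    pool = rng.choice(eligible, size=8, replace=False)
    ids = [genotypes.locus_ids[i] for i in pool]

    ft_loci = tuple(ids[:5])
    k_loci = tuple(ids[2:7])
    r_loci = tuple(ids[4:8] + ids[:1])

    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    ft = TruthModel(
        causal_loci=ft_loci,
        alpha=dict(zip(ft_loci, [8.0, -6.0, 5.0, -4.0, 3.0])),
        beta={"T0": -0.8, "T30": -0.5, "sowing_doy": -0.05, "latitude": 1.2},
        gamma={
            (ft_loci[0], "T0"): -0.45,
            (ft_loci[1], "latitude"): 0.6,
            (ft_loci[2], "T30"): 0.35,
        },
        intercept=45.0,
        noise_sd=2.0,
        seed=int(seeds[0]),
    )
    k = TruthModel(
        causal_loci=k_loci,
        alpha=dict(zip(k_loci, [15.0, -12.0, 10.0, -8.0, 6.0])),
        beta={"T0": 3.0, "T30": 2.0, "sowing_doy": -0.3, "latitude": -4.0},
        gamma={
            (k_loci[0], "T0"): -1.2,
            (k_loci[0], "latitude"): 1.5,
            (k_loci[1], "T30"): 0.9,
        },
        intercept=120.0,
        noise_sd=6.0,
        seed=int(seeds[1]),
    )
    r = TruthModel(
        causal_loci=r_loci,
        alpha=dict(zip(r_loci, [0.020, -0.015, 0.010, -0.008, 0.006])),
        beta={"T0": 0.002, "T30": 0.001, "sowing_doy": -5e-5, "latitude": -5e-4},
        gamma={
            (r_loci[0], "T0"): -6e-4,
            (r_loci[1], "latitude"): 8e-4,
        },
        intercept=0.11,
        noise_sd=0.006,
        seed=int(seeds[2]),
    )
    return {"FT": ft, "K": k, "r": r}


@dataclass
class StudyData:
    """Everything one simulated trial produces, ground truth included."""

    scenario: SimScenario
    genotypes: GenotypeMatrix
    environments: dict[str, EnvironmentSpec]
    train_envs: list[str]
    test_envs: list[str]
    truths: dict[str, TruthModel]
    traits: dict[str, TraitTable]  # FT observed; K, r latent per-replicate truth
    growth: pd.DataFrame  # individual, cultivar, environment, replicate, day, height

    def test_cultivars(self) -> list[str]:
        return self.genotypes.cultivars[: self.scenario.n_test_cultivars]

    def pheno_wide(self) -> pd.DataFrame:
        """Wide phenotype table: one row per individual with FT, weekly
        heights and terminal height."""
        ft = self.traits["FT"].records.set_index(["cultivar", "environment", "replicate"])[
            "value"
        ]
        heights = self.growth.pivot_table(
            index=["cultivar", "environment", "replicate"],
            columns="day",
            values="height",
        )
        heights.columns = [f"height_d{int(d):03d}" for d in heights.columns]
        out = heights.copy()
        out.insert(0, "FT", ft.reindex(out.index))
        out["terminal_height"] = heights.max(axis=1)
        return out.reset_index()


def simulate_study(
    scenario: SimScenario | None = None,
    truths: dict[str, TruthModel] | None = None,
    seed: int = 0,
) -> StudyData:
    """Generate a full study: genotypes, environments, traits and growth.

    All randomness derives from ``seed`` through a fixed SeedSequence spawn
    order (genotypes, environments, truths, growth), so identical calls are
    bit-reproducible.
    """
    scenario = scenario or default_scenario()
    ss = np.random.SeedSequence(seed)
    s_geno, s_env, s_truth, s_growth = (int(x) for x in ss.generate_state(4) % (2**31))

    genotypes = simulate_genotypes(scenario, s_geno)
    if truths is None:
        truths = default_truths(genotypes, s_truth)

    environments: dict[str, EnvironmentSpec] = {}
    train_envs: list[str] = []
    test_envs: list[str] = []
    env_seed_rng = np.random.default_rng(s_env)
    for split, bucket in (("train", train_envs), ("test", test_envs)):
        for site, year, doy in scenario.environment_designs(split):
            env = simulate_environment(
                site.name,
                site.latitude,
                year,
                doy,
                scenario.temp_model,
                seed=int(env_seed_rng.integers(2**31)),
            )
            environments[env.name] = env
            bucket.append(env.name)

    env_list = [environments[e] for e in train_envs + test_envs]
    test_cultivars = set(scenario.cultivar_ids()[: scenario.n_test_cultivars])

    def restrict(table: TraitTable) -> TraitTable:
        rec = table.records
        keep = rec["environment"].isin(train_envs) | rec["cultivar"].isin(test_cultivars)
        return TraitTable(table.trait, rec[keep].reset_index(drop=True))

    traits = {
        name: restrict(
            simulate_traits(
                genotypes, env_list, truth, n_replicates=scenario.n_replicates, trait=name
            )
        )
        for name, truth in truths.items()
    }

    # growth trajectories realize the per-replicate latent (K, r) values
    growth_rng = np.random.default_rng(s_growth)
    k_rec = traits["K"].records.set_index(["cultivar", "environment", "replicate"])["value"]
    r_rec = traits["r"].records.set_index(["cultivar", "environment", "replicate"])["value"]
    rows = []
    for key in k_rec.index:
        cv, env, rep = key
        K_i = float(max(k_rec[key], 20.0))  # keep curves biologically sensible
        r_i = float(np.clip(r_rec[key], 0.02, 1.0))
        series = simulate_growth_series(
            K_i,
            r_i,
            50.0,
            scenario.obs_weeks,
            scenario.height_noise_sd,
            seed=growth_rng,
            individual=f"{cv}.{env}.{rep}",
            cultivar=cv,
            environment=env,
        )
        for d, h in zip(series.days, series.heights):
            rows.append(
                {
                    "individual": series.individual,
                    "cultivar": cv,
                    "environment": env,
                    "replicate": rep,
                    "day": float(d),
                    "height": float(h),
                }
            )
    growth = pd.DataFrame(rows)
    return StudyData(
        scenario=scenario,
        genotypes=genotypes,
        environments=environments,
        train_envs=train_envs,
        test_envs=test_envs,
        truths=truths,
        traits=traits,
        growth=growth,
    )
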