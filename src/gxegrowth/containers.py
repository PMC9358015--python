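"""Core data containers shared across pipeline stages.

The package works on inbred (genetically fixed) cultivars, so genotypes are
binary dummy variables: 1 means the cultivar carries the specific homozygous
variant genotype tracked at that locus, 0 means it does not (heterozygous or
missing calls in input files are coded 0 upstream).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt", "impact")


def locus_id(chrom: str, pos: int) -> str:
    """Canonical locus identifier, e.g. ``chr10_45310798``."""
    return f"{chrom}_{int(pos)}"


@dataclass(frozen=True)
class VariantLocus:
    """A bi-allelic variant position with optional impact annotation."""

    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    impact: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1 (1-based), got {self.pos}")

    @property
    def id(self) -> str:
        return locus_id(self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Binary cultivar x locus genotype dummies with chromosomal coordinates.

    Parameters
    ----------
    values
        ``(n_cultivars, n_loci)`` array with entries in {0, 1}.
    loci
        DataFrame indexed by locus id with columns ``chrom, pos, ref, alt,
        impact``; ``pos`` is 1-based.
    cultivars
        Cultivar identifiers, one per row of ``values``.
    """

    values: np.ndarray
    loci: pd.DataFrame
    cultivars: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("genotype entries must be binary 0/1 dummies")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.cultivars), len(self.loci)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.cultivars)} cultivars x {len(self.loci)} loci"
            )
        missing = [c for c in ("chrom", "pos") if c not in self.loci.columns]
        if missing:
            raise ValueError(f"loci table lacks required columns: {missing}")
        if self.loci.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("loci must be unique by (chromosome, position)")
        self.cultivars = list(self.cultivars)

    @property
    def n_cultivars(self) -> int:
        return len(self.cultivars)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> pd.Index:
        return self.loci.index

    def column(self, locus: str) -> np.ndarray:
        """Genotype dummy vector over cultivars for one locus id."""
        j = self.loci.index.get_loc(locus)
        return self.values[:, j]

    def carrier_counts(self) -> pd.Series:
        """Number of carrier cultivars per locus."""
        return pd.Series(self.values.sum(axis=0), index=self.loci.index, name="carriers")

    def subset_cultivars(self, ids: Sequence[str]) -> "GenotypeMatrix":
        order = {c: i for i, c in enumerate(self.cultivars)}
        unknown = [c for c in ids if c not in order]
        if unknown:
            raise KeyError(f"unknown cultivars: {unknown[:5]}")
        rows = [order[c] for c in ids]
        return GenotypeMatrix(self.values[rows, :].copy(), self.loci, list(ids))

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.loci.index.get_loc(l) for l in loci]
        return GenotypeMatrix(self.values[:, cols].copy(), self.loci.loc[list(loci)], self.cultivars)


@dataclass
class EnvironmentSpec:
    """One field x year x sowing-time environment.

    ``temperatures`` holds daily mean air temperatures (degC) starting at the
    sowing day; ``sowing_doy`` is the sowing time in days from the beginning
    of the year (1-based day-of-year).
    """

    name: str
    field: str
    latitude: float
    year: int
    sowing_doy: int
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [0, 90]")
        if not 1 <= self.sowing_doy <= 365:
            raise ValueError(f"sowing day-of-year {self.sowing_doy} outside [1, 365]")
        self.temperatures = np.asarray(self.temperatures, dtype=float)

    @property
    def n_days(self) -> int:
        return len(self.temperatures)


@dataclass
class TraitTable:
    """Replicate-level trait values with on-demand replicate averaging.

    ``records`` is a long table with columns ``cultivar, environment,
    replicate, value``. Averaging follows the field convention: trait values
    obtained by replication within an environment are arithmetic means.
    """

    trait: str
    records: pd.DataFrame

    REQUIRED = ("cultivar", "environment", "replicate", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"trait records lack columns {missing}")
        self.records = self.records.reset_index(drop=True)

    def averaged(self) -> pd.DataFrame:
        """One row per (cultivar, environment): the mean over replicates."""
        out = (
            self.records.dropna(subset=["value"])
            .groupby(["cultivar", "environment"], sort=True, as_index=False)["value"]
            # plain arithmetic mean (sum/n), bit-identical to numpy's
            .agg(lambda s: float(np.mean(s.to_numpy())))
        )
        return out

    def wide(self) -> pd.DataFrame:
        """Cultivar x environment matrix of replicate-averaged values."""
        return self.averaged().pivot(index="cultivar", columns="environment", values="value")

    def env_series(self, environment: str) -> pd.Series:
        """Replicate-averaged values for one environment, indexed by cultivar."""
        avg = self.averaged()
        sel = avg[avg["environment"] == environment]
        if sel.empty:
            raise KeyError(f"no records for environment {environment!r}")
        return sel.set_index("cultivar")["value"]

    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())
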