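"""File formats: genotype TSV/VCF, phenotype CSV, weather CSV, YAML configs.

All tabular artifacts written by the pipeline carry ``# key: value`` header
comment lines (config hash, seed) and are read back with ``comment='#'``.
Genotype input accepts either the package's TSV layout or a VCF with GT
fields; in both cases the dummy tracks the homozygous ALT genotype of an
inbred line, so heterozygous or missing calls are coded 0.
"""
from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import EnvironmentSpec, GenotypeMatrix, locus_id
from .growth import GrowthSeries

__all__ = [
    "write_table",
    "read_table",
    "write_genotypes_tsv",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_weather_csv",
    "read_weather_csv",
    "write_environments_csv",
    "read_environments",
    "phenotypes_to_long",
    "growth_series_from_long",
    "write_json",
]

_META_PREFIX = "# "


def write_table(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None, sep=",", index=False) -> None:
    """Write a DataFrame with ``# key: value`` header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"{_META_PREFIX}{k}: {v}\n")
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep=",", **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", **kwargs)


def write_json(obj, path, meta: Mapping[str, object] | None = None) -> None:
    payload = {**({"_meta": dict(meta)} if meta else {}), **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(G: GenotypeMatrix, path, meta=None) -> None:
    df = G.loci.copy()
    df.insert(0, "locus", G.loci.index)
    geno = pd.DataFrame(G.values.T, columns=G.cultivars, index=G.loci.index)
    out = pd.concat([df.reset_index(drop=True), geno.reset_index(drop=True)], axis=1)
    write_table(out, path, meta=meta, sep="\t")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df = read_table(path, sep="\t")
    meta_cols = ["locus", "chrom", "pos", "ref", "alt", "impact"]
    missing = [c for c in ("locus", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV lacks columns {missing}")
    cultivars = [c for c in df.columns if c not in meta_cols]
    loci = df[[c for c in meta_cols if c != "locus" and c in df.columns]].copy()
    loci.index = df["locus"]
    values = df[cultivars].to_numpy().T
    return GenotypeMatrix(values, loci, cultivars)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    cultivars = list(vcf.samples)
    chroms, positions, refs, alts, rows = [], [], [], [], []
    for rec in vcf:
        chroms.append(rec.CHROM)
        positions.append(rec.POS)  # cyvcf2 reports 1-based positions
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else "N")
        # gts012: 0=hom-ref 1=het 2=hom-alt 3=missing; homozygote-only coding
        rows.append((np.asarray(rec.gt_types) == 2).astype(np.int8))
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts, "impact": None},
        index=[locus_id(c, p) for c, p in zip(chroms, positions)],
    )
    return GenotypeMatrix(np.vstack(rows).T, loci, cultivars)


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotypes from TSV or VCF (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        return _read_genotypes_vcf(path)
    return _read_genotypes_tsv(path)


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with GT fields; carrier dummy 1 becomes 1/1."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.cultivars),
    ]
    for j, (lid, row) in enumerate(G.loci.iterrows()):
        gts = "\t".join("1/1" if v else "0/0" for v in G.values[:, j])
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{lid}\t{row.get('ref', 'N')}\t"
            f"{row.get('alt', 'N')}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# weather and environments


def _doy_to_date(year: int, doy: int) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)


def write_weather_csv(env: EnvironmentSpec, path, meta=None) -> None:
    start = _doy_to_date(env.year, env.sowing_doy)
    dates = [start + _dt.timedelta(days=i) for i in range(env.n_days)]
    df = pd.DataFrame({"date": [d.isoformat() for d in dates], "temperature": env.temperatures})
    write_table(df, path, meta=meta)


def read_weather_csv(path) -> pd.Series:
    """Daily mean temperatures indexed by ISO date; gaps are an error."""
    df = read_table(path)
    dates = pd.to_datetime(df["date"]).dt.date.tolist()
    for prev, cur in zip(dates, dates[1:]):
        expected = prev + _dt.timedelta(days=1)
        if cur != expected:
            raise ValueError(f"weather series has a gap: missing {expected.isoformat()}")
    return pd.Series(df["temperature"].to_numpy(dtype=float), index=pd.Index(dates, name="date"))


def write_environments_csv(
    environments: Mapping[str, EnvironmentSpec],
    train_envs: Sequence[str],
    test_envs: Sequence[str],
    directory,
    meta=None,
) -> None:
    """Environment metadata CSV plus one weather CSV per environment."""
    directory = Path(directory)
    rows = []
    for name, env in environments.items():
        split = "train" if name in set(train_envs) else "test"
        weather = f"weather_{name}.csv"
        write_weather_csv(env, directory / weather, meta=meta)
        rows.append(
            {
                "environment": name,
                "field": env.field,
                "latitude": env.latitude,
                "year": env.year,
                "sowing_doy": env.sowing_doy,
                "split": split,
                "weather_csv": weather,
            }
        )
    write_table(pd.DataFrame(rows), directory / "environments.csv", meta=meta)


def read_environments(directory) -> tuple[dict[str, EnvironmentSpec], list[str], list[str]]:
    directory = Path(directory)
    df = read_table(directory / "environments.csv")
    envs: dict[str, EnvironmentSpec] = {}
    train, test = [], []
    for _, row in df.iterrows():
        temps = read_weather_csv(directory / row["weather_csv"]).to_numpy()
        env = EnvironmentSpec(
            name=row["environment"],
            field=row["field"],
            latitude=float(row["latitude"]),
            year=int(row["year"]),
            sowing_doy=int(row["sowing_doy"]),
            temperatures=temps,
        )
        envs[env.name] = env
        (train if row["split"] == "train" else test).append(env.name)
    return envs, train, test


# ---------------------------------------------------------------------------
# phenotypes


def phenotypes_to_long(pheno: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide phenotype table (height_dNNN columns) into long
    (individual, cultivar, environment, replicate, day, height) records."""
    height_cols = [c for c in pheno.columns if c.startswith("height_d")]
    if not height_cols:
        raise ValueError("no height_dNNN columns in phenotype table")
    base = pheno[["cultivar", "environment", "replicate"]].copy()
    base["individual"] = (
        pheno["cultivar"].astype(str)
        + "."
        + pheno["environment"].astype(str)
        + "."
        + pheno["replicate"].astype(str)
    )
    long = pheno[height_cols].copy()
    long.columns = [float(c.removeprefix("height_d")) for c in height_cols]
    long = pd.concat([base, long], axis=1).melt(
        id_vars=["individual", "cultivar", "environment", "replicate"],
        var_name="day",
        value_name="height",
    )
    long["day"] = long["day"].astype(float)
    return long.dropna(subset=["height"]).sort_values(
        ["individual", "day"], kind="mergesort"
    ).reset_index(drop=True)


def growth_series_from_long(long: pd.DataFrame) -> list[GrowthSeries]:
    """Group long-format height records into per-individual GrowthSeries."""
    out = []
    for ind, sub in long.groupby("individual", sort=True):
        sub = sub.sort_values("day")
        out.append(
            GrowthSeries(
                days=sub["day"].to_numpy(dtype=float),
                heights=sub["height"].to_numpy(dtype=float),
                individual=str(ind),
                cultivar=str(sub["cultivar"].iloc[0]),
                environment=str(sub["environment"].iloc[0]),
            )
        )
    return out
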