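"""File formats and run configuration.

All tabular interchange is plain UTF-8, comma-delimited, dot-decimal CSV;
configuration and run manifests are YAML.  Treatment labels are the
verbatim strings "Ambient", "pH 7.8", "pH 7.5"; day numbering is 1-based.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .survival import DEFAULT_LEVELS, MortalityDataset

__all__ = [
    "RunConfig",
    "read_mortality_csv",
    "write_mortality_csv",
    "read_morphometrics_csv",
    "write_morphometrics_csv",
    "read_water_csv",
    "write_water_csv",
]

MORTALITY_COLUMNS = MortalityDataset.COLUMNS


def read_mortality_csv(path, max_day: int | None = None,
                       levels=DEFAULT_LEVELS) -> MortalityDataset:
    """Read and validate a per-insert daily mortality CSV.

    Schema: insert_id, year, embryo_ph, larval_ph, day, new_deaths,
    initial_n.  Validation errors report the offending row numbers
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if not len(df):
        import warnings

        warnings.warn(f"{path}: empty mortality file")
        return MortalityDataset(df, max_day=max_day or 1, levels=levels)
    bad = df.index[(df["new_deaths"] < 0) | (df["initial_n"] <= 0) | (df["day"] < 1)]
    if len(bad):
        raise ValueError(f"{path}: invalid counts or days at row(s) {[i + 1 for i in bad]}")
    per = df.groupby("insert_id").agg(dead=("new_deaths", "sum"), n0=("initial_n", "first"))
    over = per[per.dead > per.n0]
    if len(over):
        rows = df.index[df.insert_id.isin(over.index)]
        raise ValueError(
            f"{path}: deaths exceed initial_n for insert(s) {list(over.index)} "
            f"(rows {[i + 1 for i in rows]})"
        )
    return MortalityDataset(df, max_day=max_day, levels=levels)


def write_mortality_csv(dataset: MortalityDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def read_morphometrics_csv(path) -> pd.DataFrame:
    """One row per specimen: label columns plus numeric measurement columns."""
    df = pd.read_csv(path)
    if df.select_dtypes("number").isna().any().any():
        raise ValueError(f"{path}: missing measurement values")
    return df


def write_morphometrics_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_water_csv(path) -> pd.DataFrame:
    """One row per water sample: temperature, salinity, and any of
    ph_free / dic / ta."""
    df = pd.read_csv(path)
    if "temperature" not in df.columns:
        raise ValueError(f"{path}: water CSV needs a temperature column")
    return df


def write_water_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    When ``mortality_csv`` is unset the survival stage simulates data at the
    configured design scale from the published best-fit parameters; an
    explicit path replaces simulation for that stage.
    """

    seed: int = 0
    out_dir: str = "results"
    year: int = 1
    inserts_per_cell: int = 5
    larvae_per_insert: int = 20
    max_day: int = 49
    likelihood_mode: str = "interval"
    n_perm: int = 9999
    salinity: float = 32.0
    n_females: int = 12
    morphometrics_n_per_group: int = 15
    morphometrics_sd: float = 0.12
    mortality_csv: str | None = None
    morphometrics_csv: str | None = None
    water_csv: str | None = None

    def validate(self) -> None:
        for name in ("mortality_csv", "morphometrics_csv", "water_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.year not in (1, 2):
            raise ValueError("year must be 1 or 2")
        if self.likelihood_mode not in ("interval", "daily-binomial"):
            raise ValueError("likelihood_mode must be 'interval' or 'daily-binomial'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
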