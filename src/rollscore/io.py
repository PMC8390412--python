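"""Tabular I/O, schema validation and run configuration.

Input tables are CSV/TSV with a header; a column mapping in the run config
renames arbitrary input columns onto the canonical roles used throughout
the package (person, family, age, phenotype, pgs, sex, array, pc1..pc5,
wave).  Outputs are TSV plus a JSON run record carrying the config echo,
seed and software versions, so any run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InputError, SchemaError
from .rolling import RollingResult, results_to_frame
from .wlmm import WlmmFit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_measures", "write_results", "read_results"]

CANONICAL_REQUIRED = [
    "person", "family", "age", "phenotype", "pgs", "sex",
    "pc1", "pc2", "pc3", "pc4", "pc5",
]
CANONICAL_OPTIONAL = ["array", "wave"]


@dataclass
class RunConfig:
    """Configuration for one end-to-end rolling analysis."""

    age_min: int = 12
    age_max: int = 70
    shoulder: float = 1.5
    decay: float = 25.0
    n_boot: int = 100
    seed: int = 0
    random_slope: bool = False
    method: str = "reml"
    n_jobs: int = 1
    columns: dict = field(default_factory=dict)  # canonical role -> input name

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise InputError(f"empty age range [{self.age_min}, {self.age_max}]")
        if self.n_boot < 0 or self.seed < 0:
            raise InputError("n_boot and seed must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_measures(path, config: RunConfig | None = None) -> pd.DataFrame:
    """Read and validate a long-format measures table.

    Applies the config's column mapping, checks the canonical schema,
    drops (and counts) rows with missing model fields, and rejects
    duplicate (person, wave) rows.
    """
    df = _read_table(path)
    mapping = (config.columns if config else {}) or {}
    missing_src = [src for src in mapping.values() if src not in df.columns]
    if missing_src:
        raise SchemaError(f"mapped columns absent from {path}: {missing_src}")
    df = df.rename(columns={src: role for role, src in mapping.items()})

    absent = [c for c in CANONICAL_REQUIRED if c not in df.columns]
    if absent:
        raise SchemaError(f"measures table is missing required columns: {absent}")

    model_cols = CANONICAL_REQUIRED + [c for c in CANONICAL_OPTIONAL if c in df.columns]
    n0 = len(df)
    df = df.dropna(subset=[c for c in model_cols if c != "wave"]).reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d rows with missing model fields", dropped)
    if len(df) == 0:
        raise SchemaError("no complete rows remain after dropping missing values")

    if "wave" in df.columns:
        dup = df.duplicated(subset=["person", "wave"])
        if dup.any():
            raise SchemaError(
                f"{int(dup.sum())} duplicate (person, wave) rows, e.g. "
                f"{df.loc[dup, ['person', 'wave']].head(3).to_dict('records')}"
            )

    for col in ["age", "phenotype", "pgs", "sex"] + [f"pc{i}" for i in range(1, 6)]:
        df[col] = pd.to_numeric(df[col])
    df.attrs["n_dropped_missing"] = dropped
    return df


def write_results(
    results: list[RollingResult],
    fit: WlmmFit | None,
    outdir,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write rolling results, the pooled fit and a JSON run record.

    Column order is deterministic and floats are written at full precision
    so a round-trip read reproduces the values exactly.
    """
    if not results:
        raise InputError("results list is empty; nothing to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # default float formatting is the shortest exact repr, so a round-trip
    # read reproduces every value bit-for-bit
    frame = results_to_frame(results)
    paths["rolling"] = outdir / "rolling_results.tsv"
    frame.to_csv(paths["rolling"], sep="\t", index=False)

    if fit is not None:
        paths["pooled"] = outdir / "pooled_fit.tsv"
        fit.summary_frame().to_csv(paths["pooled"], sep="\t", index=False)

    record = {
        "package": {"name": "rollscore", "version": __version__},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "config": config.to_dict() if config else None,
        "n_focus_ages": len(results),
        "n_failed": int(sum(r.failed for r in results)),
        "pooled": fit.to_record() if fit is not None else None,
    }
    paths["record"] = outdir / "run_record.json"
    with open(paths["record"], "w") as fh:
        json.dump(record, fh, indent=2, default=float)
    logger.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for ``rolling_results.tsv``."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
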