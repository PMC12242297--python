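"""CSV readers/writers and configuration for the pipeline.

Specimen tables are wide CSV (one row per specimen, ``d15N_<AA>`` /
``d15N_<AA>_sd`` columns), UTF-8, decimal point, header row required.
Calendar years are signed decimals CE (BCE negative); dating windows are
closed intervals. Unknown columns are preserved and passed through.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import SynthConfig
from .trend import TrendConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_specimens",
    "write_table",
    "read_standards",
    "long_to_wide",
    "load_config",
]

REQUIRED_SPECIMEN_COLUMNS = ("specimen_id", "t0", "t1")


class SchemaError(ValueError):
    """A table violates the documented schema (names file/row/column)."""


def read_specimens(path) -> pd.DataFrame:
    """Read and validate a wide specimen table.

    Requires ``specimen_id, t0, t1``; blank cells become missing values
    (never zero); duplicate specimen ids and inverted dating windows are
    schema errors naming the offending rows.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(
            f"{path}: duplicate specimen ids {sorted(dup.unique())} "
            f"(first at row {int(dup.index[0]) + 2})"
        )
    bad = df.index[df["t1"] < df["t0"]]
    if len(bad):
        raise SchemaError(
            f"{path}: dating window with t0 > t1 at row {int(bad[0]) + 2} "
            f"(column t0/t1)"
        )
    return df


def write_table(path, table: pd.DataFrame) -> Path:
    """Write a table as UTF-8 CSV without the index; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_standards(path) -> pd.DataFrame:
    """Read a calibration-standards table: batch, standard, raw, true (+sds)."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("batch", "standard", "raw", "true"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Convert a long AA table (specimen_id, aa, d15N, d15N_sd) to wide."""
    for col in ("specimen_id", "aa", "d15N"):
        if col not in long.columns:
            raise SchemaError(f"long table missing column {col!r}")
    wide = long.pivot(index="specimen_id", columns="aa", values="d15N")
    wide.columns = [f"d15N_{aa}" for aa in wide.columns]
    if "d15N_sd" in long.columns:
        sds = long.pivot(index="specimen_id", columns="aa", values="d15N_sd")
        for aa in sds.columns:
            wide[f"d15N_{aa}_sd"] = sds[aa]
    return wide.reset_index()


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either ``specimens`` points at an existing table or ``synth`` supplies
    a generator config (simulation stage). All stochastic stages draw
    from ``seed``.
    """

    output_dir: str = "isocod_output"
    specimens: str | None = None
    standards: str | None = None
    reference_skeletons: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    responses: list[str] = field(default_factory=lambda: ["D15N_Glx_Phe"])
    model_kind: str = "gam"  # gam | linear
    prediction_grid_size: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = [p for p in (self.specimens, self.standards, self.reference_skeletons) if p]
        if len(paths) != len(set(paths)):
            raise ValueError("input paths must be distinct")
        if self.model_kind not in {"gam", "linear"}:
            raise ValueError("model_kind must be 'gam' or 'linear'")


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    synth = SynthConfig(**_tupled(raw.pop("synth", {})))
    trend = TrendConfig(**raw.pop("trend", {}))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(synth=synth, trend=trend, **raw)


def _tupled(d: dict) -> dict:
    # YAML lists -> tuples where SynthConfig expects pairs
    out = dict(d)
    for key in ("time_range", "length_dist", "trend", "baseline_phe"):
        if key in out and isinstance(out[key], list):
            v = out[key]
            out[key] = (v[0], v[1]) if len(v) == 2 else tuple(v)
    return out
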