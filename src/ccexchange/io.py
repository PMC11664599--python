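"""CSV schemas, fit-report serialization and run configuration.

Two long-format CSV schemas are used throughout:

* time course: ``time_min, fluorescence_au[, replicate]`` with times
  strictly increasing within each replicate;
* plate: ``labelled_id, unlabelled_id, timepoint, replicate,
  fluorescence_au`` with timepoint in {1h, 24h, annealed} and the reserved
  ``unlabelled_id`` value "buffer" for labelled-alone controls.

Readers validate against these schemas and report offending row numbers
(1-based, counting the header as row 1).  Run configurations are YAML files
with a closed key set; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .endpoint import TIMEPOINTS, validate_plate_records
from .errors import ConfigError, SchemaError

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_plate_csv",
    "write_plate_csv",
    "write_fit_report",
    "RunConfig",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)

TIMECOURSE_REQUIRED = ("time_min", "fluorescence_au")


def _csv_row(idx: int) -> int:
    """DataFrame index -> 1-based file row (header is row 1)."""
    return idx + 2


def read_timecourse_csv(path) -> pd.DataFrame:
    """Validated time-course records; a missing replicate column becomes 1."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    for col in ("time_min", "fluorescence_au"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = [_csv_row(i) for i in df.index[vals.isna() & df[col].notna()]]
        if bad or vals.isna().any():
            bad = bad or [_csv_row(i) for i in df.index[vals.isna()]]
            raise SchemaError(f"{path.name}: non-numeric {col!r} in rows {bad}")
        df[col] = vals
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    for rep, grp in df.groupby("replicate"):
        dt = grp["time_min"].diff().dropna()
        bad = [_csv_row(i) for i in dt.index[dt <= 0]]
        if bad:
            raise SchemaError(
                f"{path.name}: times not strictly increasing for replicate "
                f"{rep} at rows {bad}"
            )
    return df


def write_timecourse_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("time_min", "fluorescence_au", "replicate") if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    """Validated long-format plate records."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and set(df.columns) >= {"labelled_id", "unlabelled_id"}:
        log.warning("%s: empty plate file", path.name)
    try:
        return validate_plate_records(df)
    except SchemaError as err:
        raise SchemaError(f"{path.name}: {err}") from err


def write_plate_csv(df: pd.DataFrame, path) -> None:
    validate_plate_records(df).to_csv(path, index=False)


def write_fit_report(fit, path, extra: dict | None = None) -> dict:
    """Serialize a fitted estimator (anything with ``to_dict``) to JSON."""
    report = dict(fit.to_dict() if hasattr(fit, "to_dict") else fit)
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Reproducible run settings; the key set is closed."""

    mechanism: str = "auto"
    seed: int = 0
    noise_cv: float = 0.02
    noise_baseline_sd: float = 5.0
    panel: str = "basis_set"
    ratio: float = 0.1
    threshold: float = 0.5
    timepoints: tuple[str, ...] = TIMEPOINTS
    outdir: str = "out"
    units: dict = field(
        default_factory=lambda: {
            "concentration": "uM",
            "time": "min",
            "temperature": "C",
        }
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    if "timepoints" in raw:
        raw["timepoints"] = tuple(raw["timepoints"])
    cfg = RunConfig(**raw)
    bad_tp = sorted(set(cfg.timepoints) - set(TIMEPOINTS))
    if bad_tp:
        raise ConfigError(f"{path}: unknown timepoints {bad_tp}")
    log.info("effective config: %s", cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
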