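"""Cohort-file ingestion, imputation and run manifests.

Cohorts are delimited text files, one row per patient: covariate columns
(declared continuous or binary), an integer event column and an integer
time column.  Missing covariate values are imputed with the column median
(continuous) or the most frequent observed value (binary), the convention
used for longitudinal-cohort extracts with substantial missingness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CompetingRisksDataset

__all__ = ["CohortSchema", "read_cohort", "impute_missing", "write_manifest"]

logger = logging.getLogger("dthazard")


@dataclass
class CohortSchema:
    """Declared layout of a cohort file."""

    continuous: list[str] = field(default_factory=list)
    binary: list[str] = field(default_factory=list)
    event_col: str = "event"
    time_col: str = "time"
    n_events: int = 3
    horizon: int = 30

    @property
    def covariate_cols(self) -> list[str]:
        return list(self.continuous) + list(self.binary)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "CohortSchema":
        return CohortSchema(**json.loads(text))


class SchemaError(ValueError):
    pass


def impute_missing(table: pd.DataFrame, schema: CohortSchema) -> pd.DataFrame:
    """Fill missing covariates: median (continuous) or mode (binary, ties -> 0)."""
    table = table.copy()
    for col in schema.continuous:
        missing = table[col].isna()
        if missing.all():
            raise SchemaError(f"column '{col}' is entirely missing")
        if missing.any():
            med = table.loc[~missing, col].median()
            table.loc[missing, col] = med
            logger.info("imputed %d missing values in '%s' with median %g",
                        missing.sum(), col, med)
    for col in schema.binary:
        missing = table[col].isna()
        if missing.all():
            raise SchemaError(f"column '{col}' is entirely missing")
        if missing.any():
            counts = table.loc[~missing, col].value_counts()
            top = counts.max()
            # tie on the most frequent value is broken toward 0
            mode = min(v for v, c in counts.items() if c == top)
            table.loc[missing, col] = mode
            logger.info("imputed %d missing values in '%s' with mode %g",
                        missing.sum(), col, mode)
    return table


def read_cohort(path: str | Path, schema: CohortSchema) -> CompetingRisksDataset:
    """Read and type a cohort file, applying the imputation rule."""
    df = pd.read_csv(path)
    needed = schema.covariate_cols + [schema.event_col, schema.time_col]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    extra = [c for c in df.columns if c not in needed]
    if extra:
        logger.warning("ignoring extra columns: %s", extra)
    for col in (schema.event_col, schema.time_col):
        if df[col].isna().any():
            raise SchemaError(f"outcome column '{col}' has missing values")
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise SchemaError(f"column '{col}' is not integer-coercible")
    events = df[schema.event_col].to_numpy(int)
    if events.max(initial=0) > schema.n_events:
        raise SchemaError(
            f"event code {events.max()} exceeds declared n_events={schema.n_events}"
        )
    df = impute_missing(df, schema)
    return CompetingRisksDataset(
        df[schema.covariate_cols].to_numpy(float),
        events,
        df[schema.time_col].to_numpy(int),
        schema.n_events,
        schema.horizon,
        schema.covariate_cols,
    )


def write_manifest(out_dir: str | Path, command: str, config: dict,
                   started: float) -> Path:
    """Write a reproducibility manifest for a CLI run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "version": __version__,
        "wall_time_s": round(time.time() - started, 3),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
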