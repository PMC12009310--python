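"""Table formats and run configuration.

The well-table CSV dialect has the header
``replicate,batch,plate,row,col,condition,role,cell_count,ciliated_count``
with rows as letters A-H and columns as 1-based integers. Unknown extra
columns are preserved. Validation failures carry the 1-based data line
number so a bad row can be found in the file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .simulate import ROWS, WELL_TABLE_COLUMNS, CONTROL_ROLES

VALID_ROLES = set(CONTROL_ROLES) | {"test"}


def read_well_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a well-level screen table.

    Raises ValidationError with the offending line number for malformed
    rows, unknown roles, or ciliated_count > cell_count.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in WELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns {missing} in {path}")
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        if rec.row not in ROWS:
            raise ValidationError(f"row {rec.row!r} not in A-H", line=line)
        if not 1 <= int(rec.col) <= 12:
            raise ValidationError(f"col {rec.col!r} not in 1-12", line=line)
        if rec.role not in VALID_ROLES:
            raise ValidationError(f"unknown role {rec.role!r}", line=line)
        if int(rec.cell_count) < 0 or int(rec.ciliated_count) < 0:
            raise ValidationError("counts must be non-negative", line=line)
        if int(rec.ciliated_count) > int(rec.cell_count):
            raise ValidationError(
                f"ciliated_count {rec.ciliated_count} > cell_count {rec.cell_count}",
                line=line)
    df["col"] = df["col"].astype(int)
    df["cell_count"] = df["cell_count"].astype(int)
    df["ciliated_count"] = df["ciliated_count"].astype(int)
    return df


def write_well_table(df: pd.DataFrame, path: str | Path) -> None:
    extras = [c for c in df.columns if c not in WELL_TABLE_COLUMNS]
    df[WELL_TABLE_COLUMNS + extras].to_csv(path, index=False)


def write_z_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["condition", "replicate", "batch", "plate", "z_cell", "z_cilia"]
    extras = [c for c in df.columns if c not in cols]
    out = df[cols + extras].copy()
    for c in ("z_cell", "z_cilia"):
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline configuration; every field lands in the run manifest."""

    well_table: str | None = None      # None -> simulate
    out_dir: str = "results/run"
    seed: int = 0
    n_batches: int = 2
    plates_per_batch: int = 4
    n_replicates: int = 2
    control_pool: str = "negatives_only"   # or all_controls
    pool_scope: str = "batch"              # or replicate
    mad_scale: float = 1.4826
    cutoff_margin: float = 2.0
    secondary_threshold: float = 2.0
    tertiary_threshold: float = 1.5
    planted_hits: list = field(default_factory=list)  # [condition, delta, mult]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_manifest(self, extra: dict | None = None) -> str:
        doc = {"config": dataclasses.asdict(self)}
        if extra:
            doc.update(extra)
        return json.dumps(doc, indent=2, sort_keys=True, default=str)
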