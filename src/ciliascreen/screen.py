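"""Plate-level screen statistics.

Cilia incidence, robust z-scores against a pooled control distribution,
SSMD screen quality, replicate concordance, per-plate QC against control
z-score windows, and per-batch hit-calling cutoffs.

The robust z of a well is (x - median(pool)) / (c * MAD(pool)) where the
pool is the set of control wells in the well's normalization scope (a
4-plate batch by default) and c = 1.4826 makes the MAD a consistent
estimator of a normal sd, so control z's are N(0,1)-comparable. The pool
may be the negative controls only (default, as in the siRNA screen tiers)
or all cilia controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateControlsError, StructuralError, ZeroVarianceError
from .simulate import NEGATIVE_ROLES, POSITIVE_ROLES

MAD_SCALE_NORMAL = 1.4826

#: roles whose cilia phenotype is informative for pooling/QC (the
#: transfection-efficiency control kills cells and is never pooled).
CILIA_CONTROL_ROLES = NEGATIVE_ROLES + POSITIVE_ROLES

SSMD_BANDS = [
    (5.0, "extremely strong"),
    (3.0, "very strong"),
    (2.0, "strong"),
    (1.0, "fairly strong"),
    (0.0, "moderate/weak"),
]


@dataclass(frozen=True)
class CutoffPair:
    """Per-batch hit thresholds: upper tail on z_cilia, lower tail on z_cell."""

    batch: object
    z_cilia_cutoff: float
    z_cell_cutoff: float


@dataclass(frozen=True)
class PlateQCResult:
    plate: object
    passed: bool
    reasons: tuple[str, ...]


def cilia_incidence(ciliated_count, cell_count):
    """Percentage of cells in a well bearing a single cilium.

    Wells with zero cells get NaN (flagged, excluded downstream).
    Accepts scalars or arrays.
    """
    ciliated = np.asarray(ciliated_count, dtype=float)
    cells = np.asarray(cell_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(cells > 0, 100.0 * ciliated / cells, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def robust_z(x, controls, scale_constant: float = MAD_SCALE_NORMAL, batch=None):
    """Robust z-score of x against a control pool: (x - median) / (c * MAD).

    Raises DegenerateControlsError when the pool has fewer than 4 values or
    zero MAD (an assay failure: the batch must be excluded, not patched).
    ``x`` may be a scalar or an array.
    """
    controls = np.asarray(controls, dtype=float)
    controls = controls[~np.isnan(controls)]
    if controls.size < 4:
        raise DegenerateControlsError(
            f"need >= 4 control values, got {controls.size}", batch=batch
        )
    med = float(np.median(controls))
    mad = float(stats.median_abs_deviation(controls, scale=1.0))
    if mad == 0.0:
        raise DegenerateControlsError(
            f"control pool has zero MAD (batch {batch!r}); batch excluded", batch=batch
        )
    z = (np.asarray(x, dtype=float) - med) / (scale_constant * mad)
    if z.ndim == 0:
        return float(z)
    return z


def ssmd(neg, pos) -> tuple[float, str]:
    """Strictly standardised mean difference between control groups.

    Method-of-moments estimate (mean(neg) - mean(pos)) / sqrt(s²_neg + s²_pos)
    with sample (n-1) variances. Returns (value, effect-size class); the class
    follows the standard banding in which 3 > |SSMD| >= 2 is "strong".
    """
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ZeroVarianceError("need >= 2 values per control group")
    v = neg.var(ddof=1) + pos.var(ddof=1)
    if v == 0.0:
        if neg.mean() == pos.mean():
            return 0.0, "no effect"
        raise ZeroVarianceError("both control groups have zero variance")
    value = float((neg.mean() - pos.mean()) / np.sqrt(v))
    return value, ssmd_class(value)


def ssmd_class(value: float) -> str:
    mag = abs(value)
    for lo, label in SSMD_BANDS:
        if mag >= lo and mag > 0:
            return label
    return "no effect"


def replicate_concordance(z_a, z_b) -> float:
    """Squared Pearson correlation (R²) between matched per-condition z-scores."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.size != z_b.size or z_a.size < 3:
        raise StructuralError("replicates must share >= 3 matched conditions")
    if np.std(z_a) == 0 or np.std(z_b) == 0:
        raise ZeroVarianceError("zero variance in a replicate; R^2 undefined")
    r, _ = stats.pearsonr(z_a, z_b)
    return float(r**2)


def zscore_table(
    wells: pd.DataFrame,
    pool: str = "negatives_only",
    scope: str = "batch",
    scale_constant: float = MAD_SCALE_NORMAL,
) -> pd.DataFrame:
    """Per-well robust z-scores for cell number and cilia incidence.

    For each normalization scope (default: one 4-plate ``batch`` within each
    replicate; alternatively the whole ``replicate``) the control pool is
    assembled from negative-control wells (``negatives_only``) or from all
    cilia controls (``all_controls``), and every well's cell count and cilia
    incidence are scored against the pool median and scaled MAD.

    Wells with zero cells are excluded (undefined incidence) and do not
    appear in the output.
    """
    if pool == "negatives_only":
        pool_roles = set(NEGATIVE_ROLES)
    elif pool == "all_controls":
        pool_roles = set(CILIA_CONTROL_ROLES)
    else:
        raise ValueError(f"unknown control pool {pool!r}")
    if scope == "batch":
        keys = ["replicate", "batch"]
    elif scope == "replicate":
        keys = ["replicate"]
    else:
        raise ValueError(f"unknown pooling scope {scope!r}")

    df = wells.copy()
    df["incidence"] = cilia_incidence(df["ciliated_count"], df["cell_count"])
    df = df[df["cell_count"] > 0]

    parts = []
    for key, grp in df.groupby(keys, sort=True):
        ctrl = grp[grp["role"].isin(pool_roles)]
        if ctrl.empty:
            raise DegenerateControlsError(
                f"no control wells in scope {key!r}", batch=key
            )
        z_cell = robust_z(grp["cell_count"], ctrl["cell_count"],
                          scale_constant, batch=key)
        z_cilia = robust_z(grp["incidence"], ctrl["incidence"],
                           scale_constant, batch=key)
        part = grp[["condition", "role", "replicate", "batch", "plate", "row", "col"]].copy()
        part["z_cell"] = np.asarray(z_cell)
        part["z_cilia"] = np.asarray(z_cilia)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def condition_plate_z(z_wells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-well z's to one record per (condition, replicate, plate).

    Control roles are duplicated in columns 1 and 12 of every plate; their two
    wells are averaged here, which is the granularity at which plate QC and
    hit calling operate. Test conditions have one well per plate, so they
    pass through unchanged.
    """
    return (
        z_wells.groupby(["condition", "role", "replicate", "batch", "plate"],
                        as_index=False)[["z_cell", "z_cilia"]]
        .mean()
    )


def plate_qc(plate_z: pd.DataFrame) -> PlateQCResult:
    """Apply the control-window QC rule to one plate's condition-level z's.

    Pass iff every positive control has z_cilia <= -2 and every negative
    control has -2 <= z_cilia <= +2. Reasons enumerate each violating record.
    """
    plates = plate_z["plate"].unique()
    if len(plates) != 1:
        raise StructuralError(f"plate_qc expects one plate, got {list(plates)}")
    plate = plates[0]
    pos = plate_z[plate_z["role"].isin(POSITIVE_ROLES)]
    neg = plate_z[plate_z["role"].isin(NEGATIVE_ROLES)]
    if pos.empty or neg.empty:
        raise StructuralError(f"plate {plate!r} is missing a control class")

    reasons = []
    for rec in pos.itertuples():
        if not rec.z_cilia <= -2.0:
            reasons.append(
                f"positive control above -2: {rec.condition} "
                f"(replicate {rec.replicate}, z_cilia {rec.z_cilia:.2f})"
            )
    for rec in neg.itertuples():
        if not -2.0 <= rec.z_cilia <= 2.0:
            reasons.append(
                f"negative control outside ±2: {rec.condition} "
                f"(replicate {rec.replicate}, z_cilia {rec.z_cilia:.2f})"
            )
    return PlateQCResult(plate=plate, passed=not reasons, reasons=tuple(reasons))


def qc_report(z_wells: pd.DataFrame) -> pd.DataFrame:
    """Run plate_qc over every (replicate, plate) and tabulate the outcomes."""
    cz = condition_plate_z(z_wells)
    rows = []
    for (rep, plate), grp in cz.groupby(["replicate", "plate"]):
        res = plate_qc(grp)
        rows.append(dict(replicate=rep, plate=plate, passed=res.passed,
                         reasons="; ".join(res.reasons)))
    return pd.DataFrame(rows)


def batch_cutoffs(batch_z: pd.DataFrame, margin: float = 2.0) -> CutoffPair:
    """Hit-calling thresholds for one batch from its negative controls.

    z_cilia_cutoff = median negative-control z_cilia + margin (upper tail);
    z_cell_cutoff  = median negative-control z_cell  - margin (lower tail).
    """
    batches = batch_z["batch"].unique()
    if len(batches) != 1:
        raise StructuralError(f"batch_cutoffs expects one batch, got {list(batches)}")
    neg = batch_z[batch_z["role"].isin(NEGATIVE_ROLES)]
    if neg.empty:
        raise StructuralError(f"batch {batches[0]!r} has no negative controls")
    return CutoffPair(
        batch=batches[0],
        z_cilia_cutoff=float(neg["z_cilia"].median()) + margin,
        z_cell_cutoff=float(neg["z_cell"].median()) - margin,
    )


def all_batch_cutoffs(z_wells: pd.DataFrame, margin: float = 2.0) -> dict:
    """CutoffPair per batch, pooling both replicates' negative controls."""
    return {
        batch: batch_cutoffs(grp, margin=margin)
        for batch, grp in z_wells.groupby("batch")
    }
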