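"""Multi-tier hit selection.

Primary drug screen: per-batch cutoffs on the mean z_cilia of two runs, with
a cytotoxicity exclusion when z_cell falls below the batch cutoff on more
than 2 of the batch's 4 plates. Secondary/tertiary confirmation: z_cilia
difference from the matched control of >= +2 (secondary) or >= 1.5
(tertiary), excluding conditions with z_cell <= -2. Genome-screen
re-analysis: z_cilia >= +2 in every replicate, -2 <= z_cell <= +2 in every
replicate, plus annotation gates (siRNA pool covers all transcripts; a human
orthologue exists).

Every non-hit carries machine-readable reason codes; conditions with missing
required values are reported as ``not_evaluable`` rather than silently
classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError
from .screen import CutoffPair

HIT_TABLE_COLUMNS = ["condition", "tier", "status",
                     "mean_z_cell", "mean_z_cilia", "reasons"]

# reason codes
R_BELOW_CUTOFF = "below_cilia_cutoff"
R_CYTOTOXIC_PLATES = "cytotoxic_gt2_of_4_plates"
R_DELTA_BELOW = "delta_below_threshold"
R_CYTOTOXIC_ZCELL = "cytotoxic_zcell_le_minus2"
R_NOT_BOTH_REPS = "not_significant_in_both_replicates"
R_CELL_CHANGE = "cell_number_change"
R_NOT_ALL_TRANSCRIPTS = "sirna_pool_not_all_transcripts"
R_NO_ORTHOLOGUE = "no_human_orthologue"
R_MEAN_BELOW = "mean_z_cilia_below_2"
R_MISSING = "missing_z_in_required_replicate"


@dataclass(frozen=True)
class AnnotationFlags:
    """Annotation gates for the genome-screen re-analysis; never defaulted true."""

    condition: str
    targets_all_transcripts: bool
    has_human_orthologue: bool


def _hit_row(condition, tier, status, mean_z_cell, mean_z_cilia, reasons):
    return dict(condition=condition, tier=tier, status=status,
                mean_z_cell=mean_z_cell, mean_z_cilia=mean_z_cilia,
                reasons=";".join(reasons))


def call_primary_drug_hits(
    z: pd.DataFrame,
    cutoffs: dict[object, CutoffPair],
    plates_per_batch: int = 4,
) -> pd.DataFrame:
    """Primary drug-screen calls from per-well z records over two runs.

    A test condition is a hit iff its mean z_cilia (over all plates and runs)
    reaches its batch's z_cilia cutoff. It is excluded as cytotoxic iff
    z_cell <= the batch's z_cell cutoff on strictly more than 2 of the
    batch's plates in either run (evaluated per run).
    """
    test = z[z["role"] == "test"]
    rows = []
    for cond, grp in test.groupby("condition", sort=True):
        batches = grp["batch"].unique()
        if len(batches) != 1:
            raise StructuralError(
                f"condition {cond!r} spans batches {list(batches)}"
            )
        cut = cutoffs[batches[0]]
        if grp[["z_cell", "z_cilia"]].isna().any().any():
            rows.append(_hit_row(cond, "primary_drug", "not_evaluable",
                                 np.nan, np.nan, [R_MISSING]))
            continue
        mean_z_cilia = float(grp["z_cilia"].mean())
        mean_z_cell = float(grp["z_cell"].mean())
        reasons = []
        cytotoxic = False
        for _, run in grp.groupby("replicate"):
            n_toxic_plates = int(
                (run.groupby("plate")["z_cell"].min() <= cut.z_cell_cutoff).sum()
            )
            if n_toxic_plates > plates_per_batch // 2:
                cytotoxic = True
        if cytotoxic:
            reasons.append(R_CYTOTOXIC_PLATES)
            status = "excluded_cytotoxic"
        elif mean_z_cilia >= cut.z_cilia_cutoff:
            status = "hit"
        else:
            reasons.append(R_BELOW_CUTOFF)
            status = "not_hit"
        rows.append(_hit_row(cond, "primary_drug", status,
                             mean_z_cell, mean_z_cilia, reasons))
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def call_confirmation_hits(
    z: pd.DataFrame,
    control_reference: dict[str, float],
    threshold: float,
    tier: str = "secondary_drug",
) -> pd.DataFrame:
    """Secondary/tertiary confirmation calls.

    ``z`` holds one or more records per condition (mean taken across them);
    ``control_reference`` maps each condition to the z_cilia of its matched
    (same-knockdown, vehicle-treated) control. Hit iff the z_cilia difference
    from that control reaches ``threshold`` (2 for the secondary tier, 1.5
    for the tertiary) and z_cell > -2; conditions with z_cell <= -2 are
    excluded as cytotoxic.
    """
    rows = []
    for cond, grp in z.groupby("condition", sort=True):
        if cond not in control_reference:
            raise StructuralError(f"no matched control for condition {cond!r}")
        if grp[["z_cell", "z_cilia"]].isna().any().any():
            rows.append(_hit_row(cond, tier, "not_evaluable",
                                 np.nan, np.nan, [R_MISSING]))
            continue
        mean_z_cilia = float(grp["z_cilia"].mean())
        mean_z_cell = float(grp["z_cell"].mean())
        delta = mean_z_cilia - control_reference[cond]
        reasons = []
        if mean_z_cell <= -2.0:
            reasons.append(R_CYTOTOXIC_ZCELL)
            status = "excluded_cytotoxic"
        elif delta >= threshold:
            status = "hit"
        else:
            reasons.append(R_DELTA_BELOW)
            status = "not_hit"
        rows.append(_hit_row(cond, tier, status, mean_z_cell, mean_z_cilia, reasons))
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def genome_refilter(
    z: pd.DataFrame,
    flags: dict[str, AnnotationFlags],
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Re-filter genome-screen z records for ciliogenesis *activators*.

    Candidate iff z_cilia >= +2 in every replicate, -2 <= z_cell <= +2 in
    every replicate, the siRNA pool targets all annotated transcripts, and a
    human orthologue exists. All failed criteria are recorded; annotation
    flags must be supplied for every condition surviving the z criteria.
    """
    rows = []
    for cond, grp in z.groupby("condition", sort=True):
        reps = grp["replicate"].nunique()
        if reps != n_replicates or grp[["z_cell", "z_cilia"]].isna().any().any():
            rows.append(_hit_row(cond, "genome_primary", "not_evaluable",
                                 np.nan, np.nan, [R_MISSING]))
            continue
        per_rep = grp.groupby("replicate")[["z_cell", "z_cilia"]].mean()
        reasons = []
        if not (per_rep["z_cilia"] >= 2.0).all():
            reasons.append(R_NOT_BOTH_REPS)
        if not per_rep["z_cell"].between(-2.0, 2.0).all():
            reasons.append(R_CELL_CHANGE)
        if not reasons:
            # z-criteria survivors must have explicit annotations
            if cond not in flags:
                raise StructuralError(f"missing annotation flags for {cond!r}")
            fl = flags[cond]
            if not fl.targets_all_transcripts:
                reasons.append(R_NOT_ALL_TRANSCRIPTS)
            if not fl.has_human_orthologue:
                reasons.append(R_NO_ORTHOLOGUE)
        elif cond in flags:
            fl = flags[cond]
            if not fl.targets_all_transcripts:
                reasons.append(R_NOT_ALL_TRANSCRIPTS)
            if not fl.has_human_orthologue:
                reasons.append(R_NO_ORTHOLOGUE)
        status = "hit" if not reasons else "not_hit"
        rows.append(_hit_row(cond, "genome_primary", status,
                             float(per_rep["z_cell"].mean()),
                             float(per_rep["z_cilia"].mean()), reasons))
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def average_z_hits(z: pd.DataFrame, tier: str = "genome_secondary") -> pd.DataFrame:
    """Secondary genome-screen calls: hit iff mean z_cilia across replicates >= 2."""
    rows = []
    for cond, grp in z.groupby("condition", sort=True):
        if grp[["z_cell", "z_cilia"]].isna().any().any():
            rows.append(_hit_row(cond, tier, "not_evaluable",
                                 np.nan, np.nan, [R_MISSING]))
            continue
        mean_z_cilia = float(grp["z_cilia"].mean())
        mean_z_cell = float(grp["z_cell"].mean())
        if mean_z_cilia >= 2.0:
            rows.append(_hit_row(cond, tier, "hit", mean_z_cell, mean_z_cilia, []))
        else:
            rows.append(_hit_row(cond, tier, "not_hit",
                                 mean_z_cell, mean_z_cilia, [R_MEAN_BELOW]))
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
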