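"""End-to-end validation experiments on simulated screens.

Each function runs one self-contained experiment — a null screen for z-score
calibration, a screen with planted effects for recall, the screen-quality
statistics — and returns the measured quantities. These are the computations
behind the repository's acceptance checks and the analysis drivers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hits import call_confirmation_hits, call_primary_drug_hits
from .screen import (
    all_batch_cutoffs,
    condition_plate_z,
    qc_report,
    replicate_concordance,
    ssmd,
    zscore_table,
)
from .simulate import (
    NEGATIVE_ROLES,
    POSITIVE_ROLES,
    ROWS,
    PlantedHit,
    SimulationConfig,
    simulate_screen,
)


def null_calibration(seed: int, n_batches: int = 48) -> dict:
    """Simulate a screen with no planted effects and measure z calibration.

    Returns the fraction of test wells with |z_cilia| >= 2 and the plate-QC
    pass rate under the default control effect sizes. Both use z's pooled
    per experimental replicate (the siRNA-tier scope): with ~24*n_batches
    negative wells the MAD is well estimated and the z's are calibrated,
    which is what the normal-approximation expectations for these rates
    assume. (Per-batch 24-well pools inflate both tails by ~50% through MAD
    estimation noise alone.)
    """
    wells = simulate_screen(SimulationConfig(n_batches=n_batches, seed=seed))
    z_rep = zscore_table(wells, scope="replicate")
    test = z_rep[z_rep.role == "test"]
    null_rate = float((test.z_cilia.abs() >= 2).mean())

    qc = qc_report(z_rep)
    return {
        "null_abs_z_ge2_fraction": null_rate,
        "n_test_wells": int(len(test)),
        "plate_qc_pass_rate": float(qc.passed.mean()),
        "n_plates": int(len(qc)),
    }


def planted_condition_ids(n_batches: int, fraction: float, seed: int,
                          ) -> tuple[list[str], list[str]]:
    """Pick a deterministic 'fraction' of test conditions; half become clean
    activators, half activators with a co-planted 80% cell kill."""
    conds = [f"c{b:02d}_{r}{c:02d}"
             for b in range(1, n_batches + 1)
             for r in ROWS for c in range(2, 12)]
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(conds)))
    chosen = list(rng.choice(conds, size=n_plant, replace=False))
    half = n_plant // 2
    return chosen[:half], chosen[half:]


def planted_recovery(seed: int, n_batches: int = 8,
                     incidence_delta: float = 15.0) -> dict:
    """Plant activators (and cytotoxic activators) into a screen and push it
    through the primary -> secondary chain.

    5% of test conditions are planted: half with a +15-point incidence delta,
    half with the same delta plus an 80% cell kill. Measures primary and
    chain recall of the clean activators, the cytotoxic-exclusion rate of the
    killed ones, and the null false-positive rate.
    """
    clean, toxic = planted_condition_ids(n_batches, 0.05, seed)
    hits = ([PlantedHit(c, incidence_delta, 1.0) for c in clean]
            + [PlantedHit(c, incidence_delta, 0.2) for c in toxic])

    wells = simulate_screen(SimulationConfig(
        n_batches=n_batches, seed=seed, planted_hits=hits))
    z = zscore_table(wells, scope="batch")
    cz = condition_plate_z(z)
    cutoffs = all_batch_cutoffs(z)
    primary = call_primary_drug_hits(cz, cutoffs)

    called = set(primary.query("status == 'hit'").condition)
    excluded = set(primary.query("status == 'excluded_cytotoxic'").condition)
    n_null = cz[cz.role == "test"].condition.nunique() - len(clean) - len(toxic)

    # secondary screen: fresh, independently seeded pass over the primary hits
    wells2 = simulate_screen(SimulationConfig(
        n_batches=n_batches, seed=seed + 1, planted_hits=hits))
    z2 = condition_plate_z(zscore_table(wells2, scope="batch"))
    z2 = z2[z2.condition.isin(called)]
    # the matched control for a test condition is its own batch's negative
    # pool, whose z_cilia median is 0 by construction of the robust z
    secondary = call_confirmation_hits(
        z2, {c: 0.0 for c in called}, threshold=2.0, tier="secondary_drug")
    confirmed = set(secondary.query("status == 'hit'").condition)

    return {
        "primary_recall": len(called & set(clean)) / len(clean),
        "chain_recall": len(confirmed & set(clean)) / len(clean),
        "cytotoxic_excluded_fraction": len(excluded & set(toxic)) / len(toxic),
        "null_false_positive_rate": len(called - set(clean) - set(toxic)) / n_null,
        "n_planted_clean": len(clean),
        "n_planted_toxic": len(toxic),
        "n_null_conditions": int(n_null),
    }


def screen_quality(seed: int, n_batches: int = 4) -> dict:
    """SSMD (negatives vs pooled cilia positives) and replicate R² of a
    simulated screen, the two headline screen-quality statistics.

    Replicate concordance is only meaningful when conditions genuinely
    differ, so the screened library is given heterogeneous effects: every
    condition draws a persistent incidence delta from N(0, 4 points).
    """
    rng = np.random.default_rng(seed)
    conds = [f"c{b:02d}_{r}{c:02d}" for b in range(1, n_batches + 1)
             for r in ROWS for c in range(2, 12)]
    library = [PlantedHit(c, float(np.clip(rng.normal(0.0, 4.0), -20, 20)), 1.0)
               for c in conds]
    wells = simulate_screen(SimulationConfig(
        n_batches=n_batches, seed=seed, planted_hits=library))
    wells = wells.assign(
        incidence=100.0 * wells.ciliated_count / wells.cell_count)
    neg = wells[wells.role.isin(NEGATIVE_ROLES)].incidence
    pos = wells[wells.role.isin(POSITIVE_ROLES)].incidence
    ssmd_value, ssmd_band = ssmd(neg, pos)

    z = condition_plate_z(zscore_table(wells, scope="batch"))
    per_rep = z.pivot_table(index=["condition", "plate"], columns="replicate",
                            values=["z_cilia", "z_cell"])
    r2_cilia = replicate_concordance(per_rep[("z_cilia", 1)],
                                     per_rep[("z_cilia", 2)])
    r2_cell = replicate_concordance(per_rep[("z_cell", 1)],
                                    per_rep[("z_cell", 2)])
    return {
        "ssmd": float(ssmd_value),
        "ssmd_class": ssmd_band,
        "replicate_r2_cilia": float(r2_cilia),
        "replicate_r2_cell": float(r2_cell),
    }
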