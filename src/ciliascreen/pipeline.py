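"""End-to-end pipeline: simulate/read -> z-score -> QC -> cutoffs -> call.

Deterministic under (config, seed): two runs from the same configuration
produce byte-identical CSV artifacts, and the written manifest suffices to
re-run the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .errors import CiliaScreenError
from .hits import call_primary_drug_hits
from .io import RunConfig, read_well_table, write_well_table, write_z_table
from .screen import all_batch_cutoffs, condition_plate_z, qc_report, zscore_table
from .simulate import PlantedHit, SimulationConfig, simulate_screen


class QCFailure(CiliaScreenError):
    """Raised when any plate hard-fails quality control."""


def run_pipeline(config: RunConfig, strict_qc: bool = False) -> dict:
    """Execute the full screen analysis chain and write its artifacts.

    Writes wells.csv (if simulated), zscores.csv, qc_report.csv,
    cutoffs.csv, hits_primary.csv and manifest.json under ``config.out_dir``.
    Returns the artifacts in memory. With ``strict_qc`` a failed plate
    aborts with QCFailure (CLI exit status 3).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.well_table is None:
        sim = SimulationConfig(
            n_batches=config.n_batches,
            plates_per_batch=config.plates_per_batch,
            n_replicates=config.n_replicates,
            planted_hits=[PlantedHit(c, d, m) for c, d, m in config.planted_hits],
            seed=config.seed,
        )
        wells = simulate_screen(sim)
        write_well_table(wells, out / "wells.csv")
    else:
        wells = read_well_table(config.well_table)

    z = zscore_table(wells, pool=config.control_pool, scope=config.pool_scope,
                     scale_constant=config.mad_scale)
    write_z_table(z, out / "zscores.csv")

    qc = qc_report(z)
    qc.to_csv(out / "qc_report.csv", index=False)
    if strict_qc and not qc["passed"].all():
        failed = qc.loc[~qc["passed"], "plate"].tolist()
        raise QCFailure(f"plates failed QC: {failed}")

    cutoffs = all_batch_cutoffs(z, margin=config.cutoff_margin)
    pd.DataFrame(
        [dict(batch=c.batch, z_cilia_cutoff=c.z_cilia_cutoff,
              z_cell_cutoff=c.z_cell_cutoff) for c in cutoffs.values()]
    ).to_csv(out / "cutoffs.csv", index=False)

    hit_input = condition_plate_z(z)
    hits = call_primary_drug_hits(hit_input, cutoffs,
                                  plates_per_batch=config.plates_per_batch)
    hits.to_csv(out / "hits_primary.csv", index=False)

    (out / "manifest.json").write_text(
        config.to_manifest({"version": __version__,
                            "n_wells": int(len(wells)),
                            "n_plates_failed_qc": int((~qc["passed"]).sum())})
    )
    return {"wells": wells, "zscores": z, "qc": qc,
            "cutoffs": cutoffs, "hits": hits}
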