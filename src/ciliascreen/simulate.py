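"""Seeded generators of synthetic screen data and phenotype fixtures.

The raw plate/image data behind the published screens are not distributed,
so this module generates well-level tables and small image/profile fixtures
with the statistical structure the downstream analysis assumes:

* 96-well plates with 8 control roles duplicated in columns 1 and 12,
  80 test wells in columns 2-11;
* batches of 4 plates sharing a condition layout, run in 2 experimental
  replicates, so every condition has one well per plate of its batch;
* cell counts from a gamma-Poisson (negative binomial) law with a
  per-plate multiplicative factor; ciliated counts binomial with the
  success probability jittered on the logit scale so it stays in (0, 1);
* control effect sizes anchored to the published screen: the transfection
  control kills 78.4% of cells, and the positive ciliogenesis controls
  drop cilia incidence by 9.8 and 17.1 percentage points.

Everything is deterministic under (config, seed): one RNG stream is derived
per (replicate, plate) from the master seed, so any plate can be regenerated
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ROWS = "ABCDEFGH"

NEGATIVE_ROLES = ("neg_scr", "neg_mlnr", "neg_mock")
POSITIVE_ROLES = ("pos_ift88", "pos_rpgrip1l", "pos_mks1")
CONTROL_ROLES = NEGATIVE_ROLES + POSITIVE_ROLES + ("transfection_plk1", "other")

WELL_TABLE_COLUMNS = [
    "replicate", "batch", "plate", "row", "col",
    "condition", "role", "cell_count", "ciliated_count",
]

#: cell-count multiplier and cilia-incidence delta (percentage points) per role.
#: The Plk1 transfection control reduces cell number by 78.4%; siIft88 and
#: siRpgrip1l reduce cilia incidence by 9.8 and 17.1 points. No magnitude is
#: published for siMks1; -12.0 is a synthetic intermediate value.
DEFAULT_CONTROL_EFFECTS: dict[str, tuple[float, float]] = {
    "neg_scr": (1.0, 0.0),
    "neg_mlnr": (1.0, 0.0),
    "neg_mock": (1.0, 0.0),
    "pos_ift88": (1.0, -9.8),
    "pos_rpgrip1l": (1.0, -17.1),
    "pos_mks1": (1.0, -12.0),
    "transfection_plk1": (1.0 - 0.784, 0.0),
    "other": (1.0, 0.0),
}


@dataclass(frozen=True)
class PlateLayout:
    """96-well layout: control roles duplicated in columns 1 and 12."""

    rows: int = 8
    cols: int = 12
    control_roles: tuple[str, ...] = CONTROL_ROLES

    def __post_init__(self):
        if len(self.control_roles) != self.rows:
            raise ConfigurationError(
                f"need exactly {self.rows} control roles (one per row), "
                f"got {len(self.control_roles)}"
            )

    @property
    def control_wells(self) -> dict[tuple[str, int], str]:
        """Map (row letter, column) -> control role; each role appears twice."""
        out = {}
        for i, role in enumerate(self.control_roles):
            out[(ROWS[i], 1)] = role
            out[(ROWS[i], self.cols)] = role
        return out

    @property
    def test_wells(self) -> list[tuple[str, int]]:
        return [(ROWS[r], c) for r in range(self.rows) for c in range(2, self.cols)]


@dataclass(frozen=True)
class PlantedHit:
    """A test condition given a known effect: incidence delta in percentage
    points and a multiplicative effect on mean cell count."""

    condition: str
    incidence_delta: float = 0.0
    cell_multiplier: float = 1.0


@dataclass
class SimulationConfig:
    """Full parameterization of the generative screen model.

    baseline_incidence is the negative-control fraction of ciliated cells
    (synthetic default 0.40; the source screens do not publish it).
    cell_dispersion is the gamma shape of the gamma-Poisson count law
    (larger = closer to Poisson). plate_sigma is the log-scale sd of the
    per-plate multiplicative factor on mean cell count; well_sigma the
    logit-scale sd of per-well incidence noise.
    """

    n_batches: int = 1
    plates_per_batch: int = 4
    n_replicates: int = 2
    layout: PlateLayout = field(default_factory=PlateLayout)
    baseline_incidence: float = 0.40
    baseline_cells: float = 2000.0
    cell_dispersion: float = 50.0
    plate_sigma: float = 0.05
    well_sigma: float = 0.08
    control_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_EFFECTS)
    )
    planted_hits: list[PlantedHit] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.baseline_incidence < 1.0:
            raise ConfigurationError("baseline_incidence must be in (0, 1)")
        if self.baseline_cells <= 0 or self.cell_dispersion <= 0:
            raise ConfigurationError("baseline_cells and cell_dispersion must be > 0")
        if self.plate_sigma < 0 or self.well_sigma < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        for name, (mult, delta) in self.control_effects.items():
            self._check_effect(name, mult, delta)
        for hit in self.planted_hits:
            self._check_effect(hit.condition, hit.cell_multiplier, hit.incidence_delta)

    def _check_effect(self, name: str, mult: float, delta: float) -> None:
        if mult < 0:
            raise ConfigurationError(f"condition {name!r}: cell multiplier must be >= 0")
        p = self.baseline_incidence + delta / 100.0
        if not 0.0 < p < 1.0:
            raise ConfigurationError(
                f"condition {name!r}: incidence delta {delta} puts the ciliation "
                f"probability at {p:.3f}, outside (0, 1)"
            )


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _plate_rng(seed: int, replicate: int, plate: int) -> np.random.Generator:
    # one independent, reproducible stream per (replicate, plate)
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, plate]))


def simulate_screen(config: SimulationConfig) -> pd.DataFrame:
    """Generate the well-level table for a full multi-batch, multi-replicate screen.

    Returns a DataFrame with columns
    ``replicate,batch,plate,row,col,condition,role,cell_count,ciliated_count``.
    Test conditions are named ``c<batch>_<row><col>`` and occupy the same well
    position on every plate of their batch in every replicate.
    """
    config.validate()
    layout = config.layout
    planted = {h.condition: h for h in config.planted_hits}

    base_logit = _logit(config.baseline_incidence)
    records: list[dict] = []

    for rep in range(1, config.n_replicates + 1):
        for batch in range(1, config.n_batches + 1):
            # shared batch-level factor so plates of a batch co-vary
            batch_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, rep, 10_000 + batch])
            )
            batch_factor = math.exp(config.plate_sigma * batch_rng.standard_normal())
            for p in range(1, config.plates_per_batch + 1):
                plate = (batch - 1) * config.plates_per_batch + p
                rng = _plate_rng(config.seed, rep, plate)
                plate_factor = batch_factor * math.exp(
                    config.plate_sigma * rng.standard_normal()
                )
                wells = []
                for (row, col), role in layout.control_wells.items():
                    mult, delta = config.control_effects[role]
                    wells.append((row, col, role, role, mult, delta))
                for row, col in layout.test_wells:
                    cond = f"c{batch:02d}_{row}{col:02d}"
                    hit = planted.get(cond)
                    mult = hit.cell_multiplier if hit else 1.0
                    delta = hit.incidence_delta if hit else 0.0
                    wells.append((row, col, cond, "test", mult, delta))

                n = len(wells)
                mults = np.array([w[4] for w in wells])
                deltas = np.array([w[5] for w in wells])
                means = config.baseline_cells * mults * plate_factor
                # gamma-Poisson: overdispersed counts, Var = m + m^2/k
                lam = rng.gamma(config.cell_dispersion, means / config.cell_dispersion, size=n)
                cells = rng.poisson(lam)
                target_p = config.baseline_incidence + deltas / 100.0
                logits = np.array([_logit(tp) for tp in target_p])
                logits = logits + config.well_sigma * rng.standard_normal(n)
                probs = _expit(logits)
                ciliated = rng.binomial(cells, probs)

                for (row, col, cond, role, _, _), cc, ci in zip(wells, cells, ciliated):
                    records.append(
                        dict(replicate=rep, batch=batch, plate=plate, row=row,
                             col=col, condition=cond, role=role,
                             cell_count=int(cc), ciliated_count=int(ci))
                    )

    return pd.DataFrame.from_records(records, columns=WELL_TABLE_COLUMNS)


@dataclass(frozen=True)
class ZProfilePair:
    """Paired per-slice intensities for a distal-appendage marker (channel A)
    and an apical-surface marker (channel B), with slice spacing in µm."""

    intensity_a: tuple[float, ...]
    intensity_b: tuple[float, ...]
    spacing_um: float = 0.5

    def __post_init__(self):
        if len(self.intensity_a) != len(self.intensity_b):
            raise ConfigurationError("channels must have the same number of slices")
        if any(v < 0 for v in self.intensity_a + self.intensity_b):
            raise ConfigurationError("intensities must be non-negative")


def _bump(n_slices: int, peak: int, width: float, amp: float) -> tuple[float, ...]:
    idx = np.arange(n_slices)
    return tuple(amp * np.exp(-0.5 * ((idx - peak) / width) ** 2))


def simulate_zprofiles(
    n: int,
    docked_fraction: float,
    n_slices: int = 9,
    spacing_um: float = 0.5,
    seed: int = 0,
) -> tuple[list[ZProfilePair], np.ndarray]:
    """Generate ``n`` unimodal profile pairs with known docking labels.

    Docked pairs place the two channel peaks within 2 slices of each other,
    undocked pairs at an offset of at least 3. The number of docked pairs is
    exactly ``round(n * docked_fraction)``. Returns (pairs, labels) with
    labels a boolean array (True = docked).
    """
    if n_slices < 5:
        raise ConfigurationError("n_slices must be >= 5")
    if not 0.0 <= docked_fraction <= 1.0:
        raise ConfigurationError("docked_fraction must be in [0, 1]")
    n_docked = int(round(n * docked_fraction))
    if n_docked < n and n_slices < 4:
        raise ConfigurationError("n_slices too small to place an undocked offset > 2")

    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=bool)
    labels[:n_docked] = True
    rng.shuffle(labels)

    pairs = []
    for docked in labels:
        if docked:
            offset = int(rng.integers(-2, 3))
        else:
            max_off = n_slices - 1
            mag = int(rng.integers(3, max_off + 1))
            offset = mag if rng.random() < 0.5 else -mag
        lo = max(0, -offset)
        hi = min(n_slices - 1, n_slices - 1 - offset)
        peak_b = int(rng.integers(lo, hi + 1))
        peak_a = peak_b + offset
        amp_a = float(rng.uniform(0.5, 2.0))
        amp_b = float(rng.uniform(0.5, 2.0))
        pairs.append(
            ZProfilePair(
                intensity_a=_bump(n_slices, peak_a, 1.2, amp_a),
                intensity_b=_bump(n_slices, peak_b, 1.2, amp_b),
                spacing_um=spacing_um,
            )
        )
    return pairs, labels


def simulate_fibre_image(
    size: int = 64,
    mode: str = "grating",
    wavelength: float = 8.0,
    angle_deg: float = 0.0,
    contrast: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize a grayscale test image for fibre-texture scoring.

    ``uniform`` emits a constant 0.5 background (plus optional Gaussian
    noise); ``grating`` superimposes a sinusoid of the given wavelength and
    orientation. At contrast 1 the grating spans the full [0, 1] range.
    """
    if mode not in ("uniform", "grating"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if not 0.0 <= contrast <= 1.0:
        raise ConfigurationError("contrast must be in [0, 1]")
    if mode == "grating" and size < 4 * wavelength:
        raise ConfigurationError("image size must be >= 4x wavelength")

    rng = np.random.default_rng(seed)
    img = np.full((size, size), 0.5)
    if mode == "grating":
        theta = math.radians(angle_deg)
        y, x = np.mgrid[0:size, 0:size]
        phase = 2.0 * np.pi * (x * math.cos(theta) + y * math.sin(theta)) / wavelength
        img = img + 0.5 * contrast * np.sin(phase)
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
    return img
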