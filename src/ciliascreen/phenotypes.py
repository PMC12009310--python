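"""Bespoke phenotype quantifications, each a pure function on explicit inputs.

* Basal-body docking: a cell's distal-appendage marker (CEP164) peak slice
  must lie within 2 z-slices (1 µm at 0.5 µm spacing) of the apical-marker
  (ezrin) peak slice.
* Ciliary vesicle trafficking: RAB8A-GFP intensity per ROI is the maximum
  over the z-stack; the image summary is the mean of per-ROI maxima.
* SMO occupancy: total Smoothened-positive area divided by cilia number,
  controlling for variable cilia size.
* Acto-myosin fibre texture: a Gabor filter-bank score (envelope sd 2 px,
  wavelength 8 px, 8 orientations) normalized by regional intensity.
* Tubule morphometry: ellipse area πab from the longest axis a and the
  perpendicular axis b.
* Organoid cysts: ordinal surface-anomaly grades 0-3; stages 2-3 count.
* Dual-luciferase reporter: firefly:Renilla ratios normalized to the
  unstimulated vehicle control.
* Dose-response: per-dose robust z and fold-change versus vehicle wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gabor_kernel

from .errors import ConfigurationError, StructuralError, UnclassifiableProfileError
from .screen import MAD_SCALE_NORMAL, robust_z
from .simulate import ZProfilePair


# ---------------------------------------------------------------- docking

def docking_classify(pair: ZProfilePair, tolerance_slices: int = 2) -> str:
    """Classify one profile pair as ``docked`` or ``undocked``.

    Docked iff the peak slice of channel A is within ``tolerance_slices`` of
    the peak slice of channel B. Argmax ties resolve to the lowest slice
    index (deterministic). An all-zero channel is unclassifiable.
    """
    a = np.asarray(pair.intensity_a, dtype=float)
    b = np.asarray(pair.intensity_b, dtype=float)
    if a.size < 2:
        raise ConfigurationError("need >= 2 slices")
    if not a.any() or not b.any():
        raise UnclassifiableProfileError("all-zero intensity channel")
    offset = abs(int(np.argmax(a)) - int(np.argmax(b)))
    return "docked" if offset <= tolerance_slices else "undocked"


def docking_rate(
    pairs: list[ZProfilePair],
    ciliated: list[bool] | None = None,
    tolerance_slices: int = 2,
) -> dict[str, float]:
    """Percentage of classifiable pairs that are docked.

    With per-pair ciliation flags, also reports the percentage docked but
    lacking an axoneme (docked AND not ciliated). Unclassifiable pairs are
    dropped from the denominator; if every pair is unclassifiable an error
    reports the count.
    """
    if not pairs:
        raise ConfigurationError("empty profile list")
    if ciliated is not None and len(ciliated) != len(pairs):
        raise ConfigurationError("ciliation flags must match the pair list")
    labels, kept = [], []
    n_bad = 0
    for i, p in enumerate(pairs):
        try:
            labels.append(docking_classify(p, tolerance_slices) == "docked")
            kept.append(i)
        except UnclassifiableProfileError:
            n_bad += 1
    if not labels:
        raise UnclassifiableProfileError(f"all {n_bad} pairs unclassifiable")
    labels = np.asarray(labels)
    out = {"pct_docked": 100.0 * labels.mean(), "n": int(labels.size),
           "n_unclassifiable": n_bad}
    if ciliated is not None:
        cil = np.asarray([ciliated[i] for i in kept], dtype=bool)
        out["pct_docked_no_axoneme"] = 100.0 * (labels & ~cil).mean()
    return out


# ------------------------------------------------------- vesicle trafficking

def rab8a_ciliary_intensity(rois: list[list[float]]) -> dict:
    """Per-ROI maximum intensity over the z-stack and the image-level mean.

    Returns the per-ROI maxima, their mean (the image summary used for
    comparisons), and the whole-image mean over every slice value (also
    reported, since either reading of "average intensity" is defensible).
    """
    if not rois or any(len(r) == 0 for r in rois):
        raise ConfigurationError("every ROI needs >= 1 slice value")
    maxima = [float(max(r)) for r in rois]
    all_values = [v for r in rois for v in r]
    return {
        "roi_maxima": maxima,
        "mean_of_maxima": float(np.mean(maxima)),
        "whole_image_mean": float(np.mean(all_values)),
    }


# ------------------------------------------------------------ SMO occupancy

def smo_occupancy(total_smo_area: float, n_cilia: int) -> float:
    """Total SMO-positive area per cilium; NaN flags a field with no cilia."""
    if total_smo_area < 0:
        raise ConfigurationError("area must be non-negative")
    if n_cilia <= 0:
        return float("nan")
    return total_smo_area / n_cilia


# ------------------------------------------------------------- Gabor score

@dataclass(frozen=True)
class GaborParams:
    """Filter-bank parameters: Gaussian envelope sd (pixels), sinusoid
    wavelength (pixels), number of orientations uniform over [0, π), and the
    normalization mode."""

    scale: float = 2.0
    wavelength: float = 8.0
    n_angles: int = 8
    normalization: str = "regional_intensity"
    n_stds: float = 4.0  # kernel support in envelope sds; 3 is visibly anisotropic

    def __post_init__(self):
        if self.wavelength < 2.0:
            raise ConfigurationError("wavelength must be >= 2 px (Nyquist)")
        if self.n_angles < 1 or self.scale <= 0:
            raise ConfigurationError("need n_angles >= 1 and scale > 0")
        if self.normalization not in ("regional_intensity", "none"):
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}")


def _gabor_bank(params: GaborParams) -> list[np.ndarray]:
    """Quadrature (complex) kernels, DC-corrected so a constant image gives
    an exactly zero even response."""
    bank = []
    for k in range(params.n_angles):
        theta = np.pi * k / params.n_angles
        kern = gabor_kernel(
            frequency=1.0 / params.wavelength, theta=theta,
            sigma_x=params.scale, sigma_y=params.scale, n_stds=params.n_stds,
        )
        kern = kern - kern.real.mean()  # remove DC from the even component
        bank.append(kern)
    return bank


def gabor_fibre_score(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: GaborParams = GaborParams(),
) -> float:
    """Fibre-texture score of a grayscale image.

    Each pixel's response is the magnitude of the quadrature Gabor pair,
    maximized over the orientation bank; the score is the mean response over
    the masked region. With ``regional_intensity`` normalization the mean
    response is divided by the mean image intensity over the same region.
    The image's regional mean is removed before filtering, so a constant
    image scores exactly 0 and the unnormalized response is invariant to a
    constant offset.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ConfigurationError("empty mask")
    bank = _gabor_bank(params)
    if min(image.shape) < max(max(k.shape) for k in bank):
        raise ConfigurationError("image smaller than the kernel support")

    if np.ptp(image[mask]) == 0:
        return 0.0  # constant region: zero AC response by definition
    regional_mean = float(image[mask].mean())
    ac = image - regional_mean
    best = np.zeros_like(image)
    for kern in bank:
        re = ndimage.convolve(ac, kern.real, mode="reflect")
        im = ndimage.convolve(ac, kern.imag, mode="reflect")
        np.maximum(best, np.hypot(re, im), out=best)
    score = float(best[mask].mean())
    if params.normalization == "regional_intensity":
        if regional_mean <= 0:
            raise ConfigurationError(
                "regional intensity normalization needs a positive mean")
        score /= regional_mean
    return score


# -------------------------------------------------------- tubule morphometry

def tubule_area(a: float, b: float) -> float:
    """Ellipse-formula tubule area πab from the longest (a) and perpendicular
    (b) axes in µm. The printed formula is used literally, i.e. the axes are
    treated as semi-axes (for full diameters the area would be πab/4)."""
    if b <= 0:
        raise ConfigurationError("axes must be positive")
    if a < b:
        raise ConfigurationError(f"longest axis a ({a}) must be >= b ({b})")
    return float(np.pi * a * b)


# ------------------------------------------------------------- cyst counting

def cyst_count(grades: pd.DataFrame) -> dict[str, float]:
    """Count cysts (surface anomalies of stage >= 2) over graded organoids.

    ``grades`` has columns ``organoid`` and ``stage`` (one row per anomaly;
    organoids without anomalies appear with a stage-0 row). Returns the cyst
    count and the mean cyst number per organoid.
    """
    stages = grades["stage"]
    if not stages.isin([0, 1, 2, 3]).all():
        bad = sorted(set(stages) - {0, 1, 2, 3})
        raise ConfigurationError(f"invalid stage values {bad}; must be 0-3")
    n_cysts = int((stages >= 2).sum())
    n_organoids = grades["organoid"].nunique()
    return {
        "n_cysts": n_cysts,
        "n_organoids": int(n_organoids),
        "mean_cysts_per_organoid": n_cysts / n_organoids,
    }


# ---------------------------------------------------------------- luciferase

def luciferase_normalize(firefly, renilla, reference_ratio: float) -> np.ndarray:
    """Firefly:Renilla ratios normalized to the unstimulated vehicle control."""
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    if firefly.shape != renilla.shape:
        raise ConfigurationError("firefly and renilla must be matched")
    if reference_ratio <= 0:
        raise ConfigurationError("reference ratio must be > 0")
    if (renilla <= 0).any():
        bad = np.nonzero(renilla <= 0)[0]
        raise ConfigurationError(f"non-positive renilla signal in wells {bad.tolist()}")
    return (firefly / renilla) / reference_ratio


# -------------------------------------------------------------- dose response

def dose_response_table(
    wells: pd.DataFrame,
    vehicle: str = "DMSO",
    scale_constant: float = MAD_SCALE_NORMAL,
) -> pd.DataFrame:
    """Per-(genotype, compound, dose) robust z and fold-change versus vehicle.

    ``wells`` needs columns genotype, compound, dose, cell_count,
    ciliated_count. For each genotype the vehicle wells (compound ==
    ``vehicle``) form the reference population; each dose group's wells are
    scored with the robust z against that population (mean per group) and the
    fold-change is the dose-group mean incidence over the vehicle mean
    incidence.
    """
    df = wells.copy()
    df["incidence"] = 100.0 * df["ciliated_count"] / df["cell_count"]
    rows = []
    for genotype, gdf in df.groupby("genotype", sort=True):
        veh = gdf[gdf["compound"] == vehicle]
        if veh.empty:
            raise StructuralError(f"no vehicle wells for genotype {genotype!r}")
        veh_inc = veh["incidence"].to_numpy()
        veh_cells = veh["cell_count"].to_numpy(dtype=float)
        for (compound, dose), grp in gdf[gdf["compound"] != vehicle].groupby(
                ["compound", "dose"], sort=True):
            z_cilia = float(np.mean(robust_z(grp["incidence"], veh_inc,
                                             scale_constant)))
            z_cell = float(np.mean(robust_z(grp["cell_count"], veh_cells,
                                            scale_constant)))
            rows.append(dict(
                genotype=genotype, compound=compound, dose=dose,
                z_cilia=z_cilia, z_cell=z_cell,
                fold_change_incidence=float(grp["incidence"].mean()
                                            / veh_inc.mean()),
                n_wells=len(grp),
            ))
    return pd.DataFrame(rows)
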