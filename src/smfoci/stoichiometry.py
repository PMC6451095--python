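"""Single-molecule intensity calibration, copy numbers and bound fractions.

The intensity of one fluorophore (the "unit intensity") is calibrated
from discrete photobleaching steps in burst-acquisition trajectories.
Cell-integrated fluorescence divided by the unit intensity, corrected
for a population autofluorescence equivalent, gives label copy numbers
per cell; the spherocylinder cell volume converts those to
concentrations.  Focus intensities divided by the unit give molecules
per focus, and the bound fraction follows as
``100 · foci_per_cell · molecules_per_focus / copies_per_cell``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro
from scipy.stats import gaussian_kde

from .errors import CalibrationError, ConfigError
from .trajectories import Trajectory

__all__ = [
    "CopyNumberEstimate",
    "flatten_field",
    "find_steps",
    "unit_intensity_from_steps",
    "copy_number",
    "concentration",
    "molecules_per_focus",
    "bound_fraction",
]


@dataclass
class CopyNumberEstimate:
    """Copy number and concentration for one cell."""

    cell_id: int
    integrated_signal: float       # counts
    unit_intensity: float          # counts / molecule
    autofluorescence_equiv: float  # molecules
    n_molecules: float             # >= 0
    volume: float | None = None    # fL
    concentration: float | None = None  # nM


# ---------------------------------------------------------------------------
# flat-field correction
# ---------------------------------------------------------------------------

def flatten_field(image: np.ndarray,
                  illumination_profile: np.ndarray) -> np.ndarray:
    """Correct for excitation-beam inhomogeneity.

    The image is divided pixelwise by the profile normalized to unit
    maximum, so a centre 12% brighter than the corners scales corner
    pixels up by ×1.12.

    Raises
    ------
    ConfigError
        On shape mismatch or a non-positive profile value.
    """
    image = np.asarray(image, dtype=float)
    profile = np.asarray(illumination_profile, dtype=float)
    if profile.shape != image.shape:
        raise ConfigError("profile must have the same shape as the image")
    if np.any(profile <= 0):
        raise ConfigError("illumination profile must be strictly positive")
    return image / (profile / profile.max())


def radial_illumination_profile(shape: tuple[int, int],
                                centre_to_corner: float = 1.12) -> np.ndarray:
    """Smooth radial profile with a given centre/corner intensity ratio."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - (1.0 - 1.0 / centre_to_corner) * r2


# ---------------------------------------------------------------------------
# photobleaching-step calibration
# ---------------------------------------------------------------------------

def find_steps(values: np.ndarray, *, min_segment: int = 3,
               penalty_factor: float = 12.0) -> list[int]:
    """Change points of a piecewise-constant signal by binary segmentation.

    A split is accepted when it reduces the residual sum of squares by
    more than ``penalty_factor · σ̂² · log(n)``, with σ̂ a robust noise
    scale from first differences.  Returns sorted change-point indices
    (each the first frame of a new plateau).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 2 * min_segment:
        return []
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
    sigma = max(sigma, 1e-9 * max(np.ptp(y), 1.0))
    penalty = penalty_factor * sigma**2 * np.log(n)

    def best_split(lo: int, hi: int):
        """Best change point in y[lo:hi]; returns (gain, index)."""
        seg = y[lo:hi]
        m = seg.size
        if m < 2 * min_segment:
            return 0.0, None
        csum = np.cumsum(seg)
        total = csum[-1]
        k = np.arange(min_segment, m - min_segment + 1)
        left = csum[k - 1]
        sse_gain = (left**2 / k + (total - left) ** 2 / (m - k)
                    - total**2 / m)
        i = int(np.argmax(sse_gain))
        return float(sse_gain[i]), lo + int(k[i])

    changes: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        gain, idx = best_split(lo, hi)
        if idx is None or gain <= penalty:
            continue
        changes.append(idx)
        stack.append((lo, idx))
        stack.append((idx, hi))
    changes = sorted(changes)

    # merge adjacent plateaus whose means are not clearly distinct
    # (Welch-style t-statistic < 3); kills spurious splits of noisy
    # plateaus that would otherwise pollute the step-size distribution
    merged = True
    while merged and changes:
        merged = False
        bounds = [0, *changes, n]
        for i in range(1, len(bounds) - 1):
            a, b, c = bounds[i - 1], bounds[i], bounds[i + 1]
            s1, s2 = y[a:b], y[b:c]
            se = np.sqrt(s1.var(ddof=1) / s1.size + s2.var(ddof=1) / s2.size) \
                if min(s1.size, s2.size) > 1 else 0.0
            se = max(se, 1e-12)
            if abs(s1.mean() - s2.mean()) / se < 3.0:
                changes.remove(b)
                merged = True
                break
    return changes


@dataclass
class UnitIntensityCalibration:
    unit_intensity: float
    uncertainty: float
    n_steps: int
    cv: float                      # coefficient of variation of used steps
    step_sizes: np.ndarray


def unit_intensity_from_steps(trajectories: list[Trajectory],
                              *, min_segment: int = 3
                              ) -> UnitIntensityCalibration:
    """Calibrate counts/molecule from photobleaching step sizes.

    Steps are located per trajectory by change-point detection; the
    distribution of downward step magnitudes is summarized by its
    dominant mode (kernel density peak) and the unit is the mean of the
    steps belonging to that mode (within ±35%).

    Raises
    ------
    CalibrationError
        With fewer than 10 trajectories or if no steps are found.
    """
    if len(trajectories) < 10:
        raise CalibrationError("need at least 10 trajectories with steps")
    drops = []
    for tr in trajectories:
        y = tr.intensities
        idx = find_steps(y, min_segment=min_segment)
        if not idx:
            continue
        bounds = [0, *idx, y.size]
        means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        for a, b in zip(means[:-1], means[1:]):
            if b < a:
                drops.append(a - b)
    if not drops:
        raise CalibrationError("no photobleaching steps found")
    drops = np.asarray(drops)
    if drops.size >= 5 and np.ptp(drops) > 0:
        kde = gaussian_kde(drops)
        grid = np.linspace(drops.min(), drops.max(), 512)
        mode = grid[np.argmax(kde(grid))]
    else:
        mode = float(np.median(drops))
    used = drops[np.abs(drops - mode) <= 0.35 * mode]
    if used.size == 0:
        used = drops
    unit = float(used.mean())
    sem = float(used.std(ddof=1) / np.sqrt(used.size)) if used.size > 1 \
        else 0.0
    cv = float(used.std(ddof=1) / unit) if used.size > 1 else 0.0
    return UnitIntensityCalibration(
        unit_intensity=unit, uncertainty=sem, n_steps=int(drops.size),
        cv=cv, step_sizes=drops,
    )


# ---------------------------------------------------------------------------
# copy numbers, concentrations, molecules per focus, bound fraction
# ---------------------------------------------------------------------------

def copy_number(mean_cell_intensity: float, area_px: float,
                autofluorescence_equiv: float = 2.5,
                unit_intensity: float = 1.0, *, cell_id: int = 0,
                volume: float | None = None) -> CopyNumberEstimate:
    """Label copies in one cell from its integrated fluorescence.

    ``integrated = mean_cell_intensity × area_px``;
    ``n = max(0, integrated/unit − autofluorescence_equiv)``.  Negative
    corrected values clamp to zero with a warning (the autofluorescence
    equivalent is a population constant applied per cell).

    Raises
    ------
    ConfigError
        If ``unit_intensity <= 0``.
    """
    if unit_intensity <= 0:
        raise ConfigError("unit_intensity must be > 0")
    integrated = mean_cell_intensity * area_px
    n = integrated / unit_intensity - autofluorescence_equiv
    if n < 0:
        if n < -1e-12:
            warnings.warn(
                f"cell {cell_id}: corrected copy number {n:.3g} < 0, "
                "clamped to 0", stacklevel=2,
            )
        n = 0.0
    conc = concentration(n, volume) if volume is not None else None
    return CopyNumberEstimate(
        cell_id=cell_id,
        integrated_signal=float(integrated),
        unit_intensity=float(unit_intensity),
        autofluorescence_equiv=float(autofluorescence_equiv),
        n_molecules=float(n),
        volume=volume,
        concentration=conc,
    )


def concentration(n_molecules: float, volume_fl: float) -> float:
    """Concentration in nM of ``n`` molecules in a volume in fL.

    ``C = n / (V · N_A)``; one molecule in 1.66 fL is 1.0 nM.

    Raises
    ------
    ConfigError
        If ``volume_fl <= 0``.
    """
    if volume_fl <= 0:
        raise ConfigError("volume must be > 0")
    molar = n_molecules / (volume_fl * 1e-15 * Avogadro)
    return molar * 1e9


def molecules_per_focus(focus_intensity: float,
                        unit_intensity: float) -> tuple[float, int]:
    """Molecules in one focus: intensity ratio and its nearest integer.

    Raises
    ------
    ConfigError
        For a negative intensity or non-positive unit.
    """
    if unit_intensity <= 0:
        raise ConfigError("unit_intensity must be > 0")
    if focus_intensity < 0:
        raise ConfigError("focus intensity must be >= 0")
    ratio = focus_intensity / unit_intensity
    return float(ratio), int(round(ratio))


def bound_fraction(foci_per_cell: float, molecules_per_focus: float,
                   copies_per_cell: float) -> float:
    """Percentage of labelled molecules bound to DNA.

    ``100 · (foci_per_cell · molecules_per_focus) / copies_per_cell``:
    e.g. two monomeric foci out of 18 copies ≈ 11%, two dimeric foci
    out of 18 copies ≈ 22%.

    Raises
    ------
    ConfigError
        If ``copies_per_cell <= 0``.
    """
    if copies_per_cell <= 0:
        raise ConfigError("copies_per_cell must be > 0")
    return 100.0 * foci_per_cell * molecules_per_focus / copies_per_cell
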