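"""Focus detection inside cell outlines and per-cell statistics.

Foci are diffraction-limited spots of DNA-bound molecules sitting on a
diffuse cytosolic background.  Detection runs per cell: a band-pass
(difference-of-Gaussians) response picks candidate local maxima above
the per-cell background plus ``min_peak_snr`` times the per-cell noise,
candidates closer than one PSF σ are merged, and each surviving peak is
refined to sub-pixel precision by a least-squares 2D Gaussian fit (with
an intensity-weighted centroid fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage import measure
from skimage.feature import peak_local_max

from .cells import CellOutline, spherocylinder_volume
from .errors import ConfigError, ConsistencyError
from .synthetic import PSF_SIGMA_PX, _rasterize_cell

__all__ = [
    "FocusRecord",
    "PerCellStats",
    "segment_cells",
    "detect_foci",
    "per_cell_stats",
    "estimate_offset",
]


@dataclass
class FocusRecord:
    """One detected focus."""

    cell_id: int
    channel: str
    time_point: float
    x_px: float
    y_px: float
    x_um: float
    y_um: float
    integrated_intensity: float   # background-subtracted counts
    peak_snr: float
    n_molecules: float | None = None


@dataclass
class PerCellStats:
    """Per-cell summary at one time point."""

    cell_id: int
    time_point: float
    n_foci: int
    area: float                  # µm²
    focus_density: float         # foci / µm²
    mean_cell_intensity: float   # background-corrected counts / px
    length: float                # µm


def records_to_frame(records: list[FocusRecord]) -> pd.DataFrame:
    cols = ["cell_id", "channel", "time_point", "x_px", "y_px",
            "x_um", "y_um", "intensity", "snr", "n_molecules"]
    rows = [
        (r.cell_id, r.channel, r.time_point, r.x_px, r.y_px, r.x_um, r.y_um,
         r.integrated_intensity, r.peak_snr, r.n_molecules)
        for r in records
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# segmentation (minimal mask-based stand-in; outlines may also be ingested)
# ---------------------------------------------------------------------------

def segment_cells(mask: np.ndarray, pixel_size: float = 0.1, *,
                  time_point: float = 0.0) -> list[CellOutline]:
    """Segment a binary mask (or thresholded image) into cell outlines.

    Connected components become polygons via marching squares; cells
    touching the frame border are discarded, mirroring the curation of
    non-overlapping in-focus cells.  A blank mask yields an empty list.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ConfigError("mask must be 2D")
    binary = mask > 0
    labels = measure.label(binary)
    cells = []
    h, w = binary.shape
    for region in measure.regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            continue  # touches the border
        contours = measure.find_contours(labels == region.label, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # contour is (row, col); convert to (x, y) µm and decimate
        step = max(len(contour) // 64, 1)
        verts = contour[::step][:, ::-1] * pixel_size
        # sub-pixel contour area is less biased than the pixel count,
        # which over-counts by about half the perimeter
        from shapely.geometry import Polygon as _Poly
        contour_area = _Poly(verts).area if len(verts) >= 3 else 0.0
        # length/width as contour extent along the principal axes (the
        # ellipse-equivalent axis lengths overestimate rod length)
        centre = verts.mean(axis=0)
        centred = verts - centre
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        proj_l = centred @ axis
        proj_w = centred @ np.array([-axis[1], axis[0]])
        length = float(np.ptp(proj_l))
        width = max(float(np.ptp(proj_w)), pixel_size)
        width = min(width, length)
        cells.append(
            CellOutline(
                cell_id=int(region.label),
                vertices=verts,
                length=length,
                width=width,
                time_point=time_point,
                centre=(float(centre[0]), float(centre[1])),
                angle=float(np.arctan2(axis[1], axis[0])),
                area=contour_area or region.area * pixel_size**2,
                volume=spherocylinder_volume(length, width),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# focus detection
# ---------------------------------------------------------------------------

def estimate_offset(image: np.ndarray, cells: list[CellOutline],
                    pixel_size: float) -> float:
    """Camera offset estimate: median intensity outside all cells."""
    inside = np.zeros(image.shape, dtype=bool)
    for c in cells:
        rr, cc = _rasterize_cell(c, image.shape, pixel_size)
        inside[rr, cc] = True
    outside = image[~inside]
    return float(np.median(outside)) if outside.size else 0.0


def _fit_gaussians(window: np.ndarray, peaks: list[tuple[float, float]],
                   sigma0: float, mask: np.ndarray | None = None,
                   wander: float = 2.0):
    """Joint least-squares fit of K 2D Gaussians with shared σ and offset.

    ``peaks`` are (x, y) starting centres relative to the window
    origin; each centre is bounded to within ``wander`` pixels of its
    start so blended neighbours cannot collapse onto one another.
    ``mask`` restricts the residuals to in-cell pixels so the cell edge
    (a large background step) cannot hijack the fit.  Returns a list of
    (x, y, amplitude, σ) tuples, or None on failure.
    """
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    if mask is None:
        mask = np.ones(window.shape, dtype=bool)
    k = len(peaks)
    if mask.sum() < 5 * k + 2:
        return None
    z = window[mask]
    mx, my = xx[mask], yy[mask]
    b0 = float(np.median(z))
    a0 = max(float(z.max()) - b0, 1e-6)
    p0, lo, hi = [], [], []
    for (pxx, pyy) in peaks:
        p0 += [pxx, pyy, a0]
        lo += [pxx - wander, pyy - wander, 0.0]
        hi += [pxx + wander, pyy + wander, np.inf]
    # σ is tied to the known PSF width: a loose upper bound would let a
    # single wide component absorb a blended pair and defeat deblending
    p0 += [sigma0, b0]
    lo += [0.7 * sigma0, -np.inf]
    hi += [1.4 * sigma0, np.inf]

    def resid(p):
        s, b = p[-2], p[-1]
        g = np.full(z.shape, b)
        for i in range(k):
            x0, y0, a = p[3 * i: 3 * i + 3]
            g = g + a * np.exp(
                -((mx - x0) ** 2 + (my - y0) ** 2) / (2 * s**2))
        return g - z

    try:
        res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=100 * k)
    except Exception:
        return None
    if not res.success:
        return None
    s = float(res.x[-2])
    return [
        (float(res.x[3 * i]), float(res.x[3 * i + 1]),
         float(res.x[3 * i + 2]), s)
        for i in range(k)
    ]


def _cluster_peaks(peaks: list[tuple[int, int]],
                   link_dist: float) -> list[list[int]]:
    """Group peak indices whose chain distance is below ``link_dist``."""
    n = len(peaks)
    unseen = set(range(n))
    clusters = []
    while unseen:
        seed = unseen.pop()
        group = [seed]
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            py, px = peaks[i]
            near = [
                j for j in unseen
                if (peaks[j][0] - py) ** 2 + (peaks[j][1] - px) ** 2
                <= link_dist**2
            ]
            for j in near:
                unseen.remove(j)
                group.append(j)
                frontier.append(j)
        clusters.append(group)
    return clusters


def detect_foci(image: np.ndarray, outlines: list[CellOutline],
                min_peak_snr: float = 3.0, *, pixel_size: float = 0.1,
                psf_sigma_px: float = PSF_SIGMA_PX, channel: str = "A",
                time_point: float | None = None,
                offset: float | None = None) -> list[FocusRecord]:
    """Detect punctate foci inside cell outlines.

    Per cell, the background is the median intensity inside the outline
    excluding 3σ disks around candidate peaks, and the noise level is a
    robust (MAD-based) standard deviation of the same pixels.  Local
    maxima of a difference-of-Gaussians response exceeding
    ``min_peak_snr × noise`` are kept, merged when closer than one PSF
    σ, refined by 2D Gaussian fitting and reported with their
    background-subtracted integrated intensity.

    Raises
    ------
    ConfigError
        If ``min_peak_snr <= 0``.
    """
    if min_peak_snr <= 0:
        raise ConfigError("min_peak_snr must be > 0")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigError("image must be 2D")
    from skimage.filters import difference_of_gaussians

    bandpass = difference_of_gaussians(image, psf_sigma_px, 4 * psf_sigma_px)
    r_fit = max(int(np.ceil(3 * psf_sigma_px)), 3)

    # round 1: per-cell background, candidate peaks and a joint fit
    state = []
    for cell in outlines:
        rr, cc = _rasterize_cell(cell, image.shape, pixel_size)
        if rr.size < 9:
            continue
        mask = np.zeros(image.shape, dtype=bool)
        mask[rr, cc] = True
        pix = image[rr, cc]
        bg = float(np.median(pix))
        noise = 1.4826 * float(np.median(np.abs(pix - bg)))
        if noise == 0:
            continue  # flat cell interior: no detectable structure
        peaks = _cell_candidates(bandpass, image, mask, bg, noise,
                                 min_peak_snr, r_fit, psf_sigma_px)
        # refine background: exclude 3 sigma disks around candidates
        if peaks:
            excl = np.zeros(image.shape, dtype=bool)
            for (py, px) in peaks:
                y0 = max(py - r_fit, 0)
                x0 = max(px - r_fit, 0)
                excl[y0:py + r_fit + 1, x0:px + r_fit + 1] = True
            clean = image[mask & ~excl]
            if clean.size >= 9:
                bg = float(np.median(clean))
                noise = max(
                    1.4826 * float(np.median(np.abs(clean - bg))), 1e-9)
            peaks = [
                (py, px) for (py, px) in peaks
                if image[py, px] - bg >= min_peak_snr * noise
            ]
        comps = _fit_cell(image, mask, peaks, psf_sigma_px, r_fit, bg)
        state.append((cell, mask, bg, noise, peaks, comps))

    # matching-pursuit rounds: subtract the fitted spots, look for
    # peaks that were blended into neighbours, refit jointly
    for _ in range(2):
        model = np.zeros_like(image)
        for (_, _, _, _, _, comps) in state:
            for (xf, yf, amp, sig) in comps:
                _add_point_gaussian(model, xf, yf, amp, sig)
        if not np.any(model):
            break
        residual = image - model
        bandpass_res = difference_of_gaussians(residual, psf_sigma_px,
                                               4 * psf_sigma_px)
        any_fresh = False
        for i, (cell, mask, bg, noise, peaks, comps) in enumerate(state):
            extra = _cell_candidates(bandpass_res, residual, mask, bg, noise,
                                     min_peak_snr, r_fit, psf_sigma_px)
            fresh = [
                (py, px) for (py, px) in extra
                if all((py - yf - 0.5) ** 2 + (px - xf - 0.5) ** 2
                       > psf_sigma_px**2
                       for (xf, yf, _, _) in comps)
            ]
            if fresh:
                any_fresh = True
                peaks = peaks + fresh
                comps = _fit_cell(image, mask, peaks, psf_sigma_px, r_fit,
                                  bg)
                state[i] = (cell, mask, bg, noise, peaks, comps)
        if not any_fresh:
            break

    records: list[FocusRecord] = []
    for (cell, mask, bg, noise, peaks, comps) in state:
        tp = cell.time_point if time_point is None else time_point
        cell_records: list[FocusRecord] = []
        for (xf, yf, amp, sig) in comps:
            integrated = 2 * np.pi * sig**2 * amp
            if integrated <= 0:
                continue
            # pixel i integrates [i, i+1): index-space estimates sit
            # half a pixel below the continuous coordinate
            x_sub, y_sub = xf + 0.5, yf + 0.5
            x_um = x_sub * pixel_size
            y_um = y_sub * pixel_size
            if not cell.contains(x_um, y_um, tol=pixel_size):
                continue
            cell_records.append(
                FocusRecord(
                    cell_id=cell.cell_id,
                    channel=channel,
                    time_point=tp,
                    x_px=x_sub, y_px=y_sub, x_um=x_um, y_um=y_um,
                    integrated_intensity=float(integrated),
                    peak_snr=float(amp / noise),
                )
            )
        # deduplicate refined positions that converged together
        cell_records.sort(key=lambda r: -r.integrated_intensity)
        kept: list[FocusRecord] = []
        for r in cell_records:
            if all((r.x_px - q.x_px) ** 2 + (r.y_px - q.y_px) ** 2
                   > psf_sigma_px**2 for q in kept):
                kept.append(r)
        records.extend(kept)
    return records


def _cell_candidates(response: np.ndarray, intensity_image: np.ndarray,
                     mask: np.ndarray, bg: float, noise: float,
                     min_peak_snr: float, r_fit: int, psf_sigma_px: float,
                     background: float | None = None) -> list:
    """Integer candidate peaks inside one cell.

    Local maxima of the band-pass response above half the peak
    threshold, that also clear ``min_peak_snr x noise`` over the cell
    background on the intensity image; near-duplicates within one PSF
    sigma are merged keeping the brighter.
    """
    resp = np.where(mask, response, -np.inf)
    coords = peak_local_max(
        resp, min_distance=1,
        threshold_abs=min_peak_snr * noise * 0.5,
        exclude_border=False,
    )
    level = bg if background is None else background
    kept = [
        (int(py), int(px)) for (py, px) in coords
        if intensity_image[py, px] - level >= min_peak_snr * noise
    ]
    kept.sort(key=lambda p: -intensity_image[p[0], p[1]])
    merged: list[tuple[int, int]] = []
    for (py, px) in kept:
        if all((py - qy) ** 2 + (px - qx) ** 2 > psf_sigma_px**2
               for (qy, qx) in merged):
            merged.append((py, px))
    return merged


def _fit_cell(image: np.ndarray, mask: np.ndarray, peaks: list,
              psf_sigma_px: float, r_fit: int, bg: float) -> list:
    """Cluster candidate peaks and fit each cluster jointly.

    Returns fitted components as (x, y, amplitude, sigma) in image
    index coordinates.
    """
    comps = []
    for group in _cluster_peaks(peaks, 2 * r_fit):
        pts = [peaks[i] for i in group]
        ys = [p[0] for p in pts]
        xs = [p[1] for p in pts]
        y0 = max(min(ys) - r_fit, 0)
        y1 = min(max(ys) + r_fit + 1, image.shape[0])
        x0 = max(min(xs) - r_fit, 0)
        x1 = min(max(xs) + r_fit + 1, image.shape[1])
        window = image[y0:y1, x0:x1]
        wmask = mask[y0:y1, x0:x1]
        starts = [(px - x0, py - y0) for (py, px) in pts]
        fit = _fit_gaussians(window, starts, psf_sigma_px, mask=wmask)
        if fit is not None:
            comps.extend(
                (x0 + fx, y0 + fy, amp, sig) for (fx, fy, amp, sig) in fit)
            continue
        # intensity-weighted centroid fallback (in-cell pixels)
        wts = np.where(wmask, np.clip(window - bg, 0, None), 0.0)
        if wts.sum() > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            amp = float(wts.sum()) / len(pts) / (2 * np.pi * psf_sigma_px**2)
            comps.append((
                float((xx * wts).sum() / wts.sum()),
                float((yy * wts).sum() / wts.sum()),
                amp, psf_sigma_px,
            ))
    return comps


def _add_point_gaussian(image: np.ndarray, x0: float, y0: float,
                        amp: float, sigma: float) -> None:
    """Add a point-sampled Gaussian (matching the fit model) in place."""
    h, w = image.shape
    r = int(np.ceil(4 * sigma))
    xa = max(int(x0) - r, 0)
    xb = min(int(x0) + r + 1, w)
    ya = max(int(y0) - r, 0)
    yb = min(int(y0) + r + 1, h)
    if xa >= xb or ya >= yb:
        return
    yy, xx = np.mgrid[ya:yb, xa:xb]
    image[ya:yb, xa:xb] += amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


# ---------------------------------------------------------------------------
# per-cell statistics
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    mean_foci_per_cell: float
    sem_foci_per_cell: float
    mean_length: float
    n_cells: int


def per_cell_stats(records: list[FocusRecord], outlines: list[CellOutline],
                   image: np.ndarray, *, pixel_size: float = 0.1,
                   offset: float | None = None
                   ) -> tuple[list[PerCellStats], EnsembleSummary]:
    """Foci counts, focus density and mean intensity per cell.

    ``mean_cell_intensity`` is the offset-corrected mean pixel value
    inside the outline (counts/px); the offset defaults to the median
    outside all cells.  The ensemble summary reports the mean ± SEM of
    foci per cell and the mean cell length.

    Raises
    ------
    ConsistencyError
        If a record references an unknown cell id.
    """
    image = np.asarray(image, dtype=float)
    known = {c.cell_id for c in outlines}
    for r in records:
        if r.cell_id not in known:
            raise ConsistencyError(f"record references unknown cell "
                                   f"{r.cell_id}")
    if offset is None:
        offset = estimate_offset(image, outlines, pixel_size)
    counts: dict[int, int] = {cid: 0 for cid in known}
    for r in records:
        counts[r.cell_id] += 1
    stats = []
    for c in outlines:
        rr, cc = _rasterize_cell(c, image.shape, pixel_size)
        mean_int = float(image[rr, cc].mean() - offset) if rr.size else 0.0
        n = counts[c.cell_id]
        stats.append(
            PerCellStats(
                cell_id=c.cell_id,
                time_point=c.time_point,
                n_foci=n,
                area=c.area,
                focus_density=n / c.area,
                mean_cell_intensity=mean_int,
                length=c.length,
            )
        )
    n_foci = np.array([s.n_foci for s in stats], dtype=float)
    lengths = np.array([s.length for s in stats])
    sem = float(n_foci.std(ddof=1) / np.sqrt(n_foci.size)) \
        if n_foci.size > 1 else np.nan
    summary = EnsembleSummary(
        mean_foci_per_cell=float(n_foci.mean()) if n_foci.size else np.nan,
        sem_foci_per_cell=sem,
        mean_length=float(lengths.mean()) if lengths.size else np.nan,
        n_cells=len(stats),
    )
    return stats, summary


def foci_histogram(stats: list[PerCellStats]) -> pd.DataFrame:
    """Histogram of foci per cell (counts sum to the number of cells)."""
    counts = np.array([s.n_foci for s in stats], dtype=int)
    if counts.size == 0:
        return pd.DataFrame({"n_foci": [], "n_cells": []})
    values = np.bincount(counts)
    return pd.DataFrame({"n_foci": np.arange(values.size),
                         "n_cells": values})
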