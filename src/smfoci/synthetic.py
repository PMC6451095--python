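"""Synthetic single-molecule microscopy generator.

Emulates two-colour live-cell imaging of rod-shaped bacteria carrying
fluorescent-protein fusions: DNA-bound molecules appear as
diffraction-limited foci, freely diffusing molecules blur into a diffuse
per-cell background at 34–100 ms exposures, and an EM-CCD camera adds
Poisson shot noise, Gaussian read noise and a constant offset.  Cells
filament (elongate without dividing) after a damage event, the focus
density per unit area stays constant as they grow, and a channel can
switch from monomeric to dimeric foci at a configurable time.

Every quantity is ground-truthed so the downstream detection,
stoichiometry, colocalization and spatial modules can be validated
without real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .cells import CellOutline, generate_cell, spherocylinder_volume
from .errors import ConfigError, ConsistencyError

__all__ = [
    "GroundTruthFocus",
    "TimelapseConfig",
    "TimelapseResult",
    "place_foci",
    "render_frame",
    "generate_timelapse",
    "replication_shutdown_preset",
]

#: Fixed pixel size, µm/px.  Chosen so that the 218 nm colocalization
#: radius equals 2.18 px, the equivalence used throughout the analysis.
PIXEL_SIZE_UM = 0.1

#: Default PSF standard deviation in pixels, typical for a 1.49 NA
#: objective at ~540 nm emission with 100 nm pixels.
PSF_SIGMA_PX = 1.3


@dataclass(frozen=True)
class GroundTruthFocus:
    """One ground-truth DNA-bound focus."""

    cell_id: int
    channel: str
    time_point: float          # minutes relative to the damage event
    position: tuple[float, float]  # (x, y) in µm, global frame
    n_molecules: int
    width_coordinate: float    # signed µm from the cell centre spline


@dataclass
class TimelapseConfig:
    """Parameters of a synthetic two-channel time-lapse experiment.

    Defaults mirror the imaging conditions the pipeline targets:
    512×512 px frames at 100 nm/px, snapshots every 10 min for 3 h, the
    damage event at t = 0 and filamentation starting ~30 min later.
    Channel A emulates a replisome-proximal monomer that dimerizes after
    damage (central placement, ~2.2 foci per average cell); channel B a
    rarer membrane-proximal monomer.
    """

    n_cells: int = 60
    pixel_size: float = PIXEL_SIZE_UM          # µm / px
    frame_size: int = 512                      # px
    psf_sigma_px: float = PSF_SIGMA_PX
    exposure_mode: str = "timelapse_100ms"     # or "burst_34ms"
    interval: float = 10.0                     # min between time points
    duration: float = 180.0                    # min
    damage_time: float = 0.0                   # min
    filamentation_onset: float = 30.0          # min after damage
    growth_rate: float = 0.01                  # 1/min exponential elongation
    static_fraction: float = 0.0               # cells that never filament
    # foci per µm² of cell area, per channel (0.8/µm² ≈ 2.2 foci in a
    # 2.8 µm² cell; 0.12/µm² ≈ 0.3 foci per cell)
    focus_density: dict = field(default_factory=lambda: {"A": 0.8, "B": 0.12})
    density_decay_rate: float = 0.0            # 1/min, post-damage decay
    # per channel: (molecules/focus before, after, switch time in min);
    # switch None means no change
    stoichiometry_schedule: dict = field(
        default_factory=lambda: {"A": (1, 2, 30.0), "B": (1, 1, None)}
    )
    # per channel: "central" | "peripheral" | "uniform", or a
    # (mode_before, mode_after, switch_time) schedule
    spatial_mode: dict = field(
        default_factory=lambda: {"A": "central",
                                 "B": ("central", "peripheral", 30.0)}
    )
    coloc_fraction: float = 0.0   # fraction of A foci forced onto B positions
    copies_per_cell: float = 18.0              # mean label copies at t=0 size
    autofluorescence_equiv: float = 2.5        # molecules-worth of autofluor.
    unit_intensity: float | None = None        # counts per molecule
    snr: float = 10.0      # approx. single-molecule peak SNR at defaults
    offset: float = 100.0                      # camera counts
    read_noise: float = 2.0                    # counts rms
    mean_length: float = 3.0                   # µm, initial cells
    mean_width: float = 1.0                    # µm
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        for name in ("n_cells", "frame_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("interval", "duration", "growth_rate", "copies_per_cell",
                     "autofluorescence_equiv", "snr", "density_decay_rate",
                     "coloc_fraction", "static_fraction"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.duration < self.interval:
            raise ConfigError("duration must be at least one interval")
        if any(d < 0 for d in self.focus_density.values()):
            raise ConfigError("focus densities must be non-negative")
        if self.unit_intensity is None:
            # Derived so that the single-molecule peak SNR over the
            # diffuse cell background lands near `snr` at the default
            # copy number and cell size (see docs/methods.md).
            self.unit_intensity = 20.0 * self.snr**2

    @property
    def time_points(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 1e-9, self.interval)

    @property
    def channels(self) -> list[str]:
        return sorted(self.focus_density)

    def spatial_mode_at(self, channel: str, t: float) -> str:
        mode = self.spatial_mode.get(channel, "uniform")
        if isinstance(mode, (tuple, list)):
            before, after, switch = mode
            return before if (switch is None or t < switch) else after
        return mode

    def molecules_per_focus_at(self, channel: str, t: float) -> int:
        pre, post, switch = self.stoichiometry_schedule.get(channel, (1, 1, None))
        return int(pre) if (switch is None or t < switch) else int(post)


def replication_shutdown_preset(**overrides) -> TimelapseConfig:
    """Scenario in which replication stops after the damage event.

    The focus density of both channels decays exponentially after the
    damage time (default half-life ~30 min), standing in for the loss
    of replication-dependent binding sites at a non-permissive
    temperature.  All other parameters keep their defaults.
    """
    kwargs = dict(density_decay_rate=np.log(2) / 30.0,
                  stoichiometry_schedule={"A": (1, 1, None), "B": (1, 1, None)})
    kwargs.update(overrides)
    return TimelapseConfig(**kwargs)


# ---------------------------------------------------------------------------
# focus placement
# ---------------------------------------------------------------------------

def _draw_width_coordinates(cell: CellOutline, n: int, mode: str,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample signed short-axis offsets according to a spatial mode.

    central:    Gaussian around the centre spline, σ = 0.1·width, so
                ≥ 90% of draws fall within ±0.2 µm in a 1 µm wide cell.
    peripheral: equal mixture of Gaussians at ±0.3·width µm (σ =
                0.07·width), producing the bimodal membrane-proximal
                distribution.
    uniform:    uniform across the width (paired with uniform area
                sampling by the caller).
    """
    half = cell.width / 2.0
    if mode == "central":
        w = rng.normal(0.0, 0.1 * cell.width, size=n)
    elif mode == "peripheral":
        side = rng.choice([-1.0, 1.0], size=n)
        w = rng.normal(side * 0.3 * cell.width, 0.07 * cell.width, size=n)
    elif mode == "uniform":
        w = rng.uniform(-half, half, size=n)
    else:
        raise ConfigError(f"unknown spatial mode {mode!r}")
    # reflect the rare tail draws back inside the membrane
    w = np.clip(w, -0.999 * half, 0.999 * half)
    return w


def place_foci(cell: CellOutline, n: int, mode: str = "uniform",
               stoichiometry: int = 1, seed=None, *, channel: str = "A",
               rng: np.random.Generator | None = None) -> list[GroundTruthFocus]:
    """Place ``n`` ground-truth foci inside a cell polygon.

    The short-axis coordinate follows the requested spatial mode; the
    long-axis coordinate is uniform over the extent available at that
    offset (so uniform mode is uniform over the polygon area up to the
    cap geometry).

    Raises
    ------
    ConfigError
        For an unknown mode or negative ``n``.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return []
    w = _draw_width_coordinates(cell, n, mode, rng)
    hmax = cell.half_length_at(w)
    l = rng.uniform(-hmax, hmax)
    out = []
    for li, wi in zip(l, w):
        # the polygon is inscribed in the true spherocylinder: draws in
        # the sliver between arc chords and the caps are pulled inward
        x, y = cell.to_global([[li, wi]])[0]
        for _ in range(60):
            if cell.contains(x, y):
                break
            li *= 0.98
            wi *= 0.98
            x, y = cell.to_global([[li, wi]])[0]
        out.append(
            GroundTruthFocus(
                cell_id=cell.cell_id,
                channel=channel,
                time_point=cell.time_point,
                position=(float(x), float(y)),
                n_molecules=int(stoichiometry),
                width_coordinate=float(wi),
            )
        )
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _rasterize_cell(cell: CellOutline, shape: tuple[int, int],
                    pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) inside a cell polygon."""
    from skimage.draw import polygon as draw_polygon

    cols = cell.vertices[:, 0] / pixel_size
    rows = cell.vertices[:, 1] / pixel_size
    rr, cc = draw_polygon(rows, cols, shape=shape)
    return rr, cc


def _add_gaussian_spot(image: np.ndarray, x_px: float, y_px: float,
                       total: float, sigma: float) -> None:
    """Add a pixel-integrated 2D Gaussian of integrated intensity ``total``.

    Uses the error-function integral over each pixel so the rendered
    flux matches ``total`` exactly (up to the ±6σ window truncation).
    """
    h, w = image.shape
    r = int(np.ceil(6 * sigma))
    x0, x1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    y0, y1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 1 - x_px) / s) - erf((xs - x_px) / s))
    fy = 0.5 * (erf((ys + 1 - y_px) / s) - erf((ys - y_px) / s))
    image[y0c:y1c, x0c:x1c] += total * np.outer(fy, fx)


def render_frame(cells: list[CellOutline], foci: list[GroundTruthFocus],
                 config: TimelapseConfig, seed=None, *,
                 copies: dict | None = None, noise: bool = True,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one fluorescence frame (float counts).

    Each focus becomes a pixel-integrated 2D Gaussian (σ =
    ``config.psf_sigma_px``) of integrated intensity
    ``n_molecules × unit_intensity``.  Unbound copies plus the
    autofluorescence equivalent contribute a uniform per-cell
    background.  With ``noise=True`` the photon part is Poisson
    distributed and Gaussian read noise plus the camera offset are
    added; with ``noise=False`` the expected image (including offset)
    is returned.

    Raises
    ------
    ConsistencyError
        If a focus lies outside every cell polygon.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    shape = (config.frame_size, config.frame_size)
    photons = np.zeros(shape, dtype=float)

    by_cell: dict[int, list[GroundTruthFocus]] = {c.cell_id: [] for c in cells}
    for f in foci:
        if f.cell_id not in by_cell:
            raise ConsistencyError(
                f"focus at {f.position} references unknown cell {f.cell_id}"
            )
        by_cell[f.cell_id].append(f)
    cell_lookup = {c.cell_id: c for c in cells}
    for f in foci:
        if not cell_lookup[f.cell_id].contains(*f.position, tol=1e-6):
            raise ConsistencyError(
                f"focus at {f.position} lies outside cell {f.cell_id}"
            )

    unit = config.unit_intensity
    base_volume = spherocylinder_volume(config.mean_length, config.mean_width)
    for cell in cells:
        rr, cc = _rasterize_cell(cell, shape, config.pixel_size)
        if rr.size == 0:
            continue
        total_copies = (copies or {}).get(cell.cell_id, config.copies_per_cell)
        bound = sum(f.n_molecules for f in by_cell[cell.cell_id])
        # autofluorescence is cytosolic and scales with cell volume
        auto = config.autofluorescence_equiv * cell.volume / base_volume
        free = max(total_copies - bound, 0.0) + auto
        photons[rr, cc] += free * unit / rr.size

    for f in foci:
        _add_gaussian_spot(
            photons,
            f.position[0] / config.pixel_size,
            f.position[1] / config.pixel_size,
            f.n_molecules * unit,
            config.psf_sigma_px,
        )

    if not noise:
        return photons + config.offset
    image = rng.poisson(photons).astype(float)
    image += rng.normal(0.0, config.read_noise, size=shape)
    image += config.offset
    return image


# ---------------------------------------------------------------------------
# time-lapse generation
# ---------------------------------------------------------------------------

@dataclass
class TimelapseResult:
    """Stacks plus ground truth from one synthetic time-lapse run."""

    config: TimelapseConfig
    stacks: dict            # channel -> (T, H, W) uint16 array
    cells: dict             # time point -> list[CellOutline]
    foci: pd.DataFrame      # ground-truth focus table
    cell_table: pd.DataFrame  # per cell/time geometry + copy numbers

    @property
    def time_points(self) -> np.ndarray:
        return self.config.time_points

    def outlines_table(self) -> pd.DataFrame:
        rows = []
        for t, cells in self.cells.items():
            for c in cells:
                for i, (x, y) in enumerate(c.vertices):
                    rows.append((c.cell_id, t, i, x, y))
        return pd.DataFrame(
            rows, columns=["cell_id", "time_point", "vertex_index",
                           "x_um", "y_um"]
        )

    def write(self, directory) -> None:
        from . import io as _io
        _io.write_timelapse(self, directory)


def _initial_cells(config: TimelapseConfig,
                   rng: np.random.Generator) -> list[CellOutline]:
    """Lay cells out on a grid of horizontal slots.

    Slots leave room for filamentation; raises ConfigError when the
    frame cannot hold ``n_cells`` non-overlapping filaments.
    """
    fov_um = config.frame_size * config.pixel_size
    margin = 1.0
    growth_factor = np.exp(
        config.growth_rate
        * max(config.duration - config.filamentation_onset, 0.0)
    )
    slot_len = min(config.mean_length * 1.3 * growth_factor + margin,
                   fov_um - margin)
    n_cols = max(int((fov_um - margin) // slot_len), 1)
    row_h = config.mean_width * 2.2
    n_rows = int((fov_um - 2 * margin) // row_h)
    if n_cols * n_rows < config.n_cells:
        raise ConfigError(
            f"frame holds at most {n_cols * n_rows} cells at these growth "
            f"settings; requested {config.n_cells}"
        )
    cells = []
    for i in range(config.n_cells):
        row, col = divmod(i, n_cols)
        length = max(
            rng.normal(config.mean_length, 0.25 * config.mean_length),
            config.mean_width * 1.2,
        )
        width = max(rng.normal(config.mean_width, 0.05), 0.6)
        cx = margin + col * slot_len + slot_len / 2.0
        cy = margin + row_h * (row + 0.5)
        cells.append(
            generate_cell(length, width, cell_id=i, centre=(cx, cy),
                          angle=0.0, time_point=0.0)
        )
    return cells


def generate_timelapse(config: TimelapseConfig) -> TimelapseResult:
    """Generate a two-channel time-lapse with full ground truth.

    Per time point and cell: length grows exponentially after
    ``filamentation_onset`` (except for the static subpopulation), the
    expected focus count is ``focus_density × area`` (Poisson), label
    copy number scales with cell volume so the mean intensity per unit
    area stays constant, and foci are placed/rendered per channel.
    Identical configs (including seed) give bit-identical output.
    """
    master = np.random.SeedSequence(config.seed)
    rng_cells, rng_foci, rng_render = (
        np.random.default_rng(s) for s in master.spawn(3)
    )
    base_cells = _initial_cells(config, rng_cells)
    static = rng_cells.random(config.n_cells) < config.static_fraction
    base_volume = {c.cell_id: c.volume for c in base_cells}

    times = config.time_points
    stacks = {ch: [] for ch in config.channels}
    cells_by_t: dict[float, list[CellOutline]] = {}
    foci_rows = []
    cell_rows = []

    fov_um = config.frame_size * config.pixel_size
    for t in times:
        cells_t = []
        for c, is_static in zip(base_cells, static):
            dt_growth = t - config.damage_time - config.filamentation_onset
            if dt_growth > 0 and not is_static:
                length = c.length * np.exp(config.growth_rate * dt_growth)
            else:
                length = c.length
            length = min(length, fov_um - 1.2)  # keep inside the frame
            cells_t.append(c.moved(c.centre, time_point=t, length=length))
        cells_by_t[t] = cells_t

        copies_t = {
            c.cell_id: config.copies_per_cell
            * c.volume / base_volume[c.cell_id]
            for c in cells_t
        }
        for c in cells_t:
            cell_rows.append(
                (c.cell_id, t, c.length, c.width, c.area, c.volume,
                 copies_t[c.cell_id])
            )

        density_scale = 1.0
        if config.density_decay_rate > 0 and t > config.damage_time:
            density_scale = np.exp(
                -config.density_decay_rate * (t - config.damage_time)
            )

        foci_t: dict[str, list[GroundTruthFocus]] = {}
        for ch in config.channels:
            mode = config.spatial_mode_at(ch, t)
            stoich = config.molecules_per_focus_at(ch, t)
            density = config.focus_density[ch] * density_scale
            ch_foci = []
            for c in cells_t:
                n = rng_foci.poisson(density * c.area)
                ch_foci.extend(
                    place_foci(c, n, mode, stoich, channel=ch, rng=rng_foci)
                )
            foci_t[ch] = ch_foci

        # optional forced co-placement of channel-A foci onto B positions
        if config.coloc_fraction > 0 and {"A", "B"} <= set(foci_t):
            b_by_cell: dict[int, list[GroundTruthFocus]] = {}
            for f in foci_t["B"]:
                b_by_cell.setdefault(f.cell_id, []).append(f)
            cell_lookup = {c.cell_id: c for c in cells_t}
            moved = []
            for f in foci_t["A"]:
                partners = b_by_cell.get(f.cell_id)
                if partners and rng_foci.random() < config.coloc_fraction:
                    b = partners[rng_foci.integers(len(partners))]
                    jitter = rng_foci.normal(0.0, 0.03, size=2)  # 30 nm
                    pos = np.asarray(b.position) + jitter
                    cell = cell_lookup[f.cell_id]
                    if cell.contains(*pos):
                        w = float(cell.to_local(pos)[0, 1])
                        f = dataclasses.replace(
                            f, position=(float(pos[0]), float(pos[1])),
                            width_coordinate=w,
                        )
                moved.append(f)
            foci_t["A"] = moved

        for ch in config.channels:
            frame = render_frame(cells_t, foci_t[ch], config,
                                 copies=copies_t, rng=rng_render)
            stacks[ch].append(np.clip(frame, 0, 65535).astype(np.uint16))
            for f in foci_t[ch]:
                foci_rows.append(
                    (f.cell_id, f.channel, t, f.position[0], f.position[1],
                     f.n_molecules, f.width_coordinate)
                )

    foci_df = pd.DataFrame(
        foci_rows,
        columns=["cell_id", "channel", "time_point", "x_um", "y_um",
                 "n_molecules", "width_coordinate"],
    )
    cell_df = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "time_point", "length_um", "width_um",
                 "area_um2", "volume_fl", "copies"],
    )
    return TimelapseResult(
        config=config,
        stacks={ch: np.stack(fr) for ch, fr in stacks.items()},
        cells=cells_by_t,
        foci=foci_df,
        cell_table=cell_df,
    )
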