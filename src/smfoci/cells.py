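"""Rod-shaped cell outlines and spherocylinder geometry.

Bacterial cells are modelled as spherocylinders: a cylinder of length
``length - width`` capped by two hemispheres of radius ``width / 2``.
Outlines live in micrometre image coordinates; pixel conversion is done
by the modules that touch images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import GeometryError

__all__ = [
    "CellOutline",
    "generate_cell",
    "spherocylinder_area",
    "spherocylinder_volume",
]


def spherocylinder_area(length: float, width: float) -> float:
    """Projected 2D area (µm²) of a rod: rectangle plus two half-discs."""
    r = width / 2.0
    return (length - width) * width + np.pi * r**2


def spherocylinder_volume(length: float, width: float) -> float:
    """3D volume (fL = µm³): cylinder plus a full sphere from the caps."""
    r = width / 2.0
    return np.pi * r**2 * (length - width) + (4.0 / 3.0) * np.pi * r**3


@dataclass(frozen=True)
class CellOutline:
    """A rod-shaped cell as a closed polygon with derived scalar geometry.

    Attributes
    ----------
    cell_id:
        Identifier, unique within one field of view / time point.
    vertices:
        ``(n, 2)`` array of (x, y) in µm; an ordered, closed, simple
        polygon (last vertex need not repeat the first).
    length, width:
        Long- and short-axis extent in µm, ``length >= width > 0``.
    area:
        Projected area in µm² (spherocylinder closed form).
    volume:
        Volume in fL (spherocylinder closed form).
    time_point:
        Minutes relative to the damage event.
    centre, angle:
        Centroid (µm) and orientation (radians, long axis vs x-axis).
    """

    cell_id: int
    vertices: np.ndarray
    length: float
    width: float
    time_point: float = 0.0
    centre: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0
    area: float = field(default=0.0)
    volume: float = field(default=0.0)

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise GeometryError(
                f"cell {self.cell_id}: need length >= width > 0, got "
                f"length={self.length}, width={self.width}"
            )
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("vertices must be an (n>=3, 2) array")
        object.__setattr__(self, "vertices", v)
        if self.area == 0.0:
            object.__setattr__(
                self, "area", spherocylinder_area(self.length, self.width)
            )
        if self.volume == 0.0:
            object.__setattr__(
                self, "volume", spherocylinder_volume(self.length, self.width)
            )
        if not self.polygon.is_valid:
            raise GeometryError(f"cell {self.cell_id}: polygon self-intersects")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the long axis."""
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    @property
    def normal(self) -> np.ndarray:
        """Unit vector across the short axis (long axis rotated +90°)."""
        return np.array([-np.sin(self.angle), np.cos(self.angle)])

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        return self.polygon.buffer(tol).contains(Point(x, y))

    def to_local(self, xy: np.ndarray) -> np.ndarray:
        """Map global µm coordinates to (long-axis l, short-axis w)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float)) - np.asarray(self.centre)
        return np.column_stack([xy @ self.axis, xy @ self.normal])

    def to_global(self, lw: np.ndarray) -> np.ndarray:
        """Map (l, w) local coordinates back to global µm coordinates."""
        lw = np.atleast_2d(np.asarray(lw, dtype=float))
        return (
            np.asarray(self.centre)
            + np.outer(lw[:, 0], self.axis)
            + np.outer(lw[:, 1], self.normal)
        )

    def half_length_at(self, w) -> np.ndarray:
        """Long-axis half-extent available at short-axis offset ``w``.

        Inside the cylindrical body this is ``(length - width)/2`` plus
        the chord of the hemispherical cap at ``|w|``.
        """
        w = np.asarray(w, dtype=float)
        r = self.width / 2.0
        chord = np.sqrt(np.maximum(r**2 - w**2, 0.0))
        return (self.length - self.width) / 2.0 + chord

    def moved(self, centre, angle: float = None, time_point: float = None,
              length: float = None) -> "CellOutline":
        """Return a copy at a new position/orientation/length."""
        length = self.length if length is None else length
        angle = self.angle if angle is None else angle
        time_point = self.time_point if time_point is None else time_point
        verts = _spherocylinder_vertices(length, self.width)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        verts = verts @ rot.T + np.asarray(centre)
        return replace(
            self,
            vertices=verts,
            length=length,
            centre=tuple(np.asarray(centre, dtype=float)),
            angle=angle,
            time_point=time_point,
            area=spherocylinder_area(length, self.width),
            volume=spherocylinder_volume(length, self.width),
        )


def _spherocylinder_vertices(length: float, width: float,
                             n_arc: int = 24) -> np.ndarray:
    """Axis-aligned spherocylinder boundary centred on the origin."""
    r = width / 2.0
    h = (length - width) / 2.0
    # right cap: -90° .. +90°, left cap: +90° .. +270°; CCW order
    th_r = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    th_l = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    right = np.column_stack([h + r * np.cos(th_r), r * np.sin(th_r)])
    left = np.column_stack([-h + r * np.cos(th_l), r * np.sin(th_l)])
    return np.vstack([right, left])


def generate_cell(length: float, width: float, seed=None, *, cell_id: int = 0,
                  centre=(0.0, 0.0), angle: float = 0.0,
                  time_point: float = 0.0, n_arc: int = 24) -> CellOutline:
    """Build a spherocylindrical cell outline.

    Parameters
    ----------
    length, width:
        Long/short axis in µm; ``length >= width > 0``.
    seed:
        Accepted for interface symmetry with the stochastic generators;
        the outline itself is deterministic.
    n_arc:
        Vertices per hemispherical cap (total ``2 * n_arc`` >= 32).

    Raises
    ------
    GeometryError
        If ``length < width`` or ``width <= 0``.
    """
    if not (length >= width > 0):
        raise GeometryError(
            f"need length >= width > 0, got length={length}, width={width}"
        )
    if 2 * n_arc < 32:
        raise GeometryError("outline needs at least 32 vertices")
    verts = _spherocylinder_vertices(length, width, n_arc=n_arc)
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    verts = verts @ rot.T + np.asarray(centre, dtype=float)
    return CellOutline(
        cell_id=cell_id,
        vertices=verts,
        length=float(length),
        width=float(width),
        time_point=float(time_point),
        centre=tuple(np.asarray(centre, dtype=float)),
        angle=float(angle),
    )
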