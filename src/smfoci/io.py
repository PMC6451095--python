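"""File formats: TIFF stacks, CSV tables, flat config files, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cells import CellOutline
from .errors import ConfigError
from .trajectories import Trajectory

__all__ = [
    "write_stack", "read_stack",
    "write_foci", "read_foci",
    "write_outlines", "read_outlines",
    "write_trajectories", "read_trajectories",
    "load_flat_config", "save_flat_config",
    "write_manifest", "write_timelapse",
]


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as 16-bit multi-page TIFF."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_foci(path, foci: pd.DataFrame) -> None:
    foci.to_csv(path, index=False)


def read_foci(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outlines(path, cells_by_time: dict) -> None:
    """Outlines CSV: cell_id, time_point, vertex_index, x_um, y_um."""
    rows = []
    for t in sorted(cells_by_time):
        for c in cells_by_time[t]:
            for i, (x, y) in enumerate(c.vertices):
                rows.append((c.cell_id, t, i, x, y))
    pd.DataFrame(
        rows, columns=["cell_id", "time_point", "vertex_index",
                       "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_outlines(path) -> dict:
    """Read an outlines CSV back into {time_point: [CellOutline, ...]}.

    Length/width/centre/angle are re-derived from the vertices by
    principal-axis analysis of the polygon boundary.
    """
    df = pd.read_csv(path)
    out: dict[float, list[CellOutline]] = {}
    for (t, cid), grp in df.groupby(["time_point", "cell_id"]):
        verts = grp.sort_values("vertex_index")[["x_um", "y_um"]].to_numpy()
        centre = verts.mean(axis=0)
        centred = verts - centre
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        angle = float(np.arctan2(axis[1], axis[0]))
        proj_l = centred @ axis
        proj_w = centred @ np.array([-axis[1], axis[0]])
        length = float(proj_l.max() - proj_l.min())
        width = float(proj_w.max() - proj_w.min())
        out.setdefault(float(t), []).append(
            CellOutline(cell_id=int(cid), vertices=verts, length=length,
                        width=min(width, length), time_point=float(t),
                        centre=tuple(centre), angle=angle)
        )
    return out


def write_trajectories(path, trajectories: list[Trajectory]) -> None:
    """Bundled trajectory table: trajectory_id, frame, time_s, intensity."""
    rows = []
    for tid, tr in enumerate(trajectories):
        for frame, (t, v) in enumerate(zip(tr.times, tr.intensities)):
            rows.append((tid, frame, t, v))
    pd.DataFrame(
        rows, columns=["trajectory_id", "frame", "time_s", "intensity"]
    ).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("trajectory_id"):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.034
        out.append(Trajectory(grp["intensity"].to_numpy(), dt=dt,
                              origin="measured"))
    return out


def _coerce(value: str):
    text = value.strip()
    lowered = text.lower()
    if lowered in ("true", "false"):
        return lowered == "true"
    if lowered in ("none", "null", ""):
        return None
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def load_flat_config(path, known_keys=None) -> dict:
    """Read a flat ``key = value`` config file.

    Lines starting with '#' are comments.  With ``known_keys`` given,
    unknown keys raise a ConfigError listing them.
    """
    config = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        config[key.strip()] = _coerce(value)
    if known_keys is not None:
        unknown = sorted(set(config) - set(known_keys))
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
    return config


def save_flat_config(path, config: dict) -> None:
    lines = [f"{k} = {v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(directory, config: dict, seed=None) -> None:
    """Run manifest: config snapshot plus versions of the key libraries."""
    import numpy, scipy, pandas, skimage, lmfit, shapely  # noqa: F401
    from . import __version__

    manifest = {
        "package": {"smfoci": __version__},
        "libraries": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-image": skimage.__version__,
            "lmfit": lmfit.__version__,
            "shapely": shapely.__version__,
        },
        "seed": seed,
        "config": {k: (v if _json_safe(v) else repr(v))
                   for k, v in config.items()},
    }
    Path(directory, "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=repr) + "\n"
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_timelapse(result, directory) -> None:
    """Write a TimelapseResult: one TIFF per channel plus CSV ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ch, stack in result.stacks.items():
        write_stack(directory / f"channel_{ch}.tif", stack)
    write_foci(directory / "ground_truth_foci.csv", result.foci)
    write_outlines(directory / "outlines.csv", result.cells)
    result.cell_table.to_csv(directory / "cells.csv", index=False)
    from dataclasses import asdict
    write_manifest(directory, asdict(result.config),
                   seed=result.config.seed)
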