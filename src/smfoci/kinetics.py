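"""Autocorrelation analysis of focus-intensity trajectories.

The normalized autocorrelation of a trajectory separates uncorrelated
noise and sub-frame binding events (which decorrelate within one frame)
from genuine binding lifetimes.  The mean ACF over an ensemble is
decomposed into a short amplitude ``a_s`` (everything that decorrelates
before the first usable lag), plus medium and long exponential
components ``a_m·exp(-τ/τ_m) + a_l·exp(-τ/τ_l)`` fitted from the first
non-zero lag onward, with ``a_s + a_m + a_l = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .errors import ConfigError, ConsistencyError, FitError
from .trajectories import Trajectory

__all__ = [
    "AcfCurve",
    "AcfDecomposition",
    "extract_trajectory",
    "autocorrelation",
    "mean_acf",
    "fit_acf_decomposition",
]


@dataclass
class AcfCurve:
    """A (possibly ensemble-averaged) normalized autocorrelation curve."""

    lags: np.ndarray            # seconds, starting at 0, step dt
    values: np.ndarray
    sem: np.ndarray | None = None
    n_trajectories: int = 1

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise ConfigError("lags and values must be matching 1D arrays")
        if self.lags[0] != 0 or np.any(np.diff(self.lags) <= 0):
            raise ConfigError("lags must increase strictly from 0")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.values.shape:
                raise ConfigError("sem must match values")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class AcfDecomposition:
    """Short/medium/long decomposition of a mean ACF.

    Amplitudes are fractions summing to one; timescales in seconds.
    ``model`` records which decay model was selected: "double",
    "single" (then ``a_m = 0`` and ``tau_m`` is undefined/NaN) or
    "degenerate" (no decay beyond lag zero, ``a_s = 1``).
    """

    a_s: float
    a_m: float
    a_l: float
    tau_m: float
    tau_l: float
    a_s_err: float = np.nan
    a_m_err: float = np.nan
    a_l_err: float = np.nan
    tau_m_err: float = np.nan
    tau_l_err: float = np.nan
    model: str = "double"

    def __post_init__(self):
        if abs(self.a_s + self.a_m + self.a_l - 1.0) > 1e-6:
            raise ConfigError("amplitudes must sum to 1")

    def as_dict(self) -> dict:
        return {
            "a_s": self.a_s, "a_m": self.a_m, "a_l": self.a_l,
            "tau_m": self.tau_m, "tau_l": self.tau_l,
            "a_s_err": self.a_s_err, "a_m_err": self.a_m_err,
            "a_l_err": self.a_l_err, "tau_m_err": self.tau_m_err,
            "tau_l_err": self.tau_l_err, "model": self.model,
        }


def extract_trajectory(stack: np.ndarray, position: tuple[float, float],
                       roi_radius_px: int = 3, *, dt: float = 0.034,
                       background: np.ndarray | float | None = None
                       ) -> Trajectory:
    """Per-frame background-subtracted intensity in a disk ROI.

    ``stack`` is (T, H, W); ``position`` is (x, y) in pixels.
    ``background`` is a per-pixel level (scalar or image) subtracted
    before summing; by default the per-frame median in an annulus
    between 1 and 2.5 ROI radii, i.e. the local diffuse cell
    background rather than the dark frame level.

    Raises
    ------
    ConsistencyError
        If the ROI is not fully inside the frame.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ConfigError("stack must be (T, H, W)")
    t, h, w = stack.shape
    x, y = position
    if not (roi_radius_px <= x < w - roi_radius_px
            and roi_radius_px <= y < h - roi_radius_px):
        raise ConsistencyError("ROI exceeds the frame")
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - x) ** 2 + (yy - y) ** 2
    disk = r2 <= roi_radius_px**2
    if background is None:
        annulus = (r2 > roi_radius_px**2) & (r2 <= (2.5 * roi_radius_px) ** 2)
        background = np.median(stack[:, annulus], axis=1)[:, None]
        values = (stack[:, disk] - background).sum(axis=1)
    else:
        values = (stack - background)[:, disk].sum(axis=1)
    return Trajectory(values, dt=dt, origin="measured",
                      focus_position=(float(x), float(y)))


def autocorrelation(traj: Trajectory, *, mean: float | None = None,
                    variance: float | None = None,
                    max_lag: int | None = None,
                    estimator: str = "biased") -> AcfCurve:
    """Normalized autocorrelation G(τ) of one trajectory.

    ``G(τ) = <δI(t) δI(t+τ)> / <δI²>`` with ``δI = I - mean``; the
    biased (1/N) estimator is used for stability at long lags, and
    ``G(0) = 1`` by construction when ``variance`` is not supplied.

    ``mean``/``variance`` default to the trajectory's own sample
    statistics; passing ensemble values instead avoids the downward
    bias of single-trajectory mean subtraction when many trajectories
    share stationary statistics.  ``estimator`` selects the 1/N
    ("biased", default — stable at long lags) or 1/(N-k) ("unbiased")
    normalization of the lag products.

    Raises
    ------
    ConfigError
        If the trajectory is shorter than 10 frames or has zero
        variance (with the chosen mean).
    """
    x = traj.intensities
    n = x.size
    if n < 10:
        raise ConfigError("trajectory too short for autocorrelation (< 10)")
    mu = float(np.mean(x)) if mean is None else float(mean)
    d = x - mu
    var = float(np.mean(d * d)) if variance is None else float(variance)
    if var <= 0:
        raise ConfigError("zero-variance trajectory has no autocorrelation")
    if max_lag is None:
        max_lag = n - 1
    if estimator not in ("biased", "unbiased"):
        raise ConfigError("estimator must be 'biased' or 'unbiased'")
    norm = float(n) if estimator == "biased" else (n - np.arange(n))
    acov = np.correlate(d, d, mode="full")[n - 1:] / norm
    values = acov[: max_lag + 1] / var
    lags = np.arange(max_lag + 1) * traj.dt
    return AcfCurve(lags=lags, values=values, n_trajectories=1)


def mean_acf(curves: list[AcfCurve]) -> AcfCurve:
    """Per-lag mean and standard error over an ensemble of ACF curves.

    Raises
    ------
    ConsistencyError
        If fewer than 2 curves are given or their lag grids differ.
    """
    if len(curves) < 2:
        raise ConsistencyError("need at least 2 curves")
    n_lags = min(c.lags.size for c in curves)
    ref = curves[0].lags[:n_lags]
    for c in curves[1:]:
        if not np.allclose(c.lags[:n_lags], ref):
            raise ConsistencyError("curves are not on a common lag grid")
    stackd = np.stack([c.values[:n_lags] for c in curves])
    mean = stackd.mean(axis=0)
    sem = stackd.std(axis=0, ddof=1) / np.sqrt(len(curves))
    return AcfCurve(lags=ref, values=mean, sem=sem,
                    n_trajectories=len(curves))


def _fit_exponentials(lags, values, weights, n_components, dt):
    """lmfit of a sum of decaying exponentials; returns the result."""
    if n_components == 1:
        model = lmfit.Model(lambda x, a_l, tau_l: a_l * np.exp(-x / tau_l))
        params = model.make_params(a_l=max(values[0], 1e-3), tau_l=10 * dt)
        params["a_l"].set(min=0, max=1.5)
        params["tau_l"].set(min=dt / 10, max=1e4)
    else:
        model = lmfit.Model(
            lambda x, a_m, tau_m, a_l, tau_ratio:
            a_m * np.exp(-x / tau_m) + a_l * np.exp(-x / (tau_m * tau_ratio))
        )
        params = model.make_params(
            a_m=max(values[0] / 2, 1e-3), tau_m=3 * dt,
            a_l=max(values[0] / 2, 1e-3), tau_ratio=10.0,
        )
        params["a_m"].set(min=0, max=1.5)
        params["a_l"].set(min=0, max=1.5)
        params["tau_m"].set(min=dt / 2, max=1e4)
        params["tau_ratio"].set(min=1.0, max=1e4)  # enforces tau_l > tau_m
    return model.fit(values, params, x=lags, weights=weights)


def fit_acf_decomposition(mean_curve: AcfCurve, fit_start: float = 0.034,
                          *, max_lag: float | None = None,
                          model: str = "auto") -> AcfDecomposition:
    """Decompose a mean ACF into short/medium/long components.

    Lags ≥ ``fit_start`` (i.e. after the sub-frame decorrelation) are
    fitted with single and double exponential decays; the double model
    is kept when it improves the Akaike information criterion, unless
    ``model`` forces "single" or "double".  The short amplitude is
    ``a_s = 1 - a_m - a_l``, with its uncertainty taken from the SEM of
    the mean curve at the first fitted lag when available.

    Raises
    ------
    ConfigError
        If fewer than 20 lags lie beyond ``fit_start``.
    FitError
        If the requested fit does not converge.
    """
    lags = mean_curve.lags
    values = mean_curve.values
    sel = lags >= fit_start - 1e-12
    if max_lag is not None:
        sel &= lags <= max_lag
    x, y = lags[sel], values[sel]
    if x.size < 20:
        raise ConfigError("need at least 20 lags beyond fit_start")
    sem0 = np.nan
    if mean_curve.sem is not None:
        sem0 = float(mean_curve.sem[sel][0])

    if np.max(np.abs(y)) < 1e-9:
        return AcfDecomposition(a_s=1.0, a_m=0.0, a_l=0.0,
                                tau_m=np.nan, tau_l=np.nan,
                                a_s_err=sem0, model="degenerate")

    weights = None
    if mean_curve.sem is not None and np.all(mean_curve.sem[sel] > 0):
        weights = 1.0 / mean_curve.sem[sel]

    dt = mean_curve.dt
    fits = {}
    for n_comp, name in ((1, "single"), (2, "double")):
        if model not in ("auto", name):
            continue
        try:
            fits[name] = _fit_exponentials(x, y, weights, n_comp, dt)
        except Exception as exc:  # pragma: no cover - lmfit raises rarely
            if model == name:
                raise FitError(f"{name}-exponential fit failed: {exc}")
    if not fits:
        raise FitError("no model converged")
    if len(fits) == 2:
        chosen = "double" if fits["double"].aic < fits["single"].aic \
            else "single"
    else:
        chosen = next(iter(fits))
    res = fits[chosen]
    if not res.success:
        raise FitError(f"{chosen}-exponential fit did not converge: "
                       f"{res.message}")

    p = res.params
    if chosen == "single":
        a_m, tau_m = 0.0, np.nan
        a_l = float(p["a_l"].value)
        tau_l = float(p["tau_l"].value)
        a_m_err = tau_m_err = np.nan
        a_l_err = _err(p["a_l"])
        tau_l_err = _err(p["tau_l"])
    else:
        a_m = float(p["a_m"].value)
        tau_m = float(p["tau_m"].value)
        a_l = float(p["a_l"].value)
        tau_l = tau_m * float(p["tau_ratio"].value)
        a_m_err = _err(p["a_m"])
        a_l_err = _err(p["a_l"])
        tau_m_err = _err(p["tau_m"])
        tau_l_err = np.nan if p["tau_ratio"].stderr is None else float(
            np.hypot(tau_m * p["tau_ratio"].stderr,
                     float(p["tau_ratio"].value)
                     * (p["tau_m"].stderr or 0.0))
        )
        # report components in timescale order (ratio >= 1 guarantees it)
    a_s = 1.0 - a_m - a_l
    return AcfDecomposition(
        a_s=a_s, a_m=a_m, a_l=a_l, tau_m=tau_m, tau_l=tau_l,
        a_s_err=sem0, a_m_err=a_m_err, a_l_err=a_l_err,
        tau_m_err=tau_m_err, tau_l_err=tau_l_err, model=chosen,
    )


def _err(param) -> float:
    return np.nan if param.stderr is None else float(param.stderr)
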