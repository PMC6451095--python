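"""Stochastic simulator for focus intensity-versus-time trajectories.

Models a complex (carrying up to ``n_mol_per_complex`` fluorescent
molecules) that binds to and dissociates from DNA as a two-state
telegraph process, molecules that exchange on the complex with their own
telegraph kinetics, and irreversible photobleaching of each molecule.
A molecule contributes signal in a frame only while it is bound to the
complex, the complex is bound to DNA and the molecule has not yet
bleached.  Poisson noise is applied at a user-defined single-molecule
signal-to-noise ratio.

Time is continuous; state trajectories are integrated over the camera
frame grid (fraction of each exposure spent emitting), which is more
faithful than per-frame Bernoulli switching when dwell times approach
the frame time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ConsistencyError

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate_state_trajectory",
    "simulate_photobleaching",
    "compose_trajectory",
    "simulate_trajectory",
    "simulate_ensemble",
    "simulate_dimer_comparison",
]


@dataclass(frozen=True)
class Trajectory:
    """An intensity-vs-time trace at a fixed position.

    Intensities are in units of the single-molecule amplitude (simulated
    traces) or camera counts (measured traces); ``dt`` is the frame time
    in seconds.
    """

    intensities: np.ndarray
    dt: float = 0.034
    origin: str = "simulated"        # or "measured"
    focus_position: tuple[float, float] | None = None

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ConfigError("intensities must be a non-empty 1D array")
        if not np.all(np.isfinite(arr)):
            raise ConfigError("intensities must be finite")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_frames(self) -> int:
        return self.intensities.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class SimulationConfig:
    """Input parameters of the trajectory simulator.

    Rates are in s⁻¹; ``tau_bleach`` is the mean photobleaching time in
    seconds of illuminated emission; ``snr`` is the mean/standard
    deviation of the single-molecule in-focus signal per frame (``None``
    disables noise).  Defaults follow the burst-acquisition geometry of
    300 frames at 34 ms and dwell times of order one second.
    """

    n_mol_per_complex: int = 1
    k_on_complex: float = 0.5
    k_off_complex: float = 0.67
    k_on_molecule: float = 1.0
    k_off_molecule: float = 0.0     # 0 -> molecules permanently attached
    tau_bleach: float = 30.0
    snr: float | None = 1.0
    n_frames: int = 300
    dt: float = 0.034
    seed: int = 0
    #: bleaching clock: "illumination" counts only emitting time (the
    #: default for continuous-excitation burst imaging); "wall" counts
    #: elapsed time regardless of emission.
    bleach_clock: str = "illumination"

    def __post_init__(self):
        if self.n_mol_per_complex < 1:
            raise ConfigError("n_mol_per_complex must be >= 1")
        for name in ("k_on_complex", "k_off_complex",
                     "k_on_molecule", "k_off_molecule"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.tau_bleach <= 0:
            raise ConfigError("tau_bleach must be > 0")
        if self.dt <= 0 or self.n_frames < 1:
            raise ConfigError("need dt > 0 and n_frames >= 1")
        if self.snr is not None and self.snr <= 0:
            raise ConfigError("snr must be > 0 or None")
        if self.bleach_clock not in ("illumination", "wall"):
            raise ConfigError("bleach_clock must be 'illumination' or 'wall'")


# ---------------------------------------------------------------------------
# sub-routine 1 & 2: telegraph state trajectories
# ---------------------------------------------------------------------------

def simulate_state_trajectory(k_on: float, k_off: float, n_frames: int,
                              dt: float, seed=None, *,
                              rng: np.random.Generator | None = None,
                              integrate: bool = True) -> np.ndarray:
    """Two-state (bound/unbound) telegraph occupancy on the frame grid.

    Dwell times are exponential with the given rates and the initial
    state is drawn from the stationary distribution
    ``p_on = k_on / (k_on + k_off)``.  With ``integrate=True`` (default)
    each entry is the fraction of that frame spent bound; otherwise the
    state at the frame start (0/1).

    Raises
    ------
    ConfigError
        If both rates are zero (no stationary distribution).
    """
    if k_on < 0 or k_off < 0:
        raise ConfigError("rates must be >= 0")
    if k_on == 0 and k_off == 0:
        raise ConfigError("k_on and k_off cannot both be zero")
    if rng is None:
        rng = np.random.default_rng(seed)
    total = n_frames * dt
    p_on = k_on / (k_on + k_off)
    state = bool(rng.random() < p_on)

    # event times of state switches in (0, total]
    edges = [0.0]
    states = [state]
    t = 0.0
    s = state
    while t < total:
        rate = k_off if s else k_on
        if rate == 0:
            break  # absorbing: stays in s forever
        t += rng.exponential(1.0 / rate)
        if t >= total:
            break
        edges.append(t)
        s = not s
        states.append(s)
    edges.append(total)

    if not integrate:
        out = np.empty(n_frames)
        frame_starts = np.arange(n_frames) * dt
        idx = np.searchsorted(edges[1:-1], frame_starts, side="right")
        out[:] = [states[i] for i in idx]
        return out

    # integrate occupancy over each frame
    occ = np.zeros(n_frames)
    for (t0, t1), s in zip(zip(edges[:-1], edges[1:]), states):
        if not s:
            continue
        f0 = int(t0 / dt)
        f1 = min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            lo = max(t0, f * dt)
            hi = min(t1, (f + 1) * dt)
            if hi > lo:
                occ[f] += (hi - lo) / dt
    occ = np.clip(occ, 0.0, 1.0)
    occ[np.abs(occ - 1.0) < 1e-9] = 1.0  # snap float dust at frame edges
    occ[occ < 1e-12] = 0.0
    return occ


# ---------------------------------------------------------------------------
# sub-routine 3: photobleaching
# ---------------------------------------------------------------------------

def simulate_photobleaching(tau_bleach: float, n_molecules: int,
                            seed=None, *,
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """One exponential bleach time per molecule (seconds).

    The returned times are budgets on the bleaching clock: with the
    default illumination-coupled clock they are consumed only while the
    molecule is emitting.

    Raises
    ------
    ConfigError
        If ``tau_bleach <= 0`` or ``n_molecules < 0``.
    """
    if tau_bleach <= 0:
        raise ConfigError("tau_bleach must be > 0")
    if n_molecules < 0:
        raise ConfigError("n_molecules must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.exponential(tau_bleach, size=n_molecules)


# ---------------------------------------------------------------------------
# signal composition
# ---------------------------------------------------------------------------

def compose_trajectory(complex_occupancy: np.ndarray,
                       molecule_occupancies: np.ndarray,
                       bleach_times: np.ndarray,
                       snr: float | None,
                       seed=None, *, dt: float = 0.034,
                       bleach_clock: str = "illumination",
                       rng: np.random.Generator | None = None) -> Trajectory:
    """Combine complex, molecule and bleaching trajectories into a signal.

    ``molecule_occupancies`` is ``(n_molecules, n_frames)``; each
    molecule emits in proportion to
    ``complex_occupancy × molecule_occupancy`` until its bleach budget
    is spent.  Each molecule contributes unit amplitude; Poisson noise
    is scaled so the single-molecule mean/sd equals ``snr`` (the Poisson
    rate per unit amplitude is ``snr²``), hence frames at level ``k``
    have variance ``k`` times the single-molecule variance.

    Raises
    ------
    ConsistencyError
        If the inputs are not on a common frame grid.
    """
    complex_occupancy = np.asarray(complex_occupancy, dtype=float)
    molecule_occupancies = np.atleast_2d(
        np.asarray(molecule_occupancies, dtype=float)
    )
    bleach_times = np.asarray(bleach_times, dtype=float)
    n_frames = complex_occupancy.size
    if molecule_occupancies.shape[1] != n_frames and molecule_occupancies.size:
        raise ConsistencyError("molecule occupancies not on the complex grid")
    if bleach_times.size != molecule_occupancies.shape[0] and \
            molecule_occupancies.size:
        raise ConsistencyError("one bleach time per molecule required")
    if rng is None:
        rng = np.random.default_rng(seed)

    signal = np.zeros(n_frames)
    if molecule_occupancies.size:
        emitting = molecule_occupancies * complex_occupancy[None, :]
        for m in range(emitting.shape[0]):
            budget = bleach_times[m]
            if bleach_clock == "wall":
                alive = np.arange(n_frames) * dt < budget
                signal += emitting[m] * alive
                continue
            # illumination-coupled clock: budget consumed while emitting
            consumed = np.cumsum(emitting[m]) * dt
            with np.errstate(over="ignore", invalid="ignore"):
                alive_frac = np.clip(
                    (budget - (consumed - emitting[m] * dt)) / np.maximum(
                        emitting[m] * dt, 1e-300),
                    0.0, 1.0,
                )
            signal += emitting[m] * np.where(emitting[m] > 0, alive_frac, 0.0)

    if snr is None:
        return Trajectory(signal, dt=dt)
    scale = snr**2
    noisy = rng.poisson(signal * scale) / scale
    return Trajectory(noisy, dt=dt)


# ---------------------------------------------------------------------------
# full simulator and the one- vs two-molecule comparison
# ---------------------------------------------------------------------------

def simulate_trajectory(config: SimulationConfig, seed=None, *,
                        rng: np.random.Generator | None = None) -> Trajectory:
    """Run the three sub-routines for one trajectory.

    1. telegraph trajectory of the complex on DNA;
    2. telegraph trajectory of each molecule on the complex
       (``k_off_molecule = 0`` makes molecules permanent residents);
    3. one exponential bleach time per molecule;
    then signal composition with Poisson noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    comp = simulate_state_trajectory(
        config.k_on_complex, config.k_off_complex,
        config.n_frames, config.dt, rng=rng,
    )
    n_mol = config.n_mol_per_complex
    if config.k_off_molecule == 0:
        mols = np.ones((n_mol, config.n_frames))
    else:
        mols = np.stack([
            simulate_state_trajectory(
                config.k_on_molecule, config.k_off_molecule,
                config.n_frames, config.dt, rng=rng,
            )
            for _ in range(n_mol)
        ])
    bleach = simulate_photobleaching(config.tau_bleach, n_mol, rng=rng)
    return compose_trajectory(
        comp, mols, bleach, config.snr, dt=config.dt,
        bleach_clock=config.bleach_clock, rng=rng,
    )


def simulate_ensemble(config: SimulationConfig, n_traj: int,
                      seed=None) -> list[Trajectory]:
    """Simulate ``n_traj`` independent trajectories (seed-deterministic)."""
    if n_traj < 1:
        raise ConfigError("n_traj must be >= 1")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    return [
        simulate_trajectory(config, rng=np.random.default_rng(s))
        for s in master.spawn(n_traj)
    ]


@dataclass
class DimerComparisonResult:
    """Matched one- vs two-molecule ensembles and their ACF decompositions."""

    trajectories_1: list[Trajectory]
    trajectories_2: list[Trajectory]
    acf_1: "object" = None            # kinetics.AcfCurve
    acf_2: "object" = None
    decomposition_1: "object" = None  # kinetics.AcfDecomposition
    decomposition_2: "object" = None


def simulate_dimer_comparison(config: SimulationConfig, n_traj: int = 150,
                              seed=None) -> DimerComparisonResult:
    """Compare complexes permanently carrying one vs two molecules.

    All parameters are held constant except ``n_mol_per_complex``
    (1 vs 2).  Doubling the per-focus intensity raises the in-focus
    signal-to-noise, which shows up in the decomposition as a reduced
    fast-decorrelating (short) amplitude ``a_s``.

    Raises
    ------
    ConfigError
        If ``n_traj < 2``.
    """
    from . import kinetics

    if n_traj < 2:
        raise ConfigError("n_traj must be >= 2")
    base_seed = config.seed if seed is None else seed
    ensembles = {}
    for n_mol in (1, 2):
        cfg = replace(config, n_mol_per_complex=n_mol)
        ensembles[n_mol] = simulate_ensemble(cfg, n_traj, seed=base_seed)

    result = DimerComparisonResult(
        trajectories_1=ensembles[1], trajectories_2=ensembles[2],
    )
    for n_mol, (acf_attr, dec_attr) in (
        (1, ("acf_1", "decomposition_1")),
        (2, ("acf_2", "decomposition_2")),
    ):
        curves = [
            kinetics.autocorrelation(tr)
            for tr in ensembles[n_mol]
            if np.var(tr.intensities) > 0
        ]
        mean = kinetics.mean_acf(curves)
        setattr(result, acf_attr, mean)
        setattr(result, dec_attr, kinetics.fit_acf_decomposition(mean))
    return result
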