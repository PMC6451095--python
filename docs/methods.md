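# Methods

## The measurement model

A labelled protein in a rod-shaped bacterium is imaged in one of two
regimes. In time-lapse mode a snapshot pair is taken every 10 minutes
for 3 hours (100 ms fluorescence exposures); in burst mode a continuous
movie of 300 × 34 ms frames is recorded. At these exposures a molecule
bound to DNA (D ≈ 10⁻⁵ µm²/s) is effectively stationary and renders as
a diffraction-limited spot, while a free molecule (D ≈ 10 µm²/s)
travels several microns per frame and contributes only to a diffuse
per-cell background. All quantification in this package rests on that
diffusional contrast: a focus is a bound molecule (or several), the
diffuse signal is the free pool plus cellular autofluorescence.

Pixels are fixed at 100 nm so that the colocalization radius of 218 nm
equals 2.18 px; all px↔µm conversions use this constant.

## Synthetic microscopy

Cells are spherocylinders: projected area `(L−W)·W + π(W/2)²`, volume
`π(W/2)²(L−W) + (4/3)π(W/2)³` (in fL). Initial lengths are normal
around 3 µm (σ = 25%), widths around 1 µm. After the damage event cells
filament: beginning at `filamentation_onset` (default 30 min) length
grows exponentially at `growth_rate` (default 0.01 /min, so a cell
roughly quadruples over 2.5 h). The growth law is exponential because
elongation without division is exponential in biomass; the rate is
therefore a relative rate (1/min), not µm/min. A `static_fraction`
of cells never filaments (default 0; mutant-like presets can raise it).

Foci are placed per channel at a constant area density (default
0.8 /µm² for channel A ≈ 2.2 foci in an average cell; 0.12 /µm² ≈ 0.3
foci for channel B), so counts grow in proportion to cell area during
filamentation — the "constant focus density" behaviour. Short-axis
placement modes:

- `central`: Gaussian around the centre spline, σ = 0.1·width, putting
  ≥ 90% of foci within ±0.2 µm of mid-cell in a 1 µm cell;
- `peripheral`: equal mixture at ±0.3·width µm, σ = 0.07·width —
  membrane-proximal, nucleoid-excluded binding;
- `uniform`: uniform over the polygon.

A channel may switch mode or stoichiometry at a set time (channel A
defaults to monomer→dimer at 30 min, emulating damage-induced
dimerization). `coloc_fraction` forces that fraction of channel-A foci
in partner-containing cells onto a channel-B position (30 nm jitter).
A `replication_shutdown_preset` decays focus density exponentially
after the damage time (half-life 30 min), emulating the loss of
replication-dependent binding sites when the replicative helicase is
inactivated.

Rendering: each focus is a pixel-integrated 2D Gaussian (σ = 1.3 px —
not stated by the imaging hardware description; chosen as typical for a
1.49 NA objective at ~540 nm with 100 nm pixels) of integrated
intensity `n_molecules × unit_intensity`. Free copies plus an
autofluorescence equivalent (2.5 molecules, scaled with cell volume)
spread uniformly over the cell's pixels. Label copies scale with cell
volume so concentration — and hence mean cell intensity — stays
constant through filamentation. The camera model is Poisson shot noise
+ Gaussian read noise (2 counts) + a constant offset (100 counts);
EM-gain excess noise is folded into the effective SNR.
`unit_intensity` defaults to `20·snr²` counts/molecule (snr = 10 →
2000), calibrated so the single-molecule peak SNR over the diffuse
background lands near `snr` at the default copy number and cell size.
Free molecules are not rendered as explicit diffusing emitters; at
these exposures their image is indistinguishable from a uniform
background, which is the diffusional-contrast argument itself.

What the generator does **not** emulate: optical aberrations and PSF
heterogeneity, cell crowding/overlap, segmentation errors (cells are
laid out on a grid and their outlines are exact), focus motion within a
trajectory, dark-state photophysics, and damage-dose response beyond
the single damage-time switch. Passing round-trip tests therefore
demonstrates internal consistency of the algorithms under realistic
noise, not performance on real microscopy.

## Focus detection

Per cell: background = median intensity inside the outline excluding
candidate-peak neighbourhoods; noise = 1.4826·MAD of the same pixels.
Candidates are local maxima of a difference-of-Gaussians response
(σ₁ = PSF σ, σ₂ = 4σ₁) that also clear `min_peak_snr` (default 3) ×
noise above background in the raw image. Nearby candidates are fitted
**jointly** as a sum of 2D Gaussians with shared width (bounded to
0.7–1.4 of the nominal PSF σ — a loose width bound would let one wide
component swallow a blended pair) and per-component centres bounded
near their starting peaks. Up to two matching-pursuit rounds subtract
the fitted spots and re-detect on the residual, recovering foci blended
into neighbours; without this, recall at ~2 foci/cell saturates near
90% because central-mode placement concentrates foci in a narrow
mid-cell band. Sub-pixel positions follow the pixel-centre convention
(pixel *i* integrates [i, i+1)). Cells touching the frame border are
discarded; a focus whose refined position leaves its cell is dropped.

The `min_peak_snr = 3` default is validated only on synthetic data.

## Stoichiometry

The single-molecule intensity unit is calibrated from photobleaching
steps in burst trajectories: change points are found by binary
segmentation (penalty `12·σ̂²·ln n`, σ̂ from first differences) with a
Welch-t merge pass (t < 3) that removes spurious splits of noisy
plateaus; the unit is the mean of downward step magnitudes within ±35%
of the kernel-density mode of the step distribution. "Return events"
of single molecules are an equivalent operational source of unit-sized
steps.

Copy number per cell: `(mean_cell_intensity × area_px)/unit − 2.5`,
clamped at zero with a warning (the autofluorescence equivalent is a
population constant; individual dim cells may undershoot it).
Concentration: `n/(V·N_A)` with V the spherocylinder volume in fL —
one molecule in 1.66 fL is 1.0 nM. Molecules per focus is the
focus-integrated intensity over the unit, reported raw and rounded.
Bound fraction: `100·(foci/cell × molecules/focus)/copies per cell`.

Flat-field correction divides by the illumination profile normalized
to its sampled maximum (a 12% centre/corner gradient is the motivating
case).

## Trajectory simulator

Three sub-routines: (1) a continuous-time two-state telegraph process
for the complex on DNA (exponential dwells at `k_on`, `k_off`,
stationary initial state); (2) the same per molecule on the complex
(`k_off_molecule = 0` makes residence permanent); (3) one exponential
bleach time per molecule. State trajectories are integrated over the
camera frame grid (fraction of each 34 ms exposure spent emitting)
rather than sampled per frame — more faithful when dwell times approach
the frame time; point sampling is available via `integrate=False`.
A molecule emits only while (bound to complex) ∧ (complex on DNA) ∧
(unbleached). The bleaching clock is illumination-coupled by default
(budget consumed only while emitting, matching continuous-excitation
burst imaging); a wall-clock variant is selectable. Noise: the frame
signal `s` (in single-molecule units) becomes `Poisson(s·snr²)/snr²`,
so the single-molecule mean/sd is `snr` and level-k frames have k-fold
the single-molecule variance — the mapping of the "signal-to-noise
parameter" onto a Poisson scale is a documented convention (`snr²`).
"User-defined distributions" of rates are read as fixed rates with
exponential dwells (the degenerate single-rate case).

Defaults (`k_on = 0.5 /s`, `k_off = 0.67 /s`, τ_bleach = 30 s,
snr = 1, 300 × 34 ms) give dwell times of order a second — the regime
the decomposition targets — with bleaching slow compared to them.

The dimer comparison simulates matched ensembles identical except for
1 vs 2 permanently resident molecules. Doubling the per-focus signal
doubles the correlated variance ~4× while Poisson noise only doubles,
so the uncorrelated (short) fraction of the ACF drops — the signature
that distinguishes "dimerization raises SNR" from "longer binding".

## Autocorrelation analysis

Per trajectory, `G(τ) = ⟨δI(t)δI(t+τ)⟩/⟨δI²⟩` with mean subtraction,
so G(0) = 1; the 1/N (biased) estimator is the default for stability at
long lags. For oracle comparisons the ensemble mean/variance and the
1/(N−k) estimator can be requested — single-trajectory mean subtraction
biases the ACF down by ~2τ_c/T, which matters when validating against
closed forms. The ensemble mean ACF carries per-lag SEMs.

The decomposition fits `a_m·e^(−τ/τ_m) + a_l·e^(−τ/τ_l)` (τ_l > τ_m
enforced by a ratio ≥ 1 parameterization) and the single-exponential
special case to lags ≥ 0.034 s, weighting by 1/SEM when available, and
keeps the double model when it lowers the AIC. `a_s = 1 − a_m − a_l`;
its uncertainty is the SEM at the first fitted lag. A curve with no
decay beyond lag 0 is reported as degenerate with a_s = 1. Timescales
are fitted freely per condition (a shared-timescale mode can be
emulated by fixing parameters in `lmfit` but is not the default).
Photobleaching is not detrended before fitting; validation ensembles
keep τ_bleach ≫ fitted timescales instead.

## Colocalization

A channel-A focus is colocalized when ≥ 1 same-cell channel-B centroid
lies within 218 nm (inclusive — "within" resolved inclusively);
directions are computed independently, so percentages are asymmetric
whenever counts differ. Matching is "at least one partner", not
one-to-one assignment. The chance baseline is
`mean over cells of min(1, n_B·πr²/area) × 100`; overlap between
partner discs is ignored (summed, clamped), valid at the observed
densities of ≲ 5 foci per ~4 µm² cell — at those densities the
analytic baseline agrees with Monte-Carlo placement to within 0.5
percentage points, the residual gap coming from search discs clipped
by the cell membrane. Distance histograms use equal-area annulus bins,
`r_k = r_max·√(k/n)`, so uniform partner density is flat.

## Short-axis profiles

The centre spline of a (straight) rod is its principal axis through
the centroid; the width coordinate is the signed perpendicular offset,
with an arbitrary but fixed per-cell side convention (profiles are
reported in both folded and unfolded form where symmetry matters).
Curved or bent cells are not modelled — the generator produces straight
rods, and the midline reduces to the axis exactly. Width histograms
use bins centred on 0 with mirror-symmetric edges. Line-scan contours
average focus-enhanced (difference-of-Gaussians, negatives clipped)
cross-sections perpendicular to the spline over the cylindrical body of
each cell, resampled onto a common ±0.6 µm width axis, then over cells,
one row per time point; the membrane reference for ~1 µm cells sits at
±0.5 µm. The exact digital filters of the original line-scan tool are
not published; difference-of-Gaussians is the substitute, validated on
synthetic data only.

## Numerical choices and degenerate inputs

- Seeds: every stochastic stage derives independent generators from a
  single `SeedSequence`, so identical configs are bit-identical.
- Frame-integration float dust (occupancies at 1−1e−16) is snapped.
- Zero-variance trajectories are rejected for ACF analysis and skipped
  in ensembles; a flat cell interior yields no detections rather than
  an error; an empty mask segments to an empty list.
- Negative copy numbers clamp to zero with a warning; negative
  intensities and non-positive volumes/units raise configuration
  errors.
- Change-point detection guards σ̂ = 0 (noise-free staircases) with a
  scale-relative floor.

## Problem sizes used in validation

Round-trip tests run at 60–100 cells per field (512×512 px), 150–200
trajectories of 300 frames per ensemble, 10 seed replicates for the
dimer comparison, and 10⁴ Monte-Carlo placements for the chance
baseline — sizes at which the targeted tolerances (10–15%) are several
standard errors wide. The full suite and the acceptance script each
complete in well under five minutes on one CPU.
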