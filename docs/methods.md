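# Methods

This note documents the models implemented in `minibeam`, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic data can and cannot validate.

## Lattice dose model

Pencil minibeams are idealised as 2-D isotropic Gaussians of standard
deviation σ placed on a square grid of spacing ctc, with beam centers at
integer multiples of ctc so that the unit cell is [−ctc/2, ctc/2]² and
the valley sits at the cell corners. The single-beam amplitude is fixed
by the field-mean dose of the *infinite* lattice,
A = D̄·ctc²/(2πσ²), which makes every derived quantity at fixed D̄ a
function of σ/ctc alone. The lattice sum is separable,
D(x, y) = A·θ(x)·θ(y) with θ(x) = Σᵢ exp(−(x−i·ctc)²/2σ²), which gives

* the analytic PVDR = [θ(0)/θ(ctc/2)]², evaluated in the log domain
  (at σ/ctc ≲ 0.05 the valley underflows double precision and the PVDR
  is reported as +inf);
* fast rendering of dose maps as an outer product of 1-D sums.

The sum is truncated at K = ⌈6σ/ctc⌉ + 1 lattice neighbours (tail
< 1e−8 relative); tests verify K vs 2K agreement below 1e−6. Finite
n×n grids are centred on the origin (a 1×1 grid is a single beam at the
origin); they use the same separable evaluation over the n beam
positions. Square top-hat beams concentrate the unit-cell dose into the
beam area, peak = D̄·(ctc/width)².

Maps are rendered on midpoint pixel grids (default 256 px per ctc,
coarser than ctc/32 is rejected), so whole unit cells average to D̄ to
better than 1e−3. Profiles are cut along the lattice diagonal — the
only straight line showing both the absolute maxima and the absolute
(corner-valley) minima — with bilinear interpolation; peak spacing along
the cut is ctc·√2.

**Profile PVDR.** Peaks are detected by prominence (default 5% of the
profile span, which rejects noise bumps on beam flanks); each valley is
the minimum between two consecutive peaks. The PVDR is mean-peak over
mean-valley with Gaussian error propagation of the two standard errors.
When the valley mean falls below a configurable noise floor (default
0.5% of the peak mean — film measurements do not resolve deeper
valleys), the result is flagged as a lower bound, peak/floor. The floor
is a free parameter because the actual film noise level is
setup-dependent.

**Beam-size fits.** σ is estimated by nonlinear least squares of a
four-parameter Gaussian (amplitude, center, σ, baseline). For film-like
data with multiplicative darkening noise, `relative_noise=True` switches
to a signal-weighted fit restricted to pixels above 5% of the peak with
the baseline pinned at the tail level; this makes the reported standard
error consistent with the noise model (unweighted fits underestimate it).
On noiseless data the residual variance is zero and the standard error
is reported as 0.

An ideal-Gaussian caveat: at σ/ctc ≈ 0.31 the ideal lattice predicts
PVDR ≈ 3.3 while film measurements of the corresponding pattern report
2.69 ± 0.19. Real beam tails and film response plausibly lower the
measured value; the toolkit reports the ideal value and the
profile-extracted value side by side and does not force agreement.

## Fluence dosimetry

For a thin slab in which LET is nearly constant (a ~0.2 mm ear
traversed by 20 MeV protons, LET ≈ 2.7 keV/μm), mean dose is fluence ×
mass stopping power: D = N·LET/(ρ·A), with 1 keV = 1.602×10⁻¹⁶ J and
ρ = 1 g/cm³ for soft tissue. The reference conditions (16 beams ×
4.58×10⁸ protons, 51.84 mm²) give 61.1 Gy; the inverse returns
4.49×10⁸ protons per beam for exactly 60 Gy — about 2% below the
reference count, a residual that may reflect the "~" precision of the
quoted LET or an embedded dead-time convention, and is left unreconciled.
The proton count is interpreted per beam (the total-count reading yields
an implausible 3.8 Gy).

Dead-time correction: factor 1/(1−loss) from a loss fraction, or the
low-rate/high-rate darkening ratio of two films exposed to the same
nominal count (assuming a linear film response over the correction
range; no calibration curve is modelled). For a non-paralyzable counter
the loss-fraction correction is exact, which the tests verify up to 30%
loss.

## Beam transport

Range–energy uses the Bragg–Kleeman power law R = αE^p with water
defaults α = 0.0022 cm·MeV⁻¹·⁷⁷, p = 1.77 (configurable); the two
directions are exact inverses. These constants give 78.8 and 106.3 MeV
for 5.0 and 8.5 cm ranges. For 20 MeV they give 4.4 mm, ~5% below the
~4.6 mm quoted for the experimental setup — detector geometry may be
included in that figure; not reconciled.

Lateral spread uses Fermi–Eyges integration of the Highland formula:

σ_mcs²(d) = [1 + 0.038·ln(d/X₀)]² · ∫₀ᵈ (14.1 MeV / p(z)v(z))² (d−z)²/X₀ dz

with X₀ = 36.08 g/cm² (water), pv from the residual kinetic energy via
the Bragg–Kleeman residual range, and the log factor clamped at 0.25 for
unphysically shallow depths. The integral is composite Simpson with
step doubling from 64 panels to a 1e−4 relative tolerance. The initial
spot size adds in quadrature. This analytic transport stands in for
tabulated scattering databases; it reproduces the expected depth scale
(σ ≈ 766 μm at 5 cm for 107 MeV entering at σ₀ = 95 μm, within ~13% of
the 883 μm the tabulated data give) and is treated as qualitative to
±25%. Nuclear interactions, energy straggling and the depth–dose curve
are out of scope — only lateral σ is transported.

`plan_ctc` encodes the homogeneous-tumor-coverage rule: the largest ctc
such that the PVDR at the proximal target edge stays below a cap
(default 1.11, the measured near-homogeneous value), found by bisection
on the monotone σ/ctc → PVDR map. It is scale-invariant: doubling σ
doubles the planned ctc.

## Survival averaging

Clonogenic survival follows the linear-quadratic model
S = exp(−αD − βD²) with keratinocyte defaults α = 0.2 Gy⁻¹,
β = 0.06 Gy⁻². The tissue-level quantity is the *mean of survival* over
one unit cell (not survival at the mean dose): survival is evaluated
pixel-wise on a midpoint grid over the unit cell and averaged. The
implementation works in units of ctc, so only σ/ctc and the mean dose
enter; log-survival is accumulated and exponentiated under suppressed
underflow, since peak doses reach thousands of Gy where S underflows
harmlessly to zero. The grid starts at 512² (evaluated on one
mirror-symmetric quarter cell) and doubles until the mean changes by
less than 1e−3 relative, erroring out at 8192² rather than returning an
unconverged value.

The LQ model is only validated to ~10 Gy; an optional log-linear
high-dose extension (matched value and slope at a configurable
transition, default off / 10 Gy when on) is exposed. At 60 Gy mean dose
it changes the unit-cell mean only marginally on the percent scale,
because the average is dominated by the valley region.

An independent cross-check used in the tests: for small σ/ctc the beams
do not overlap and the survival deficit reduces to a 1-D radial
integral, S̄ = 1 − (2πσ²/ctc²)·∫₀^A [1−S(u)]/u du. The 2-D average
agrees with this oracle within 1% for σ/ctc ≤ 0.1 (≈ 0.866 at 0.053).
A published summary figure of >90% survival below σ/ctc = 0.1 is *not*
reproduced by this procedure (the oracle gives ≈87% at 0.053 and ≈60%
at 0.1); the integration choices behind that figure are not recoverable,
so the toolkit reports its computed values and documents the
discrepancy instead of tuning toward it.

## Response analysis

Per mouse and day, the three thickness replicates are averaged first;
group mean and SEM are then taken across the (≥2) mice. Missing days
are left absent — the measurement schedule is irregular by design — and
no imputation is performed. The skin score is the sum of the erythema
scale {0, 0.5, 1.5, 3} and desquamation scale {0, 1, 2, 3}; off-scale
values are rejected at validation.

"Maximum ear thickness" is read off the group-mean curve (a per-mouse
maximum would be systematically inflated by noise; the group-curve
reading also matches how mean±SEM time courses are summarised). t₅₀ is
the first linearly interpolated crossing of half the maximum swelling,
measured against a baseline that defaults to the contemporaneous
control-group mean; t₅₀ ≤ day-of-max by construction.

The threshold fit is ordinary least squares of the irradiated groups'
maximum thickness on σ/ctc, excluding the control (it carries no
radiation effect and would bend the line). The no-effect geometry is
the intersection with the control thickness:
ratio_min = (t₀ − intercept)/slope, σ_min = ratio_min·ctc,
FWHM = 2√(2 ln 2)·σ_min. Values are reported unrounded.

Group comparisons use a two-sided Welch t-test on a per-mouse scalar
(default: maximum thickness). This is a declared convention — the
original analyses do not name their test — and the tests cross-check it
against a permutation test. The ±0.5 scoring accuracy is treated as a
reporting uncertainty and not propagated into fits.

## Synthetic data

The generator reproduces the study design: 7 groups (σ/ctc = 0,
0.053, 0.11, 0.17, 0.228, 0.312, 0.491) × 8 mice, triplicate
measurements on a 1–4-day schedule over 90 days. Group swelling
amplitude is linear in σ/ctc above a threshold:
amplitude = max(0, 840.6 μm·(ratio − 0.032)), the slope derived from the
calibration endpoints (610 μm maximum thickness at ratio 0.491 over a
225 μm control baseline, threshold 0.032). The time course is an
invented parametric stand-in — the experimental curves are plotted but
not parameterised — consisting of a gamma-shaped pulse
amplitude·(t/t_peak)^k·exp(k(1−t/t_peak)) with k = 4 and t_peak rising
linearly from 18 d (smallest ratio) to 32 d (largest), matching the
observed later-peak trend, plus a logistic rise to a 35 μm residual
plateau for ratios > 0.23, centred 15 d after the pulse peak so the
calibrated pulse maximum is preserved (the residual thickening is a
late effect). The t_peak endpoints are placeholders (no printed
numbers exist) and config-overridable. Noise: inter-mouse baseline SD
12 μm, per-replicate measurement SD 8 μm. Scores are derived by
thresholding each mouse's measured mean swelling (thresholds 30/80/200
μm for erythema, 50/120/250 μm for desquamation), which yields
group-shifted onsets and values confined to the clinical lattices. All
randomness comes from a single `numpy.random.default_rng(seed)` stream;
(config, seed) reproduces the CSV byte-for-byte.

What passing the end-to-end test shows: the analysis pipeline recovers
the generator's threshold with |bias| < 0.005 and RMSE < 0.015 over 100
seeds *under this model* — linear amplitude, Gaussian noise,
no dropout, no day-to-day correlation. Real data add scorer
subjectivity, autocorrelated within-mouse fluctuations and possible
attrition, none of which the generator emulates; the recovery result
validates the estimator's implementation, not its robustness to those
effects. Film images likewise carry only white multiplicative/additive
pixel noise, not the spatial autocorrelation of real scanned film.

## Problem sizes and determinism

Default sizes keep every computation interactive on one CPU: 512²–2048²
unit-cell grids for survival averages, 256 px/ctc dose maps, 100-seed
Monte-Carlo checks for generator calibration and threshold recovery
(a few seconds each), Simpson depth quadrature with ≤ 65536 panels.
The acceptance script is fully deterministic; its `--seed` argument
pins any future stochastic additions and is recorded in provenance.
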