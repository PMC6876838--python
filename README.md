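# minibeam

Modelling toolkit for **proton pencil-minibeam radiotherapy** — spatial
fractionation of a proton field into sub-millimetre Gaussian pencil beams
on a square lattice — and for the mouse-ear skin-response experiments
used to quantify its healthy-tissue sparing.

Spatially fractionated fields spare normal tissue because cells between
the beams see only the valley dose. For Gaussian beams of standard
deviation σ on a square grid of center-to-center distance *ctc*, the
entire dose modulation at a fixed field-mean dose is governed by the
single dimensionless ratio **σ/ctc**. The package covers the full
computational chain around that parameter:

* **`grid_dose`** — lattice dose maps `D(x,y) = A·Σᵢⱼ exp(−[(x−i·ctc)² +
  (y−j·ctc)²]/2σ²)` with the amplitude `A = D̄·ctc²/(2πσ²)` normalising an
  infinite lattice to a mean dose D̄; analytic peak-to-valley dose ratio
  `PVDR = [θ(0)/θ(ctc/2)]²` from the separable 1-D lattice sum θ; diagonal
  profile cuts, profile-based PVDR with uncertainty (and lower bounds when
  valleys fall below a film noise floor), Gaussian beam-size fits, and the
  top-hat peak dose `D̄·(ctc/w)²`.
* **`fluence_dosimetry`** — proton counts → dose via `D = N·LET/(ρ·A)`
  for a thin slab of near-constant LET, its inverse, and dead-time
  correction factors from loss fractions or film darkening ratios.
* **`beam_transport`** — Bragg–Kleeman range–energy `R = αE^p`
  (α = 0.0022 cm·MeV⁻¹·⁷⁷, p = 1.77 in water) and lateral beam growth
  σ(d) = √(σ₀² + σ_mcs(d)²) from Fermi–Eyges integration of the Highland
  multiple-Coulomb-scattering formula; `plan_ctc` returns the largest
  lattice spacing whose proximal PVDR stays under a homogeneity cap.
* **`survival_model`** — linear-quadratic clonogenic survival
  `S = exp(−αD − βD²)` (keratinocyte defaults α = 0.2 Gy⁻¹,
  β = 0.06 Gy⁻²) averaged over one lattice unit cell; depends only on
  σ/ctc and the mean dose.
* **`response_pipeline`** — longitudinal ear-thickness/skin-score
  analysis: group mean ± SEM time courses, maximum swelling and the
  half-maximum time t₅₀, Welch group comparisons, and the linear
  extrapolation of maximum thickness vs σ/ctc to the control level,
  yielding the no-effect geometry σ_min/ctc (and σ_min, FWHM).
* **`synthetic_data`** — a calibrated generator of per-mouse datasets
  (7 groups × 8 mice × 90 days) and noisy film-like dose images, so the
  whole pipeline is testable without animal data.
* **`pipeline` / `minibeam` CLI** — one YAML-configured entry point tying
  simulate → analyse → dose/survival into a single JSON report.

## Worked example

The study conditions: 60 Gy mean dose, ctc = 1.8 mm, beam sizes
σ = 95…883 μm (σ/ctc = 0.053…0.491).

```console
$ minibeam dose-from-counts --protons-per-beam 4.58e8
mean dose = 61.143 Gy
```

16 beams of 4.58×10⁸ protons at LET 2.7 keV/μm over 7.2 × 7.2 mm² give
61.1 Gy — the nominal 60 Gy within the counting-dosimetry uncertainty.

```console
$ minibeam pvdr --sigma 883 --ctc 1800
sigma/ctc = 0.4906  PVDR = 1.07166
```

The largest studied beam is nearly homogeneous (PVDR ≈ 1.07; the film
measurement gave 1.11 ± 0.10).

```console
$ minibeam survival-curve --ratios 0.053,0.11,0.17,0.228,0.312,0.491 --mean-dose 60
ratio,mean_survival
0.053,0.865814
0.11,0.533007
0.17,0.109056
0.228,0.00047547
0.312,2.11995e-29
0.491,6.13322e-95
```

Mean unit-cell keratinocyte survival collapses from 87% at the smallest
ratio to effectively zero for near-homogeneous fields — the computational
counterpart of the observed tissue sparing.

```console
$ minibeam transport --range 8.5
energy = 106.30 MeV
range = 8.500 cm
$ minibeam plan-ctc --sigma-proximal 883 --pvdr-max 1.11
ctc = 1883.2 μm (PVDR 1.1100)
```

A tumor spanning 5–8.5 cm depth needs ~79–107 MeV protons; a beam that
has widened to σ = 883 μm at the proximal edge merges into a
near-homogeneous field (PVDR ≤ 1.11) for ctc ≲ 1.9 mm — consistent with
the 1.8 mm grid used on the skin.

```console
$ minibeam run --seed 0 --out-dir out
{
 "slope_um": 854.6256134977181,
 "intercept_um": 198.93434338312366,
 "r_value": 0.999792772818487,
 "ratio_min": 0.03410330063774896,
 "sigma_min_um": 61.38594114794813,
 "fwhm_min_um": 144.55284469827842,
 "slope_stderr_um": 8.7006514950819
}
```

The full pipeline simulates the 56-mouse study, fits maximum ear
thickness against σ/ctc (here R = 0.9998) and extrapolates the
no-swelling threshold: for this seed ratio_min ≈ 0.034, i.e. σ_min ≈
61 μm (FWHM ≈ 145 μm) at ctc = 1.8 mm. Across seeds the estimate
scatters around the generator truth of 0.032 with an RMSE of about
0.007; `out/report.json` holds the per-group statistics, PVDR table and
survival curve.

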