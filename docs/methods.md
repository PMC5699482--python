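# Methods

`stochdec` is a simulation and acquisition-engineering toolkit for
low-RF-power proton decoupling in carbon-13 magnetic resonance
spectroscopy (MRS) of the carboxylic/amide spectral region (169–185 ppm).
This note documents the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Scientific setting

In vivo ¹³C-MRS conventionally detects alkanyl carbons (10–65 ppm), whose
large one-bond couplings (¹J_CH = 125–145 Hz) demand decoupling fields
γB₂ well above 1 kHz.  Because decoupling power grows quadratically with
static field, composite-pulse decoupling (WALTZ) collides with SAR
(specific absorption rate) safety limits above roughly 4 T.  The
carboxylic/amide carbons of glutamate, glutamine, aspartate, NAA and
GABA, by contrast, couple to protons only through weak long-range
couplings of a few Hz, which broadband *stochastic* (random) decoupling
removes with a nominal γB₂ of order 100 Hz.  Two further power-saving
mechanisms are modelled here: frequency-domain windowing of the
stochastic waveform (its spectral components in the empty 3.90–6.83 ppm
proton window are wasted and can be filtered out), and time-domain random
under-sampling (the decoupler is gated off during randomly chosen
segments of acquisition and the spectrum restored by an iterative
reconstruction).

## Spin model (`spinsim`)

A single heteronuclear ¹H–¹³C pair of spins-½ in the doubly rotating
frame, with the weak-coupling Hamiltonian

    H/2π = δ_H H_z + δ_C C_z + J H_z C_z + γB₂(t) [H_x cos φ(t) + H_y sin φ(t)]

(δ in Hz, J in Hz, proton-first product-operator basis).  Free evolution
of transverse carbon magnetization obeys σ(t) = C_x cos(πJt) +
2C_yH_z sin(πJt), and a selective proton 180°ₓ at time t refocuses the
coupling, σ(2t) = C_x; both closed forms serve as oracles in the test
suite (agreement better than 1e-8 / 1e-9).

**Propagation is exact, not time-stepped.**  All supported waveforms are
piecewise constant, so each segment's propagator is the exact matrix
exponential, evaluated through a cached eigendecomposition keyed by
(amplitude, phase).  No integration-step parameter exists and no
discretization error is incurred; unitarity, trace and eigenvalue
preservation hold to 1e-10 in the tests.  Relaxation, when enabled, is
phenomenological: off-diagonal density-matrix elements are damped by
exp(−dt/T₂) per segment.

**Acquisition.**  The carbon FID is Tr(ρ(C_x + iC_y)) sampled at 1/SW
from ρ(0) = C_x.  With a gate mask, irradiation runs only during sampled
intervals; during skipped intervals the spins evolve freely and the
waveform cursor does not advance (decoupler truly off, saving power).
Waveforms shorter than the acquisition repeat cyclically.

**Decoupling metrics.**  `decoupling_profile` reports, per proton offset:
the centerband fraction (share of spectral magnitude within
max(J/4, 2 bins) of the carbon line — strictly inside the undecoupled
doublet at ±J/2), the residual splitting (distance between the two
largest interpolated maxima, zero when the second is below 10% of the
first), and the FWHM of the largest peak.  Peak positions are refined by
quadratic interpolation; FWHM crossings by linear interpolation.  A
single stochastic realization leaves random "decoupling noise" sidebands
that can exceed the 10% picker threshold; an ensemble of waveforms can
therefore be passed, whose FIDs are averaged before analysis.  This
mirrors in vivo accumulation (NS ≥ 100 with an ongoing pseudo-random
modulation): sidebands average down as 1/√N while the centerband adds
coherently.  Profiles in the benchmark use 8 transients, 256 points at
SW 100 Hz — enough to resolve a 5 Hz doublet in ~2 s of simulated
acquisition while keeping the suite fast.

## Decoupling waveforms (`waveforms`)

Waveforms carry per-sample (amplitude [Hz of γB₂], phase [deg]) on a
uniform raster; the complex representation is A·exp(iφ).

* **CW** — constant amplitude, zero phase; baseline for profiles.
* **WALTZ-4/16** — built from the composite inversion block
  S = 90°ₓ 180°₋ₓ 270°ₓ (a θ° pulse lasts θ/360/γB₂ s; the raster dwell
  is the 90° duration so every pulse is exact).  WALTZ-4 = S S S̄ S̄.
  WALTZ-16 is expanded as the MLEV-style supercycle W W′ W′ W with W′ the
  phase-inverted WALTZ-4 — one of the equivalent published phase-cycle
  conventions; at the very low γB₂ relevant here the choice among
  supercycle conventions is immaterial to the simulated performance,
  which is dominated by the sub-kHz bandwidth.
* **Pseudo-stochastic (Ernst)** — constant amplitude, i.i.d. equiprobable
  {0°, 180°} phases per sub-pulse, seeded.  The decoupling bandwidth is
  the sub-pulse repetition rate 1/τ.  The default τ is chosen so that the
  band covers the full coupled-proton range: the protons scalar-coupled
  to carboxylic/amide carbons cluster in 1.91–3.90 ppm (alkyl) and
  6.83–7.60 ppm (amide); with the 0.1 ppm filter margins the span is
  1.81–7.70 ppm = 5.89 ppm, so τ = 1/(5.89 ppm × f0_MHz) with the carrier
  at the band centre, 4.755 ppm.  One raster sample per sub-pulse is the
  natural sampled representation (amplitude and phase are constant within
  a sub-pulse), making the discrete spectrum white across the repetition
  bandwidth.
* **Vectorial noise** — i.i.d. phases uniform on [0°, 360°) and, as a
  documented modelling choice, amplitudes uniform on [0, peak] (expected
  power peak²/3); only "random amplitude and phase" is prescribed by the
  source experiments, so the amplitude law is configurable.

**Windowing.**  `window_waveform` multiplies the DFT of the complex
waveform by an ideal 0/1 multi-bandpass mask (band edges mapped to the
nearest DFT bin; real and imaginary spectral components masked
identically, i.e. the complex bins) and inverse transforms.  By
Parseval/Rayleigh the output power equals the in-band fraction of the
input's spectral power; windowing is exactly idempotent.  For the double
bandpass over the coupled-proton regions at 500 MHz, the expected
retained fraction of a white pseudo-stochastic sequence is the band
measure over the repetition bandwidth, (2.19 + 0.97)/5.89 ≈ 53.7%, and
the benchmark measures ≈53.5% — the commonly quoted experimental figure
is 51.4%, and since the experimental sub-pulse duration is not published
the few-percent difference is attributable to that unknown.  Note the
two readings in circulation ("power reduced by 51.4%" vs "power at 51.4%
of the original"); this package always reports the **retained** ratio.

## Power and SAR accounting (`power_sar`)

Time-averaged transmitted power RF_ave = RF_DEC·DC_DEC + RF_NOE·DC_NOE;
local SAR_max = SAR₁₀g × RF_ave; averaged SAR = RF_ave/M.  SAR₁₀g (the
normalized maximum local SAR per 10 g tissue at 1 W absorbed) comes from
external electromagnetic simulation and is strictly an input; M (head
mass, kg) has no default and must be supplied.  Regulatory thresholds are
config inputs, never hard-coded.  Savings compose multiplicatively:
1 − (1−w)(1−g) for windowing fraction w and gating fraction g.  Gating
saving equals the skipped fraction of the sampling pattern exactly,
because SAR accumulates linearly with decoupling duration.

## Under-sampling and reconstruction (`undersampling`)

**Terminology.**  `skip_rate` is the fraction of acquisition points NOT
sampled (= fractional decoupling power saving).  The originating
literature sometimes formally defines "under-sampling rate" as the
sampled percentage while using it as the skipped fraction; the skipped
reading — consistent with "errors grow with the rate" and "30% rate ↔
30% power saving" — is used throughout.

**Patterns.**  A fully sampled leading core (default 20%) followed by
skipped segments (default 8 points; the realized skip count is
⌈skip_rate·n⌉, so 30% of 1024 points skips 308).  `random_segments`
drops segments at seeded random positions; `coherent` drops them at
regular spacing as the comparison strategy.

**Iteration.**  Unsampled points are zero-filled; then, per iteration:
forward FFT → zero the empty frequency group Z (keep the signal group P)
→ inverse FFT → compute ε_n between the updated series and the measured
data over the sampled points s → stop if ε_n < tolerance (default 1e-6),
else restore the measured data on s and continue, up to max_iter
(default 5000).  Non-convergence is a flagged result, not an error — it
typically indicates too high a skip rate or data inconsistent with the
support (e.g. noise).  ε_n is, by default, the summed (l2) difference
relative to the l2 norm of the measured data: an absolute threshold of
10⁻⁶ is meaningless without a scale; absolute and max-norm modes are
available.  The projection onto Z is applied from the first pass — on the
zero-filled series this is identical to starting the projection at the
second iteration with restored data, since the zero-filled series *is*
the restored data at iteration one.  The **delivered spectrum** is the
FFT of the final time series with the measured data restored on s (the
data-consistency step is always the last applied): sampled noise is
retained, unsampled points carry the support-consistent fill.  This is
the object on which intensity errors and noise statistics are measured.

**Support construction and conditioning.**  `build_support` offers two
rules.  The default thresholds the reference magnitude at 1% of its
maximum and dilates by a guard band (default 6 Hz ≈ 2× a 3 Hz
linewidth).  Alternatively P is built from a peak list as shift ± k
linewidths (default k = 2).  The distinction matters more than it
appears: a complex Lorentzian decays only as 1/f off-resonance (the
dispersion component), so the 1% threshold chases tails tens of bins
wide and yields a broad, nearly contiguous P.  Estimating a wide
contiguous frequency band from gappy time samples is a prolate-type
problem with exponentially decaying singular values (condition numbers
~10⁵ at the default sizes), and the iteration then *semiconverges* on
noisy data: intensity errors are small after tens of iterations but
degrade toward the noise-amplifying least-squares solution by iteration
5000.  Narrow peak-window supports keep the problem well conditioned
(condition ~2) at the same total sampling.  The benchmarks therefore use
the peak-window rule — which is also the physical definition of P, "bins
belonging to a metabolite peak" — while the threshold rule remains the
default for data without a known peak list.

**Baseline premise.**  The reconstruction assumes Z-bins are genuinely
empty *after baseline removal*.  For raw synthetic Lorentzians this is
false at the several-percent level (dispersion tails), which both stalls
convergence and biases narrow-P reconstructions.  In vivo pipelines
subtract a fitted baseline model before reconstructing;
`remove_model_baseline` plays that role for synthetic data by
subtracting the out-of-support component of the noise-free model (a
time-domain, pointwise subtraction, hence applicable to under-sampled
data).  A generic low-order polynomial baseline estimator
(`estimate_baseline`/`remove_baseline`) is provided for data without a
model.  With the premise restored, noiseless reconstructions converge in
tens of iterations and the fully-sampled input is an exact fixed point.

**Error metric.**  Per-peak intensity is the magnitude of the complex
integral over the peak window (shift ± 2 linewidths); error is the
percent deviation from the fully sampled spectrum of the same dataset.
When averaging over repeated datasets the benchmark averages *signed*
errors and then takes the absolute value — the convention used for
multi-subject means — so unbiased noise cancels and the reported figure
isolates the reconstruction's systematic error.  Per-dataset absolute
errors are also reported.

**Pattern comparison.**  With an exact narrow support and moderate skip
rates, random and coherent patterns reconstruct comparably — the
consistent-projection problem is easy either way.  The random advantage
emerges when the sparsity premise is imperfect (residual unmodelled
baseline) or near the feasibility limit: periodic gaps fold the
unmodelled content coherently onto other peaks, random gaps spread it
incoherently.  The property test runs the imperfect-baseline condition
(raw Lorentzian tails retained, 50% skip): mean per-peak error ≈ 21%
(random) vs ≈ 29% (coherent) over 20 seeds.

**Noise at equal power budget.**  `monte_carlo_noise_ratio` compares
n_full fully sampled averages with round(n_full/(1−skip)) under-sampled
reconstructed averages — the same total decoupled points, hence the same
SAR — measuring noise variance in an empty-region probe window.  At 30%
skip (7 vs 10 averages) the variance ratio full:under is ≈1.7–2: the
under-sampled average wins because each reconstruction carries only the
sampled points' noise.  Scaled down from the published 70/100-average
experiment; the exact published ratio (2.16:1) depends on unstated
simulation parameters and is reported, not asserted.

## Synthetic spectra (`synthspec`)

FIDs are sums of exponentially damped complex sinusoids (shift in ppm,
amplitude, Lorentzian FWHM in Hz, phase), plus an optional slowly varying
baseline (polynomial over the normalized frequency axis, added via
inverse FFT), plus seeded circular complex Gaussian noise.  Defaults
follow the published acquisitions: SW 5 kHz, 1024 complex points, carbon
carrier 177 ppm at 75 MHz (≈7 T).

The ten-peak carboxylic/amide preset uses the published in vivo shifts —
GABA C1 182.2 (also reported as 182.3; 182.2 adopted), Glu C5 182.0,
NAA C1 179.6, NAA C4 179.4, Gln C5 178.5, Asp C4 178.3, Glu C1 175.4,
Asp C1 175.0, Gln C1 174.9, NAA C5 174.3 ppm.  Relative amplitudes and
linewidths are **assumptions**, not published facts: Glu C5 : Gln C5 :
Asp C4 = 1 : 0.45 : 0.35, the remaining peaks scaled to resemble
late-infusion summed spectra, all linewidths 3 Hz, everything
configurable.  `INVIVO_LIKE_NOISE_SD = 0.5` (time-domain per-component)
gives a spectral SNR of ≈30–40 for Glu C5 at the default acquisition,
comparable to a summed in vivo block; it was fixed once as the benchmark
condition.

What the generator does *not* emulate: ¹³C-¹³C isotopomer doublets,
metabolite-concentration kinetics, lipid contamination, B₀/B₁
inhomogeneity, and frequency drift.  Passing benchmarks therefore
demonstrate the correctness and self-consistency of the algorithms under
the stated spectral model, not clinical performance.

## Benchmark problem sizes

The reconstruction benchmark uses 8 seeded datasets of 1024 points
(~10 s total); the windowing benchmark 20 seeds of 2048 sub-pulses
(sub-second); the decoupling comparison 7 offsets × 8 transients of
256-point FIDs (~2 s).  These sizes give seed-to-seed stability of the
reported figures (reconstruction mean error varies by ~±1 percentage
point across master seeds, retained power by ~±0.3) while keeping the
whole suite under a minute.

## Known limitations

* Two spins only; strong-coupling proton networks and NOE cross-
  relaxation dynamics are out of scope (NOE enters only as a power term).
* The SAR module implements the bookkeeping identities; field
  distributions and tissue heating are external inputs.
* The iterative reconstruction inherits the sparsity premise; spectra
  with dense or broad signals (e.g. lipid-contaminated regions) violate
  it and are outside the method's domain.
* JCAMP-DX support covers the subset this package writes (labelled
  header records plus simple data tables), not the full standard.
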