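# stochdec

Low-RF-power heteronuclear decoupling toolkit for in vivo carbon-13
magnetic resonance spectroscopy (MRS).

¹³C-MRS of brain metabolism normally requires proton decoupling fields
far stronger than the one-bond ¹J_CH coupling (125–145 Hz), and the
required RF power grows as B₀², so composite-pulse decoupling (WALTZ)
runs into SAR safety limits above ~4 T.  The carboxylic/amide carbons of
glutamate, glutamine, aspartate, NAA and GABA (169–185 ppm), however,
couple to protons only via long-range couplings of a few Hz and can be
decoupled with *stochastic* (random-phase) irradiation at a nominal
γB₂ ≈ 100 Hz.  `stochdec` implements the simulation and
acquisition-engineering side of this strategy for spectroscopists and
sequence developers:

* **`waveforms`** — CW, WALTZ-4/16, Ernst pseudo-stochastic (random
  0°/180° phases) and vectorial-noise decoupling waveforms; ideal
  double-bandpass frequency windowing (keep only the 1.91–3.90 and
  6.83–7.60 ppm coupled-proton bands); power/energy accounting via
  Parseval; JCAMP-DX-style shape and delimited text I/O.
* **`spinsim`** — exact density-matrix simulation of a scalar-coupled
  ¹H–¹³C pair under arbitrary piecewise-constant irradiation:
  σ(t) = C_x cos(πJt) + 2C_yH_z sin(πJt) free evolution, spin-echo
  refocusing, gated FID acquisition, decoupling-quality profiles
  (centerband fraction, residual splitting, linewidth).
* **`power_sar`** — RF_ave = RF_DEC·DC_DEC + RF_NOE·DC_NOE,
  SAR_max = SAR₁₀g·RF_ave, SAR_ave = RF_ave/M, duty cycles, and the
  energy savings of windowing and gating.
* **`undersampling`** — time-domain random under-sampling patterns
  (fully sampled core + skipped segments) and the iterative
  projection-onto-convex-sets reconstruction: zero-fill, FFT, zero the
  empty frequency group Z, inverse FFT, restore measured data, repeat
  until the residual on sampled points falls below tolerance.
* **`synthspec`** — synthetic carboxylic/amide spectra (Lorentzian peaks
  at the published in vivo shifts, baseline, seeded complex noise) used
  as fixtures by everything else.
* **`cli`** — `stochdec waveform | simulate | sar-report | synth |
  recon`, with JSON manifests recording every seed.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Generate a noise-free synthetic carboxylic/amide FID (SW 5 kHz, 1024
points, 75 MHz carbon at 7 T), gate off 30% of the acquisition in random
8-point segments after a 20% fully sampled core, and reconstruct:

```sh
stochdec synth --seed 3 --noise-sd 0 --out fid.txt
stochdec recon --fid fid.txt --skip-rate 0.3 --seed 11 --out run
```

which prints (abridged):

```json
{
  "converged": true,
  "iterations": 30,
  "final_eps": 9.2e-07,
  "decoupling_energy_saving": 0.30078125,
  "per_peak_error_pct": {
    "Glu C5": 1.9e-06,
    "Gln C5": 2.3e-05,
    "Asp C4": 1.5e-05
  }
}
```

The iteration converged in 30 passes (residual below the 1e-6 relative
tolerance); every metabolite intensity is recovered to ~1e-5 percent,
while the decoupler was off for 30.1% of the acquisition — a direct
30.1% cut in decoupling energy and hence SAR, since SAR accumulates
linearly with decoupling duration.  With realistic noise
(`--noise-sd 0.5`) the per-peak errors rise to the few-percent level;
the `reconstruction_intensity_benchmark` protocol quantifies this
(mean ≈ 2.6% over Glu C5 / Gln C5 / Asp C4 at 30% skip, averaged over
8 seeded datasets).

Window a stochastic decoupling sequence to the coupled-proton bands at
500 MHz (11.7 T):

```sh
stochdec waveform --type pseudo --gamma-b2 100 --duration 0.5 --seed 7 \
    --band 1.91:3.90 --band 6.83:7.60 --f0 500 --out wf.shape
```

reports `"retained_power_fraction": 0.5195` — the ideal double bandpass
discards roughly half of the decoupling power (the in-band fraction of
the sequence's white spectrum) while leaving the decoupled bands
untouched.

Library use mirrors the CLI:

```python
import stochdec as sd

peaks = sd.preset_peaks()                      # Glu/Gln/Asp/NAA/GABA, 169-185 ppm
fid = sd.synth_fid(peaks, noise_sd=0.5, seed=1)
model = sd.synth_fid(peaks, noise_sd=0.0).to_spectrum()
support = sd.build_support(model, peaks=peaks)           # signal group P
fid = sd.remove_model_baseline(fid, model, support)      # make Z truly empty
pattern = sd.make_pattern(1024, skip_rate=0.3, core_fraction=0.2, seed=2)
result = sd.reconstruct(sd.undersample(fid, pattern), pattern, support)
errors = sd.intensity_error(result.spectrum, fid.to_spectrum(), peaks)
```

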