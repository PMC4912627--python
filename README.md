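# segclock

Quantitative analysis of segmentation-clock wave patterns in the zebrafish
presomitic mesoderm (PSM), built around the question of how elevated
Delta-Notch coupling shortens the segmentation period.  The package
implements, as a single tested chain:

* a **delayed-coupling phase-oscillator model** of the PSM in a frame
  co-moving with the tailbud — a 1D chain with intrinsic frequency profile
  ω(x) (maximal at the tailbud), anterior cell flow at speed v, and
  nearest-neighbour coupling of strength ε acting through a transmission
  delay τ:

  dφᵢ/dt = ω(xᵢ) − v(φᵢ−φᵢ₋₁)/a + (ε/2) Σⱼ sin(φⱼ(t−τ) − φᵢ(t)) + noise.

  Steady wave patterns φ = Ωt + ψ(x) are solved on the lattice; the
  collective frequency of a homogeneous chain obeys
  Ω = ω₀ − ε·sin(Ωτ).  Patterns are characterized by the local wavelength
  λ(x) = 2π/|ψ′(x)|, the anterior wavelength λ_A, and the wave count
  K = |ψ(L) − ψ(0)|/2π; stability is probed by perturbation decay, and a
  DAPT pulse-chase (coupling switched off, then restored) is simulated
  through the Kuramoto order parameter Z;
* the **Doppler-effect period prediction**: with a fraction f of the
  segmentation rate R = 1/T attributed to the anterior boundary moving into
  the waves, and the Doppler term scaling inversely with λ_A, the perturbed
  rate is R′ = R(1 + f(λ/λ̃ − 1)) and the period T′ = 1/R′;
* the **measurement pipelines** those quantities rest on: anterior
  wavelength, stripe border X0 and expression length from 1D intensity
  profiles; segmentation period and tissue elongation/shortening rates by
  linear regression; boundary-defect scoring (ALD, FRS, re-synchronization
  rate = 1/(FRS−9)); and efficiency-corrected qPCR copy-number estimation
  with deltaC loading calibration;
* **synthetic-data generators** with known ground truth for every input, so
  the full inference chain runs and is tested without any external data.

## Worked example

```python
from segclock.oscillator import (wt_like_params, damascus_like_params,
                                 solve_preset_pattern)
from segclock.synth import gen_wave_profile
from segclock.profiles import measure_wavelength
from segclock.doppler import DopplerInputs, predict_period

wt  = solve_preset_pattern(wt_like_params())        # eps=0.07, tau=21 min
dam = solve_preset_pattern(damascus_like_params())  # eps=0.14, tau=12 min
print(round(wt.anterior_wavelength, 2), round(dam.anterior_wavelength, 2),
      round(wt.wave_count_K, 2), round(dam.wave_count_K, 2))
# 70.85 55.54 3.54 4.16

profile, truth = gen_wave_profile(pattern=dam, noise_sd=3.0, seed=0)
print(measure_wavelength(profile).anterior_wavelength)
# 56.0

res = predict_period(DopplerInputs(T_ref=24.7, doppler_fraction=0.22,
                                   wavelength_ratio=70.85 / 55.54))
print(round(res.T_perturbed, 2))
# 23.29
```

Doubling the coupling strength (with a plausibly altered delay) locks the
chain on a faster collective branch carrying more waves at a ~1.28-fold
shorter anterior wavelength; feeding the measured wavelength ratio through
the Doppler relation predicts a segmentation period ~6% shorter than the
24.7-min reference — the same magnitude as the directly measured period
difference.

## Analysis scripts

The `analysis/` drivers run the chain end to end on synthetic data and
write their tables under `results/`:

1. `01_wave_patterns.py` — solve and characterize the two preset wave
   patterns; small ε×τ phase diagram.
2. `02_wavelength_measurement.py` — stripe profiles from the solved
   patterns, measured λ_A / X0 / her1-L.
3. `03_doppler_prediction.py` — period prediction from the measured ratio.
4. `04_somite_timing.py` — period and tissue-rate recovery from synthetic
   time-lapse cohorts.
5. `05_copy_number.py` — qPCR copy-number estimates across genotypes.
6. `06_resynchronization.py` — pulse-chase simulations across coupling
   strengths and scored boundary records.

Run them in order from `analysis/` (e.g. `python 01_wave_patterns.py`).

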