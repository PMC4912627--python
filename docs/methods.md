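# Methods

## The oscillator model

The presomitic mesoderm is described as a chain of N phase oscillators at
positions xᵢ = i·a in a frame co-moving with the tailbud tip (x = 0) and
ending at the arrest front (x = L = N·a).  Each site carries an intrinsic
frequency ω(x) that is maximal at the tailbud (ω(0) = ω₀) and decreases
anteriorly; cells flow anteriorly at speed v and couple to their neighbours
with strength ε through a signalling delay τ:

    dφᵢ/dt = ω(xᵢ) − v(φᵢ − φᵢ₋₁)/a
             + (ε/2)[sin(φᵢ₋₁(t−τ) − φᵢ) + sin(φᵢ₊₁(t−τ) − φᵢ)]
             + σ ξᵢ(t).

Assumptions inherited from the underlying picture: constant PSM length (no
tissue shortening inside the model), phase-level description only (no
molecular Delta/Notch kinetics), nearest-neighbour coupling, 1D geometry,
no cell division or mixing.

**Boundary conditions.**  The posterior site carries a mirror ghost
(φ₋₁ ≡ φ₀): the tailbud is treated as a locally homogeneous oscillator
population with no advective inflow of phase.  With this closure a
homogeneous chain locks exactly at the collective frequency Ω solving
Ω = ω₀ − ε·sin(Ωτ).  The anterior ghost is linearly extrapolated
(φ_N ≡ 2φ_{N−1} − φ_{N−2}): cells that arrest and leave the PSM carry the
local wave with them, so the front site sees a continuation of the local
phase gradient.  A mirror there would flatten ψ′ over the last few sites
and corrupt the anterior wavelength exactly where it is read off; in the
homogeneous case the extrapolated ghost reduces to the mirror, so the
two-oscillator frequency results are unchanged.

**Frequency profiles.**  Families: linear ω₀(1 − x/L) (default; the
minimal profile producing gradual slowing and anterior arrest),
exponential ω₀·e^(−x/x₀), normalized descending sigmoid, and uniform (for
homogeneous-chain tests).  The family and its parameters are configuration
axes.

**Steady patterns.**  Time-periodic solutions φ = Ωt + ψ(x) satisfy the
stationary lattice system with Ω closed by the posterior boundary
equation.  The solver seeds Ω at the homotopy-continued root of
Ω = ω₀ − ε·sin(Ωτ) (continued from the delay-free solution Ω = ω₀, which
makes branch selection deterministic; all roots are available for
diagnostics and an explicit `Omega_init` selects another branch), seeds ψ
at the uncoupled closed form ψ′ = (ω − Ω)/v, relaxes by a damped
posterior→anterior upwind sweep, and polishes with a Newton-type root
solve; residuals land at 1e−15.  Note the exact lattice Ω with a frequency
gradient differs from the scalar root by the posterior boundary-gradient
term, O(ε·a·ω₀/(v·L)) ≈ 0.1% at the preset scales; the delay-free identity
Ω = ω₀ holds exactly for the scalar solver and to ~0.5% on the lattice.

Patterns are characterized by λ(x) = 2π/|ψ′(x)| (centered differences),
the anterior wavelength λ_A at the anterior-most interior site, and the
wave count K = |ψ(L) − ψ(0)|/2π.  Where ψ′ vanishes the wavelength is
reported as undefined (NaN).

**Stability.**  Rather than solving the delay-lattice characteristic
problem, stability is probed dynamically: the pattern plus a small
zero-mean random perturbation (≤ 0.01 rad) is integrated for 20 collective
periods and the growth rate fitted by OLS to the log of the deviation norm
max_i|φᵢ − Ωt − ψᵢ − mean deviation|.  The spatially uniform phase shift
is a neutral mode and is projected out; a pattern is stable iff the fitted
rate is below −1e−5 min⁻¹.  The probe is validated against the analytic
two-oscillator linearization (in-phase decay −ε/2, anti-phase growth +ε/2
at τ = 0 under the ghost convention above).

**Numerics.**  Euler–Maruyama with dt = min(0.01·2π/ω₀, τ/10); fixed-step
delay ring buffer with linear interpolation at t − τ (exact on the steady
solution, so a simulation started on a solved pattern stays within
integrator precision of it); upwind advection under the CFL bound
v·dt ≤ a; phases stored unwrapped; every stochastic run records its seed.

## Illustration presets

The generic parameter anchors are 2π/ω₀ = 23.5 min, L = 500 μm, a = 10 μm
and v = 0.8 μm/min.  The two preset configurations used by the analysis
scripts instead set v = 3 μm/min: at v = 0.8 the anterior phase jump per
cell exceeds π, i.e. a 10-μm lattice cannot resolve the anterior
wavelength it is supposed to measure, while v = 3 keeps ~6 sites per
anterior wave.  The wildtype-like preset uses ε = 0.07 rad/min and
τ = 21 min (the coupling strength and delay scale inferred for zebrafish
Delta-Notch signalling); the elevated-coupling preset doubles ε to 0.14
with τ = 12 min and locks on the largest collective-frequency root.  These
choices were fixed once, by scanning for a stable pattern pair whose
anterior-wavelength ratio matches the ~1.27 value that the period
arithmetic implies (below); the qualitative signature — more waves,
shorter λ_A at higher ε — holds across a region of the (ε, τ) plane, which
the phase-diagram scan in `analysis/01` demonstrates.

## Doppler period arithmetic

The anterior end of a shortening PSM moves into the incoming waves, so
waves arrive — and segments form — faster than the posterior oscillation
alone dictates.  With a fraction f of the reference segmentation rate
R = 1/T attributed to this Doppler term, and the term scaling with
shortening speed over anterior wavelength, an unchanged shortening speed
gives

    D = f·R,   D̃ = D·(λ/λ̃),   R̃ = R − D + D̃,   T̃ = 1/R̃.

Defaults: T = 24.7 min, f = 0.22, giving D = 0.0089 min⁻¹.  A wavelength
ratio of ~1.27 yields T̃ ≈ 23.3 min, 5.7% shorter.  Rounding to printed
precision happens only at the reporting layer.  Propagation of the ±s.d.
on f and T is deliberately out of scope; only point estimates are
reported.

## Measurement pipelines

**Profiles.**  Intensity profiles run anterior→posterior (inverted
grayscale, signal high).  Peaks: boxcar smoothing (5 samples), local
maxima filtered by prominence (default 10% of dynamic range) and
separation (20 μm for stripes, 5 μm for somata).  Anterior wavelength:
distance between the two most anterior maxima.  X0: background line fit to
the anterior baseline (the longer of the anterior-most 15% of the line or
the sub-20th-percentile samples before the first peak — the original
procedure leaves the baseline definition open, so both knobs are exposed);
inflection point as the maximum smoothed first difference on the anterior
flank (ties toward the peak); regression windows grown point-by-point
anteriorly from the inflection, best r² kept (ties within 1e−6 to the
longer window); X0 is the intersection of that line with the baseline.
Degenerate geometry (parallel lines) raises; r² < 0.5 sets a
low-confidence flag.  her1-L is the distance from X0 to the line end.
Neuron density is peaks per 100 μm; area measurement replaces the manual
watershed step with a single documented threshold, preserving the
pixel-count × scale² contract.

**Timing.**  Period: OLS slope of frame index on somite number over
segments 4–19, times the frame interval (kept literal to the assay even
though it equals time-on-somite regression for uniform sampling).  Rates:
OLS slope over the 0–600 min window (time 0 at the 5-somite stage);
shortening reported as a positive magnitude.  Temperature is metadata; no
temperature correction is applied.

**Boundary scoring.**  Segments 1–2 and those past 30 are defined
non-defective.  ALD is the first defective boundary in [3, 30].  FRS is
the first non-defective boundary after washout (stage 9) that follows at
least one defective segment — without a preceding defective region FRS is
undefined, which prevents a spurious FRS = 10 on defect-free records; an
all-defective tail through segment 30 leaves FRS censored.
Re-synchronization rate is 1/(FRS − 9).  Recomputing percent differences
in re-synchronization time from mean FRS values gives 21.8% (heterozygote
vs wildtype) and 14.8% (high-copy vs wildtype) rather than the rounded
20.5%/15.0% sometimes quoted; the package reports the formulaic values.

**qPCR.**  Replicate Cts are averaged per sample × primer before ΔCt.
Relative concentration against the in-group wildtype mean is
E^(Ct_ref − Ct_sample) with per-primer efficiency E (default 2.0 unless a
standard curve supplies 10^(−1/slope)).  Each sample's deltaD values are
divided by its averaged deltaC relative concentration, cancelling
per-sample loading errors exactly; estimates are averaged across deltaD
primer pairs, total copies are 2× the calibrated value and transgenic
copies total − 2.  venus primers measure transgene dose only; they are
bridged through an assigned anchor sample's deltaD-based transgenic
estimate and enter the same average.  The point-mutant allele amplifies
normally and counts as a genomic copy.  Aggregation over trials reports
mean ± s.d. and flags fewer than 3 trials.

## Synthetic data

Each generator is deterministic given its arguments and seed and returns
its ground truth.  Noise is Gaussian throughout — the study conventions
report mean ± s.d., and nothing finer is recoverable — with defaults tied
to reported scatter where available: 1.5 min furrow-timing jitter (period
s.d. ±0.6–0.8 min at the cohort level), 0.05-cycle Ct noise, lognormal
loading factors (s.d. 0.2 in log), 15-μm length-measurement noise.

Stripe profiles are background + amplitude·max(0, cos ψ)^p sampled at
pixel resolution, with the solved pattern's ψ(x) (or a parametric
wavelength + gradient) setting the phase, an anterior baseline pad for X0
estimation, and additive pixel noise.  Boundary records are driven by an
order-parameter trajectory: Z falls from Z₀ during the coupling block,
crossing Zc at a per-side Gaussian crossing point, bottoms at Z_min, and
recovers linearly after washout, recrossing Zc at a second Gaussian
crossing; a segment is defective iff Z at its formation time is below Zc.
The preset crossing means/s.d. are placed so the scored records reproduce
the anchor values (mean ALD ≈ 8; mean FRS 19.1/17.8/21.3 with s.d. ~2 for
the wildtype-like, high-copy-like and heterozygote-like presets).  This is
a calibration of the generator to its documented anchors, done once.

What the generators do **not** emulate: staining batch effects beyond a
per-profile gain, non-Gaussian measurement error, embryo-to-embryo
frequency-profile variation, 2D tissue geometry, or any coupling between
the assays.  Passing tests therefore demonstrate that the estimators
recover truth under the stated statistical structure, not that they are
robust to every failure mode of real embryo data.

## Problem sizes

Default analysis/test scales: 50-site chains (200 for closed-form
convergence checks), 10–40 simulated embryos per cohort, 20 matched seeds
per coupling strength in the pulse-chase scan, 100-oscillator populations
for the order-parameter simulations, 2–3 qPCR primers × 2 replicates × 3
trials.  These sizes make every stochastic check reproducible in seconds
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The model omits tissue shortening, so the Doppler arithmetic lives
  outside the lattice model; the chain only supplies wave patterns and
  wavelength ratios.
* The exact (ε, τ) values and frequency profile of the original
  supplementary phase diagrams are not published; the presets here are the
  package's own calibration, and the phase-diagram claims are qualitative
  (existence and direction of the elevated-coupling region).
* Stability is an empirical decay-rate fit, not a spectral computation; it
  cannot distinguish slow instabilities with growth rates inside ±1e−5
  min⁻¹.
* The venus-bridging normalization requires an anchor sample with a
  reliable deltaD-based estimate; the anchor's absolute value propagates
  into every venus-derived estimate.
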