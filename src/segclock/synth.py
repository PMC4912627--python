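"""Synthetic-data generators with known ground truth.

Every input the analysis chain consumes can be generated here: spatially
periodic expression profiles (optionally driven by a solved oscillator wave
pattern), furrow-emergence times, tissue-length series, qPCR Ct tables,
per-side boundary-defect records driven by a synchrony trajectory, neuron
soma lines and filled-disc images.  All generators are deterministic given
their arguments and a seed, and return their ground truth alongside the
data.  Noise is Gaussian throughout, with defaults set to the measured
scatter of the corresponding assay where one is printed (timing jitter from
the +/-0.6-0.8 min period s.d., Ct noise 0.05 cycles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oscillator import SteadyPattern, SyncTrajectory, TWO_PI
from .profiles import IntensityProfile
from .qpcr import PrimerMeta, QpcrTable
from .timing import BoundaryRecord, FurrowTimes, LengthSeries

#: printed anchor values bundled as generator truths
PRESETS = {
    "wt_like": {
        "period_min": 24.7, "period_sd": 0.6,
        "axial_rate": 1.13, "psm_rate": 0.80,
        "total_copies": 2, "frs_mean": 19.1, "frs_sd": 2.2,
        "ald_mean": 8.0, "ald_sd": 1.5,
    },
    "damascus_like": {
        "period_min": 23.1, "period_sd": 0.8,
        "axial_rate": 1.06, "psm_rate": 0.79,
        "total_copies": 102, "frs_mean": 17.8, "frs_sd": 1.9,
        "ald_mean": 8.0, "ald_sd": 1.5,
    },
    "dover_like": {"total_copies": 9},
    "aei_het_like": {"total_copies": 1, "frs_mean": 21.3, "frs_sd": 2.0},
}

CT_NOISE_SD_DEFAULT = 0.05  # cycles
TIMING_JITTER_SD_DEFAULT = 1.5  # min


# ---------------------------------------------------------------------------
# expression profiles


def gen_wave_profile(pattern: SteadyPattern | None = None,
                     wavelength: float | None = None,
                     gradient: float = 0.0,
                     span: float = 700.0,
                     background: float = 20.0,
                     amplitude: float = 100.0,
                     noise_sd: float = 0.0,
                     pixel_scale: float = 1.0,
                     anterior_pad: float = 60.0,
                     stripe_power: float = 2.0,
                     seed: int = 0) -> tuple[IntensityProfile, dict]:
    """Synthesize a stripe profile (anterior at index 0) with known truth.

    If ``pattern`` is given, the stripe phase is the pattern's steady profile
    psi(x) interpolated to pixel resolution and mirrored so that the model's
    anterior end (x = L) sits just after an ``anterior_pad`` of baseline at
    the start of the line.  Otherwise a parametric phase with anterior
    wavelength ``wavelength`` and fractional wavelength ``gradient`` per span
    is used.  Intensity is
    ``background + amplitude * max(0, cos(phase))**stripe_power + noise``.

    Returns (profile, truth) with truth holding the noise-free peak
    positions, the first-stripe onset and the generating wavelength.
    """
    rng = np.random.default_rng(seed)
    if pattern is not None:
        L = float(pattern.positions[-1])
        u_model = np.arange(0.0, L + pixel_scale / 2, pixel_scale)
        psi_f = np.interp(u_model, pattern.positions, pattern.psi)
        # line runs anterior -> posterior: distance d from line start maps to
        # model coordinate x = L - (d - anterior_pad)
        d_signal = anterior_pad + (L - u_model)[::-1]  # increasing d
        phase = psi_f[::-1] - psi_f[-1]  # zero phase at the anterior end
        positions = np.arange(0.0, anterior_pad + L + pixel_scale / 2,
                              pixel_scale)
        phase_line = np.interp(positions, d_signal, phase,
                               left=np.nan, right=np.nan)
        lam_true = float(pattern.anterior_wavelength)
    else:
        if wavelength is None:
            raise ValueError("need a pattern or an explicit wavelength")
        positions = np.arange(0.0, span + pixel_scale / 2, pixel_scale)
        d = positions - anterior_pad
        lam_local = wavelength * (1.0 + gradient * np.clip(d, 0, None) / span)
        # phase = 2 pi * integral du / lambda(u), zero at the pad edge
        inv = np.where(d >= 0, 1.0 / lam_local, 0.0)
        phase = TWO_PI * np.concatenate(
            [[0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1])
                              * np.diff(positions))])
        phase_line = np.where(d >= 0, phase, np.nan)
        lam_true = float(wavelength)

    signal = np.zeros_like(positions)
    in_sig = ~np.isnan(phase_line)
    osc = np.cos(phase_line[in_sig])
    signal[in_sig] = amplitude * np.clip(osc, 0.0, None) ** stripe_power
    intensity = background + signal
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.size)

    # noise-free truth: peaks where the phase crosses multiples of 2 pi
    ph = phase_line[in_sig]
    pos_sig = positions[in_sig]
    peak_pos = []
    kmin = int(math.floor(ph.min() / TWO_PI))
    kmax = int(math.ceil(ph.max() / TWO_PI))
    for k in range(kmin, kmax + 1):
        target = k * TWO_PI
        crossings = np.nonzero(np.diff(np.sign(ph - target)) != 0)[0]
        for c in crossings:
            frac = (target - ph[c]) / (ph[c + 1] - ph[c])
            peak_pos.append(float(pos_sig[c] + frac
                                  * (pos_sig[c + 1] - pos_sig[c])))
    if abs(ph[0]) < 1e-9:
        peak_pos.append(float(pos_sig[0]))
    peak_pos = sorted(set(peak_pos))

    truth = {
        "anterior_wavelength": lam_true,
        "peak_positions": peak_pos,
        "stripe_onset": float(anterior_pad),
        "seed": seed,
    }
    profile = IntensityProfile(positions=positions, intensities=intensity,
                               pixel_scale=pixel_scale)
    return profile, truth


def gen_neuron_line(n_peaks: int = 10, length_um: float = 200.0,
                    spacing: str = "even", peak_sigma: float = 2.0,
                    amplitude: float = 80.0, background: float = 10.0,
                    noise_sd: float = 0.0, pixel_scale: float = 0.756,
                    seed: int = 0) -> tuple[IntensityProfile, dict]:
    """Line of Gaussian soma peaks, evenly or Poisson spaced."""
    rng = np.random.default_rng(seed)
    positions = np.arange(0.0, length_um + pixel_scale / 2, pixel_scale)
    if n_peaks > 0:
        if spacing == "even":
            centers = (np.arange(n_peaks) + 0.5) * length_um / n_peaks
        elif spacing == "poisson":
            centers = np.sort(rng.uniform(2 * peak_sigma,
                                          length_um - 2 * peak_sigma,
                                          n_peaks))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
    else:
        centers = np.array([])
    intensity = np.full_like(positions, background)
    for c in centers:
        intensity += amplitude * np.exp(-0.5 * ((positions - c)
                                                / peak_sigma) ** 2)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.size)
    profile = IntensityProfile(positions=positions, intensities=intensity,
                               pixel_scale=pixel_scale)
    return profile, {"centers": centers.tolist(),
                     "density_per_100um": 100.0 * n_peaks / length_um,
                     "seed": seed}


def gen_disc_image(shape: tuple[int, int] = (200, 200), radius: float = 50.0,
                   center: tuple[float, float] | None = None,
                   foreground: float = 1.0, background: float = 0.0,
                   noise_sd: float = 0.0, seed: int = 0
                   ) -> tuple[np.ndarray, dict]:
    """Filled disc of known radius on a background grid."""
    rng = np.random.default_rng(seed)
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    img = np.where(mask, foreground, background).astype(float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img, {"analytic_area_px": math.pi * radius**2,
                 "pixel_count": int(mask.sum()), "seed": seed}


# ---------------------------------------------------------------------------
# timing


def gen_furrow_times(true_period: float, n_embryos: int = 26,
                     somites: tuple[int, int] = (4, 19),
                     jitter_sd: float = TIMING_JITTER_SD_DEFAULT,
                     frame_interval: float = 1.0,
                     t0: float = 100.0, seed: int = 0
                     ) -> tuple[list[FurrowTimes], dict]:
    """Furrow-emergence records: t_s = t0 + s*T + N(0, jitter), framed."""
    if true_period <= 0:
        raise ValueError("true_period must be positive")
    rng = np.random.default_rng(seed)
    s = np.arange(somites[0], somites[1] + 1)
    out = []
    for _ in range(n_embryos):
        t = t0 + s * true_period + rng.normal(0.0, jitter_sd, s.size)
        frames = np.round(t / frame_interval).astype(int)
        out.append(FurrowTimes(somite_numbers=s, frame_indices=frames,
                               frame_interval=frame_interval))
    return out, {"true_period": true_period, "jitter_sd": jitter_sd,
                 "seed": seed}


def gen_length_series(rate: float, intercept: float = 1500.0,
                      window: tuple[float, float] = (0.0, 660.0),
                      sample_interval: float = 10.0,
                      noise_sd: float = 15.0, kind: str = "axis",
                      seed: int = 0) -> tuple[LengthSeries, dict]:
    """Linear length-change series; shortening kinds use a negative slope."""
    rng = np.random.default_rng(seed)
    t = np.arange(window[0], window[1] + sample_interval / 2, sample_interval)
    slope = -abs(rate) if kind == "psm" else rate
    y = intercept + slope * t + rng.normal(0.0, noise_sd, t.size)
    return (LengthSeries(times=t, lengths=y, kind=kind),
            {"true_rate": abs(rate), "slope": slope, "noise_sd": noise_sd,
             "seed": seed})


# ---------------------------------------------------------------------------
# qPCR


def gen_qpcr(copies_by_sample: dict[str, float],
             wt_samples: tuple[str, ...] = ("wt1", "wt2"),
             n_deltaD_primers: int = 2, n_deltaC_primers: int = 2,
             efficiency: float = 2.0,
             ct_noise_sd: float = CT_NOISE_SD_DEFAULT,
             loading_sd: float = 0.2, n_replicates: int = 2,
             seed: int = 0) -> tuple[QpcrTable, dict]:
    """Inverse model of the copy-number pipeline.

    Ct = base_Ct(primer) - log_E(copies/2 * loading) + N(0, ct_noise_sd) for
    deltaD primers; deltaC wells carry the same per-sample loading factor
    with copies fixed at 2.  Wildtype reference samples (2 copies) are added
    automatically.  ``loading_sd`` is the s.d. of the lognormal per-sample
    loading factor.
    """
    rng = np.random.default_rng(seed)
    samples = dict(copies_by_sample)
    for wts in wt_samples:
        samples.setdefault(wts, 2.0)

    primers: dict[str, PrimerMeta] = {}
    base_ct: dict[str, float] = {}
    for i in range(n_deltaD_primers):
        pid = f"dd{i + 1}"
        primers[pid] = PrimerMeta(pid, "deltaD", efficiency)
        base_ct[pid] = float(rng.uniform(20.0, 26.0))
    for i in range(n_deltaC_primers):
        pid = f"dc{i + 1}"
        primers[pid] = PrimerMeta(pid, "deltaC", efficiency)
        base_ct[pid] = float(rng.uniform(20.0, 26.0))

    loading = {s: float(np.exp(rng.normal(0.0, loading_sd)))
               for s in samples}
    logE = math.log(efficiency)
    rows = []
    for s_id, copies in samples.items():
        for pid, meta in primers.items():
            dose = (copies if meta.target == "deltaD" else 2.0) / 2.0
            ct_true = base_ct[pid] - math.log(dose * loading[s_id]) / logE
            for rep in range(n_replicates):
                ct = ct_true + (rng.normal(0.0, ct_noise_sd)
                                if ct_noise_sd > 0 else 0.0)
                rows.append((s_id, pid, rep, ct))
    wells = pd.DataFrame(rows, columns=["sample_id", "primer_id",
                                        "replicate", "Ct"])
    groups = {s: ("WT" if s in wt_samples else "sample") for s in samples}
    table = QpcrTable(wells=wells, primers=primers, group_labels=groups)
    truth = {"copies_by_sample": samples, "loading_factors": loading,
             "efficiency": efficiency, "ct_noise_sd": ct_noise_sd,
             "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# boundary-defect records


def _z_trajectory(s: np.ndarray, c_down: float, c_up: float,
                  z0: float, zc: float, z_min: float,
                  washout_stage: int, block_start_stage: float) -> np.ndarray:
    """Synchrony level at segment formation indices.

    Piecewise-linear order-parameter trajectory: Z falls from ``z0`` at the
    block start, crossing ``zc`` at segment coordinate ``c_down`` and
    bottoming at ``z_min`` by washout; after washout it rises, recrossing
    ``zc`` at ``c_up`` and saturating at 1.
    """
    z = np.empty(s.shape, dtype=float)
    down_rate = (z0 - zc) / max(c_down - block_start_stage, 1e-9)
    up_start = washout_stage
    up_rate = (zc - z_min) / max(c_up - up_start, 1e-9)
    for i, si in enumerate(s):
        if si <= block_start_stage:
            z[i] = z0
        elif si <= washout_stage:
            z[i] = max(z0 - down_rate * (si - block_start_stage), z_min)
        else:
            z[i] = min(z_min + up_rate * (si - up_start), 1.0)
    return z


def gen_boundary_records(n_embryos: int = 20, preset: str = "wt_like",
                         frs_mean: float | None = None,
                         frs_sd: float | None = None,
                         ald_mean: float | None = None,
                         ald_sd: float | None = None,
                         Zc: float = 0.75, z0: float = 0.98,
                         n_segments: int = 32, washout_stage: int = 9,
                         block_start_stage: float = 3.0,
                         error_rate: float = 0.0,
                         sync: SyncTrajectory | None = None,
                         segment_period: float = 24.7,
                         seed: int = 0
                         ) -> tuple[list[BoundaryRecord], dict]:
    """Per-side boundary records driven by a noisy synchrony trajectory.

    Segment s is defective iff the order parameter Z at its formation time is
    below Zc (plus optional per-boundary flips at ``error_rate``).  By
    default Z follows a piecewise-exponential desynchronize/resynchronize
    trajectory whose rate constants are calibrated so that Z crosses Zc at
    the preset's mean ALD and recrosses it at the mean FRS; per-embryo-side
    lognormal rate scatter reproduces the preset s.d. values.  Passing a
    simulated :class:`SyncTrajectory` thresholds that trajectory instead
    (segment s forms at s * segment_period after the trajectory origin).
    """
    rng = np.random.default_rng(seed)
    p = PRESETS.get(preset, {})
    frs_mean = frs_mean if frs_mean is not None else p.get("frs_mean", 19.1)
    frs_sd = frs_sd if frs_sd is not None else p.get("frs_sd", 2.2)
    ald_mean = ald_mean if ald_mean is not None else p.get("ald_mean", 8.0)
    ald_sd = ald_sd if ald_sd is not None else p.get("ald_sd", 1.5)

    segs = np.arange(1, n_segments + 1)
    records = []
    if sync is not None:
        z_of_seg = np.interp(segs * segment_period, sync.times, sync.Z)
        for _ in range(n_embryos):
            for side in ("left", "right"):
                defect = z_of_seg < Zc
                if error_rate > 0:
                    flips = rng.random(n_segments) < error_rate
                    defect = defect ^ flips
                statuses = tuple("defective" if d else "ok" for d in defect)
                records.append(BoundaryRecord(side=side, statuses=statuses,
                                              washout_stage=washout_stage))
        truth = {"mode": "trajectory", "Zc": Zc, "seed": seed}
        return records, truth

    # calibrated crossings: the downward Zc crossing sits at ald_mean - 0.5
    # and the recovery crossing at frs_mean - 0.5, so the first integer
    # segment past each crossing averages to the preset's mean; per-side
    # Gaussian scatter of the crossings reproduces the preset s.d.
    z_min = 0.3
    for _ in range(n_embryos):
        for side in ("left", "right"):
            c_down = float(np.clip(
                rng.normal(ald_mean - 0.5, ald_sd),
                block_start_stage + 0.05, washout_stage - 0.05))
            c_up = float(max(rng.normal(frs_mean - 0.5, frs_sd),
                             washout_stage + 0.05))
            z = _z_trajectory(segs.astype(float), c_down, c_up, z0, Zc,
                              z_min, washout_stage, block_start_stage)
            defect = z < Zc
            if error_rate > 0:
                flips = rng.random(n_segments) < error_rate
                defect = defect ^ flips
            statuses = tuple("defective" if d else "ok" for d in defect)
            records.append(BoundaryRecord(side=side, statuses=statuses,
                                          washout_stage=washout_stage))
    truth = {"mode": "calibrated", "frs_mean": frs_mean, "ald_mean": ald_mean,
             "frs_sd": frs_sd, "ald_sd": ald_sd, "Zc": Zc, "z_min": z_min,
             "seed": seed}
    return records, truth
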