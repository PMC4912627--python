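"""Quantification of 1D gene-expression intensity profiles.

Profiles are lines drawn from anterior (index 0) to posterior over
inverted-grayscale images, so signal is high-valued.  The module measures:

* stripe peaks and the anterior wavelength (distance between the two most
  anterior expression maxima);
* X0, the anterior border of the first stripe, by intersecting the anterior
  background line with the best-r^2 regression line grown anteriorly from the
  inflection point of the first peak's anterior flank;
* her1-L, the expression length from X0 to the end of the measured line;
* neuron densities as peaks per 100 um along a line;
* thresholded areas on 2D grids (pixel count times pixel_scale^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

#: default peak separations: stripes are tens of um apart, somata a few um
HER1_MIN_SEPARATION_UM = 20.0
SOMA_MIN_SEPARATION_UM = 5.0
SMOOTH_WINDOW = 5  # samples of boxcar smoothing before peak/derivative steps


@dataclass(frozen=True)
class IntensityProfile:
    """1D intensity profile; positions in um, anterior at index 0."""

    positions: np.ndarray
    intensities: np.ndarray
    pixel_scale: float = 1.0  # um per pixel
    line_width: float | None = None  # um averaged across, metadata

    def __post_init__(self) -> None:
        x = np.asarray(self.positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if x.shape != y.shape:
            raise ValueError("positions and intensities differ in length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        object.__setattr__(self, "positions", x)
        object.__setattr__(self, "intensities", y)

    @property
    def span(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass(frozen=True)
class PeakSet:
    peak_positions: np.ndarray  # um, sorted anterior -> posterior
    peak_heights: np.ndarray
    prominences: np.ndarray
    peak_indices: np.ndarray

    def __len__(self) -> int:
        return len(self.peak_positions)


@dataclass(frozen=True)
class WavelengthMeasurement:
    anterior_wavelength: float
    x0: float
    her1_L: float
    r2_of_front_fit: float
    low_confidence: bool = False


@dataclass(frozen=True)
class AreaMeasurement:
    area: float  # um^2
    threshold_used: float
    foreground_pixel_count: int


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    return ndimage.uniform_filter1d(y.astype(float), size=window,
                                    mode="nearest")


def find_peaks(profile: IntensityProfile, min_prominence: float | None = None,
               min_separation: float = HER1_MIN_SEPARATION_UM,
               smooth_window: int = SMOOTH_WINDOW) -> PeakSet:
    """Detect local maxima after boxcar smoothing.

    ``min_prominence`` defaults to 10% of the profile's dynamic range;
    ``min_separation`` is in um.  Returns an empty PeakSet if nothing
    qualifies (e.g. a constant profile).
    """
    y = profile.intensities
    if y.size < 5:
        raise ValueError("profile too short for peak detection")
    ys = _smooth(y, smooth_window)
    rng = float(ys.max() - ys.min())
    if min_prominence is None:
        min_prominence = 0.10 * rng
    if rng == 0.0:
        empty = np.array([])
        return PeakSet(empty, empty, empty, np.array([], dtype=int))
    dx = float(np.median(np.diff(profile.positions)))
    distance = max(1, int(round(min_separation / dx)))
    idx, props = signal.find_peaks(ys, prominence=max(min_prominence, 1e-12),
                                   distance=distance)
    return PeakSet(
        peak_positions=profile.positions[idx],
        peak_heights=y[idx],
        prominences=props["prominences"],
        peak_indices=idx,
    )


def anterior_wavelength(peaks: PeakSet) -> float:
    """Distance between the two most anterior peaks (um)."""
    if len(peaks) < 2:
        raise ValueError(
            f"anterior wavelength needs >= 2 peaks, found {len(peaks)}"
        )
    return float(peaks.peak_positions[1] - peaks.peak_positions[0])


def _baseline_region(profile: IntensityProfile, first_peak_idx: int,
                     anterior_fraction: float = 0.15,
                     intensity_percentile: float = 20.0) -> np.ndarray:
    """Indices of the anterior background segment.

    The longer of: the anterior-most ``anterior_fraction`` of the line, or all
    samples anterior to the first peak below the given intensity percentile
    (computed over the pre-peak segment).  Both knobs are configurable to stay
    robust on clean and on drifting baselines.
    """
    n = profile.positions.size
    frac_end = max(3, int(round(anterior_fraction * n)))
    frac_idx = np.arange(min(frac_end, first_peak_idx))
    pre = profile.intensities[:first_peak_idx]
    if pre.size >= 3:
        thr = np.percentile(pre, intensity_percentile)
        low_idx = np.nonzero(pre <= thr)[0]
    else:
        low_idx = np.array([], dtype=int)
    region = frac_idx if frac_idx.size >= low_idx.size else low_idx
    if region.size < 2:
        region = np.arange(max(2, min(3, first_peak_idx)))
    return region


def locate_x0(profile: IntensityProfile, first_peak_idx: int,
              smooth_window: int = SMOOTH_WINDOW,
              anterior_fraction: float = 0.15,
              intensity_percentile: float = 20.0,
              r2_tie_tol: float = 1e-6) -> tuple[float, float, bool]:
    """Anterior border X0 of the first stripe.

    Steps: fit the background line on the anterior baseline segment; find the
    inflection point (maximum smoothed first difference, ties toward the peak)
    on the anterior flank; grow regression windows anteriorly from the
    inflection point, keep the one with the highest r^2 (ties broken toward
    the longer window); X0 is the abscissa where that line meets the
    background line.  Returns (x0, r2, low_confidence_flag).
    """
    x = profile.positions
    y = profile.intensities
    if first_peak_idx < 5:
        raise ValueError("first peak needs >= 5 samples on its anterior flank")

    base_idx = _baseline_region(profile, first_peak_idx, anterior_fraction,
                                intensity_percentile)
    base_fit = stats.linregress(x[base_idx], y[base_idx])
    m_b, b_b = base_fit.slope, base_fit.intercept

    ys = _smooth(y, smooth_window)
    flank = slice(int(base_idx[-1]), first_peak_idx + 1)
    d = np.diff(ys[flank])
    if d.size == 0:
        raise ValueError("empty anterior flank")
    # ties toward the peak: take the last index attaining the max derivative
    rel = np.nonzero(d == d.max())[0][-1]
    infl = flank.start + rel

    best: tuple[float, int, float, float] | None = None  # r2, length, m, b
    for start in range(infl - 2, -1, -1):
        xs = x[start:infl + 1]
        yw = y[start:infl + 1]
        if xs.size < 3:
            continue
        if np.allclose(yw, yw[0]):
            continue
        fit = stats.linregress(xs, yw)
        r2 = fit.rvalue**2
        length = xs.size
        if best is None or r2 > best[0] + r2_tie_tol or (
                abs(r2 - best[0]) <= r2_tie_tol and length > best[1]):
            best = (r2, length, fit.slope, fit.intercept)
    if best is None:
        raise ValueError("no valid regression window on the anterior flank")
    r2, _, m_f, b_f = best
    if abs(m_f - m_b) < 1e-12:
        raise ValueError("front line is parallel to the background line")
    x0 = (b_b - b_f) / (m_f - m_b)
    return float(x0), float(r2), bool(r2 < 0.5)


def expression_length(profile: IntensityProfile, x0: float) -> float:
    """her1-L: distance from X0 to the posterior end of the measured line."""
    if x0 > profile.positions[-1]:
        raise ValueError("x0 lies beyond the posterior end of the profile")
    return float(profile.positions[-1] - x0)


def measure_wavelength(profile: IntensityProfile,
                       min_prominence: float | None = None,
                       min_separation: float = HER1_MIN_SEPARATION_UM
                       ) -> WavelengthMeasurement:
    """Full stripe-profile measurement: wavelength, X0 and her1-L."""
    peaks = find_peaks(profile, min_prominence, min_separation)
    lam = anterior_wavelength(peaks)
    x0, r2, low = locate_x0(profile, int(peaks.peak_indices[0]))
    return WavelengthMeasurement(
        anterior_wavelength=lam,
        x0=x0,
        her1_L=expression_length(profile, x0),
        r2_of_front_fit=r2,
        low_confidence=low,
    )


def neuron_density(profile: IntensityProfile,
                   min_prominence: float | None = None,
                   min_separation: float = SOMA_MIN_SEPARATION_UM) -> float:
    """Soma peaks per 100 um of line."""
    if profile.span <= 0:
        raise ValueError("zero-length line")
    peaks = find_peaks(profile, min_prominence, min_separation,
                       smooth_window=3)
    return 100.0 * len(peaks) / profile.span


def threshold_area(image: np.ndarray, threshold: float,
                   pixel_scale: float) -> AreaMeasurement:
    """Area of pixels at or above ``threshold`` (signal-high convention)."""
    img = np.asarray(image, dtype=float)
    count = int(np.count_nonzero(img >= threshold))
    return AreaMeasurement(
        area=count * pixel_scale**2,
        threshold_used=threshold,
        foreground_pixel_count=count,
    )
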