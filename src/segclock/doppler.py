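"""Doppler-effect arithmetic linking anterior wavelength to segmentation period.

In a shortening presomitic mesoderm the anterior end moves into the incoming
gene-expression waves, so segments are laid down faster than the posterior
oscillations alone dictate.  The Doppler contribution ``D`` to the segmentation
rate ``R = 1/T`` scales with the tissue-shortening speed and inversely with the
anterior wavelength ``lambda_A``.  If shortening speed is unchanged between two
conditions, the Doppler term rescales by the wavelength ratio
``lambda_ref / lambda_perturbed``, and the perturbed rate is

    R' = R - D + D * (lambda_ref / lambda_perturbed),   T' = 1 / R'.

All rates are per minute, periods in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DopplerInputs:
    """Inputs for the period prediction.

    Parameters
    ----------
    T_ref : float
        Reference (wildtype) segmentation period in minutes.
    doppler_fraction : float
        Fraction of the reference rate attributed to the Doppler effect,
        in [0, 1).
    wavelength_ratio : float
        Reference anterior wavelength divided by the perturbed anterior
        wavelength (> 1 means the perturbed pattern has shorter waves).
    """

    T_ref: float
    doppler_fraction: float
    wavelength_ratio: float

    def __post_init__(self) -> None:
        if self.T_ref <= 0:
            raise ValueError(f"T_ref must be positive, got {self.T_ref}")
        if not 0 <= self.doppler_fraction < 1:
            raise ValueError(
                f"doppler_fraction must be in [0, 1), got {self.doppler_fraction}"
            )
        if self.wavelength_ratio <= 0:
            raise ValueError(
                f"wavelength_ratio must be positive, got {self.wavelength_ratio}"
            )


@dataclass(frozen=True)
class DopplerResult:
    """Rates and periods produced by :func:`predict_period`."""

    R_ref: float
    D_ref: float
    D_perturbed: float
    R_perturbed: float
    T_perturbed: float


def segmentation_rate(T: float) -> float:
    """Segmentation rate R = 1/T (per minute) for period ``T`` (minutes)."""
    if T <= 0:
        raise ValueError(f"period must be positive, got {T}")
    return 1.0 / T


def doppler_contribution(R: float, fraction: float) -> float:
    """Doppler contribution D = fraction * R (per minute)."""
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if R <= 0:
        raise ValueError(f"rate must be positive, got {R}")
    return fraction * R


def rescale_doppler(D: float, wavelength_ratio: float) -> float:
    """Rescale the Doppler contribution by the anterior-wavelength ratio.

    At equal tissue-shortening speed, D is inversely proportional to the
    anterior wavelength, so the perturbed contribution is
    ``D * (lambda_ref / lambda_perturbed)``.
    """
    if wavelength_ratio <= 0:
        raise ValueError(
            f"wavelength_ratio must be positive, got {wavelength_ratio}"
        )
    if D < 0:
        raise ValueError(f"Doppler contribution must be >= 0, got {D}")
    return D * wavelength_ratio


def predict_period(inputs: DopplerInputs) -> DopplerResult:
    """Predict the perturbed segmentation period from the wavelength ratio.

    With ``wavelength_ratio == 1`` the output period equals the reference,
    bit-exactly.  A ratio > 1 (shorter perturbed wavelength) shortens the
    predicted period.
    """
    R_ref = segmentation_rate(inputs.T_ref)
    if inputs.doppler_fraction == 0:
        D_ref = 0.0
        D_pert = 0.0
    else:
        D_ref = doppler_contribution(R_ref, inputs.doppler_fraction)
        D_pert = rescale_doppler(D_ref, inputs.wavelength_ratio)
    R_pert = R_ref - D_ref + D_pert
    if R_pert <= 0:
        raise ValueError(
            f"predicted rate is non-positive ({R_pert}); inputs are unphysical"
        )
    return DopplerResult(
        R_ref=R_ref,
        D_ref=D_ref,
        D_perturbed=D_pert,
        R_perturbed=R_pert,
        T_perturbed=1.0 / R_pert,
    )


def percent_change(reference: float, test: float) -> float:
    """Signed percent change 100 * (test - reference) / reference.

    Decreases are negative; callers report magnitudes where conventional.
    """
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (test - reference) / reference


def wavelength_ratio_for_period(
    T_ref: float, doppler_fraction: float, T_target: float
) -> float:
    """Invert :func:`predict_period`: the wavelength ratio giving ``T_target``.

    Closed form: R' = R (1 + f (r - 1))  =>  r = 1 + (R'/R - 1) / f.
    """
    if doppler_fraction <= 0:
        raise ValueError("inversion requires a positive doppler_fraction")
    R_ref = segmentation_rate(T_ref)
    R_target = segmentation_rate(T_target)
    return 1.0 + (R_target / R_ref - 1.0) / doppler_fraction
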