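"""Transgene copy-number estimation from genomic qPCR Ct tables.

Efficiency-corrected relative quantification: raw Ct values from primers
targeting the deltaD locus (or the venus ORF of the transgene) are normalized
to the in-group wildtype Ct per primer pair, converted to relative
concentrations with the primer's amplification efficiency, divided by the
sample's averaged deltaC relative concentration to calibrate loading error,
and averaged across primer pairs.  Total deltaD copies are twice the
calibrated relative concentration (wildtype carries 2 endogenous copies);
transgenic copies are total minus 2.  The aei point-mutant allele still
amplifies, so it counts as a deltaD copy in this assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ENDOGENOUS_COPIES = 2.0


@dataclass(frozen=True)
class PrimerMeta:
    primer_id: str
    target: str  # 'deltaD' | 'deltaC' | 'venus'
    efficiency: float = 2.0  # fold amplification per cycle

    def __post_init__(self) -> None:
        if self.target not in ("deltaD", "deltaC", "venus"):
            raise ValueError(f"unknown primer target {self.target!r}")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(
                f"efficiency must be in (1, 2.2], got {self.efficiency}"
            )


@dataclass
class QpcrTable:
    """Long-format well table plus primer metadata and genotype labels.

    ``wells`` columns: sample_id, primer_id, replicate, Ct.
    """

    wells: pd.DataFrame
    primers: dict[str, PrimerMeta]
    group_labels: dict[str, str]  # sample_id -> genotype ('WT' marks refs)

    def __post_init__(self) -> None:
        required = {"sample_id", "primer_id", "replicate", "Ct"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"well table missing columns {missing}")
        if (self.wells["Ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        counts = self.wells.groupby(["sample_id", "primer_id"]).size()
        if (counts < 2).any():
            raise ValueError("need >= 2 replicates per sample x primer")


@dataclass(frozen=True)
class StandardCurve:
    log10_dilutions: np.ndarray
    mean_Cts: np.ndarray
    slope: float
    intercept: float
    efficiency: float
    r2: float


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    rel_deltaD: float
    rel_deltaC: float
    calibrated: float
    total_copies: float
    transgenic_copies: float
    n_trials: int = 1
    sd_transgenic: float | None = None
    low_trial_flag: bool = False


def efficiency_from_curve(curve_points) -> StandardCurve:
    """Fit a standard curve (Ct vs log10 dilution) and derive the efficiency.

    ``curve_points``: iterable of (dilution, mean_Ct).  Efficiency is
    10**(-1/slope); a perfect doubling chemistry has slope -1/log10(2).
    """
    pts = list(curve_points)
    if len(pts) < 3:
        raise ValueError(f"need >= 3 dilution points, got {len(pts)}")
    dil = np.array([p[0] for p in pts], dtype=float)
    ct = np.array([p[1] for p in pts], dtype=float)
    logd = np.log10(dil)
    fit = stats.linregress(logd, ct)
    if fit.slope >= 0:
        raise ValueError(
            f"standard-curve slope must be negative, got {fit.slope:.3f}"
        )
    return StandardCurve(
        log10_dilutions=logd,
        mean_Cts=ct,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        r2=float(fit.rvalue**2),
    )


def relative_concentration(Ct_sample: float, Ct_reference: float,
                           efficiency: float) -> float:
    """Relative template concentration efficiency**(Ct_ref - Ct_sample)."""
    if not 1.0 < efficiency <= 2.2:
        raise ValueError(f"efficiency must be in (1, 2.2], got {efficiency}")
    return float(efficiency ** (Ct_reference - Ct_sample))


def _mean_ct(table: QpcrTable) -> pd.DataFrame:
    """Replicate-averaged Ct per sample x primer."""
    return (table.wells.groupby(["sample_id", "primer_id"])["Ct"]
            .mean().reset_index())


def copy_number(table: QpcrTable, *, venus_anchor: str | None = None
                ) -> list[CopyNumberResult]:
    """Per-sample deltaD copy-number estimates from a qPCR table.

    For every deltaD and deltaC primer pair, replicate-averaged Cts are turned
    into relative concentrations against the mean Ct of the wildtype reference
    samples for that primer; each sample's deltaD values are divided by its
    averaged deltaC relative concentration (loading calibration) and averaged
    across deltaD primer pairs.  When venus primers are present,
    ``venus_anchor`` names the transgenic sample whose deltaD-based estimate
    bridges venus relative concentrations onto the copy scale; the venus-based
    estimates then enter the same average.
    """
    mean_ct = _mean_ct(table)
    wt_samples = [s for s, g in table.group_labels.items() if g == "WT"]
    if not wt_samples:
        raise ValueError("no wildtype reference samples in group_labels")

    by_target: dict[str, list[str]] = {"deltaD": [], "deltaC": [], "venus": []}
    for pid, meta in table.primers.items():
        by_target[meta.target].append(pid)
    if not by_target["deltaC"]:
        raise ValueError("deltaC loading-calibrator primers are required")
    if not by_target["deltaD"]:
        raise ValueError("no deltaD primers in table")

    pivot = mean_ct.pivot(index="sample_id", columns="primer_id", values="Ct")
    samples = list(pivot.index)

    def rel_vs_wt(sample: str, primer: str) -> float:
        eff = table.primers[primer].efficiency
        ct_ref = float(np.mean([pivot.loc[w, primer] for w in wt_samples]))
        return relative_concentration(float(pivot.loc[sample, primer]),
                                      ct_ref, eff)

    rel_dc = {
        s: float(np.mean([rel_vs_wt(s, p) for p in by_target["deltaC"]]))
        for s in samples
    }
    if any(not np.isfinite(v) or v <= 0 for v in rel_dc.values()):
        raise ValueError("invalid deltaC calibrator concentrations")

    # deltaD estimates, loading-calibrated per sample
    calibrated_dd = {
        s: [rel_vs_wt(s, p) / rel_dc[s] for p in by_target["deltaD"]]
        for s in samples
    }

    # venus primers amplify only the transgene, so the venus route estimates
    # transgenic copies directly, bridged through the anchor sample's
    # deltaD-based estimate; totals add the 2 endogenous copies back
    venus_totals: dict[str, list[float]] = {s: [] for s in samples}
    if by_target["venus"]:
        if venus_anchor is None:
            raise ValueError(
                "venus primers present: venus_anchor sample must be given"
            )
        anchor_tg = (ENDOGENOUS_COPIES * float(np.mean(calibrated_dd[venus_anchor]))
                     - ENDOGENOUS_COPIES)
        for p in by_target["venus"]:
            eff = table.primers[p].efficiency
            ct_anchor = float(pivot.loc[venus_anchor, p])
            for s in samples:
                rel = relative_concentration(float(pivot.loc[s, p]),
                                             ct_anchor, eff)
                rel_corrected = rel * rel_dc[venus_anchor] / rel_dc[s]
                venus_totals[s].append(
                    ENDOGENOUS_COPIES + rel_corrected * anchor_tg
                )

    results = []
    for s in samples:
        totals = ([ENDOGENOUS_COPIES * v for v in calibrated_dd[s]]
                  + venus_totals[s])
        total = float(np.mean(totals))
        cal = total / ENDOGENOUS_COPIES
        results.append(CopyNumberResult(
            sample_id=s,
            rel_deltaD=float(np.mean([rel_vs_wt(s, p)
                                      for p in by_target["deltaD"]])),
            rel_deltaC=rel_dc[s],
            calibrated=cal,
            total_copies=total,
            transgenic_copies=total - ENDOGENOUS_COPIES,
        ))
    return results


def aggregate_trials(results: list[CopyNumberResult]) -> CopyNumberResult:
    """Average copy-number estimates for one sample across independent trials.

    Flags the aggregate when fewer than 3 trials are available (the study
    averages at least three).
    """
    if not results:
        raise ValueError("no trials to aggregate")
    ids = {r.sample_id for r in results}
    if len(ids) > 1:
        raise ValueError(f"trials mix samples: {ids}")
    tg = np.array([r.transgenic_copies for r in results])
    tot = np.array([r.total_copies for r in results])
    n = len(results)
    return CopyNumberResult(
        sample_id=results[0].sample_id,
        rel_deltaD=float(np.mean([r.rel_deltaD for r in results])),
        rel_deltaC=float(np.mean([r.rel_deltaC for r in results])),
        calibrated=float(np.mean([r.calibrated for r in results])),
        total_copies=float(np.mean(tot)),
        transgenic_copies=float(np.mean(tg)),
        n_trials=n,
        sd_transgenic=float(np.std(tg, ddof=1)) if n > 1 else None,
        low_trial_flag=n < 3,
    )
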