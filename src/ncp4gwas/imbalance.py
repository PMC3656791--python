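"""Allelic-imbalance quantification from Sanger peak heights.

Allele-specific expression in a heterozygote is measured as the ratio of
ratios (cDNA Q/q) / (gDNA Q/q): normalizing the cDNA peak ratio by the gDNA
ratio from the same animal cancels allele-specific dye and amplification
bias, since the gDNA of a heterozygote carries exactly one copy of each
allele. A gDNA mixing series provides an optional calibration curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PEAK_COLUMNS = ("cdna_Q", "cdna_q", "gdna_Q", "gdna_q")


@dataclass
class ImbalanceEstimate:
    tissue: str
    n: int
    mean_ratio: float          # mean ratio-of-ratios, natural scale
    t_statistic: float
    p_value: float
    paired: bool
    ratios: np.ndarray         # per-animal ratio-of-ratios


@dataclass
class CalibrationCurve:
    true_ratios: np.ndarray
    measured_ratios: np.ndarray
    intercept: float           # log scale
    slope: float


def ratio_of_ratios(row) -> float:
    """(cDNA Q/q) / (gDNA Q/q) for one animal's four peak heights."""
    heights = [float(row[c]) for c in PEAK_COLUMNS]
    if any(h <= 0 for h in heights):
        ident = row["animal_id"] if "animal_id" in row else "?"
        raise ValueError(f"non-positive peak height for animal {ident}")
    cq, cq2, gq, gq2 = heights
    return (cq / cq2) / (gq / gq2)


def peak_ratios(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-animal cDNA ratio, gDNA ratio and ratio-of-ratios."""
    out = traces[["animal_id", "tissue"]].copy()
    out["cdna_ratio"] = traces["cdna_Q"] / traces["cdna_q"]
    out["gdna_ratio"] = traces["gdna_Q"] / traces["gdna_q"]
    out["ratio_of_ratios"] = [ratio_of_ratios(r) for _, r in traces.iterrows()]
    return out


def fit_calibration(true_ratios: np.ndarray, measured_ratios: np.ndarray
                    ) -> CalibrationCurve:
    """Least-squares fit of log(measured) on log(true) over a mixing series."""
    t = np.asarray(true_ratios, float)
    m = np.asarray(measured_ratios, float)
    if len(np.unique(t)) < 2:
        raise ValueError("calibration series needs at least 2 distinct design points")
    if (t <= 0).any() or (m <= 0).any():
        raise ValueError("ratios must be positive")
    slope, intercept = np.polyfit(np.log(t), np.log(m), 1)
    return CalibrationCurve(t, m, float(intercept), float(slope))


def apply_calibration(raw_ratio, curve: CalibrationCurve):
    """Invert the calibration fit: true = exp((log(measured) - b0) / b1)."""
    raw = np.asarray(raw_ratio, float)
    return np.exp((np.log(raw) - curve.intercept) / curve.slope)


def imbalance_test(traces: pd.DataFrame, tissue: str | None = None,
                   paired: bool = False,
                   calibration: CalibrationCurve | None = None) -> ImbalanceEstimate:
    """Test cDNA Q/q ratios against gDNA Q/q ratios.

    Default is a two-sample Welch t-test of the per-animal cDNA ratios versus
    the gDNA ratios; ``paired=True`` runs a paired t-test on the same-animal
    differences. Two-sided p; identical constant groups give p = 1.
    """
    df = traces if tissue is None else traces[traces["tissue"] == tissue]
    if len(df) < 2:
        raise ValueError("need at least 2 animals")
    ratios = peak_ratios(df)
    cdna = ratios["cdna_ratio"].to_numpy()
    gdna = ratios["gdna_ratio"].to_numpy()
    if calibration is not None:
        cdna = apply_calibration(cdna, calibration)
        gdna = apply_calibration(gdna, calibration)
    ror = cdna / gdna
    if np.ptp(cdna) == 0 and np.ptp(gdna) == 0 and cdna[0] == gdna[0]:
        t_stat, p = 0.0, 1.0
    elif paired:
        t_stat, p = stats.ttest_rel(cdna, gdna)
    else:
        t_stat, p = stats.ttest_ind(cdna, gdna, equal_var=False)
    label = tissue if tissue is not None else str(df["tissue"].iloc[0])
    return ImbalanceEstimate(label, len(df), float(np.mean(ror)),
                             float(t_stat), float(p), paired, ror)
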