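"""Normalized dose coefficients, SSDE, and risk-surrogate evaluation.

The size-specific dose estimate scales the scanner's standardized output
(CTDIvol) by a size-dependent normalized dose coefficient,

    NDC(D) = a * exp(-b * D),        SSDE = NDC * CTDIvol,

with D a patient-size surrogate in cm — the water-equivalent diameter (WED)
or the geometric effective diameter (ED) — and (a, b) the TG-204 fit for the
32 cm PMMA reference phantom.  All package-internal lengths are mm; the
single mm→cm conversion happens at this boundary.

To judge how well a dose metric tracks a per-patient radiation risk index
RI (e.g. a lifetime-attributable-risk figure from an external dosimetry
chain), the metric is regressed against RI by ordinary least squares and two
figures of merit are derived:

* RSI (radiation sensitivity index): the regression slope normalized by
  mean(RI)/mean(metric).  Perfect proportionality between metric and RI
  gives RSI = 1; a metric carrying no risk information gives RSI → 0.
* RDI (risk differentiability index): RMSE of the regression divided by
  |slope|, in risk-index units — the risk resolution achievable when reading
  risk off the fitted line (0 is ideal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NdcModel",
    "TG204_32CM",
    "ndc",
    "ssde",
    "DoseEstimate",
    "dose_estimate",
    "RiskAssessment",
    "assess_risk_surrogate",
    "compare_surrogates",
]


@dataclass(frozen=True)
class NdcModel:
    """Exponential size model NDC(D) = a·exp(−b·D), D in cm."""

    a: float = 3.70469
    b: float = 0.03671937  # per cm
    reference_phantom: str = "32 cm PMMA"

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("NDC model coefficients must be positive")


#: TG-204 coefficients for the 32 cm PMMA reference phantom.
TG204_32CM = NdcModel()


def ndc(d_cm, model: NdcModel = TG204_32CM):
    """Normalized dose coefficient for size surrogate ``d_cm`` (WED or ED, cm)."""
    d = np.asarray(d_cm, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("size surrogate D must be non-negative")
    out = model.a * np.exp(-model.b * d)
    return float(out) if np.isscalar(d_cm) else out


def ssde(ndc_value, ctdivol_mgy):
    """Size-specific dose estimate: NDC × CTDIvol (mGy)."""
    cv = np.asarray(ctdivol_mgy, dtype=np.float64)
    if np.any(cv < 0):
        raise ValueError("CTDIvol must be non-negative")
    out = np.asarray(ndc_value, dtype=np.float64) * cv
    if np.isscalar(ndc_value) and np.isscalar(ctdivol_mgy):
        return float(out)
    return out


@dataclass(frozen=True)
class DoseEstimate:
    """NDC and SSDE derived from one size surrogate and one CTDIvol."""

    d_cm: float
    ndc: float
    ctdivol_mgy: float
    ssde_mgy: float
    source: str  # e.g. "WED-localizer", "WED-axial", "ED-localizer"


def dose_estimate(
    d_mm: float,
    ctdivol_mgy: float,
    source: str = "WED-localizer",
    model: NdcModel = TG204_32CM,
) -> DoseEstimate:
    """Build a :class:`DoseEstimate` from a size surrogate in mm."""
    d_cm = d_mm / 10.0
    coefficient = ndc(d_cm, model)
    return DoseEstimate(d_cm, coefficient, ctdivol_mgy, ssde(coefficient, ctdivol_mgy), source)


@dataclass(frozen=True)
class RiskAssessment:
    metric: str
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    rsi: float
    rdi: float  # cancers per 1000 patients per 100 mGy; nan when slope == 0
    n: int


def assess_risk_surrogate(
    metric_values: Sequence[float],
    risk_index: Sequence[float],
    metric: str = "metric",
    convention: str = "literal",
) -> RiskAssessment:
    """OLS regression of risk index on a dose metric, with RSI and RDI.

    ``convention`` selects the RSI normalization: ``"literal"`` divides the
    slope by mean(RI)/mean(metric) (so exact proportionality gives RSI = 1);
    ``"reciprocal"`` multiplies instead.
    """
    x = np.asarray(metric_values, dtype=np.float64)
    y = np.asarray(risk_index, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric and risk index must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need at least 3 patients for a regression")
    if np.ptp(x) == 0:
        raise ValueError(f"metric {metric!r} has zero variance")
    if x.mean() <= 0 or y.mean() <= 0:
        raise ValueError("metric and risk-index means must be positive")
    if convention not in ("literal", "reciprocal"):
        raise ValueError(f"unknown RSI convention {convention!r}")

    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    rmse = math.sqrt(float(np.mean(residuals**2)))
    mean_ratio = y.mean() / x.mean()
    rsi = fit.slope / mean_ratio if convention == "literal" else fit.slope * mean_ratio
    rdi = rmse / abs(fit.slope) if fit.slope != 0 else float("nan")
    return RiskAssessment(
        metric=metric,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        rmse=rmse,
        rsi=float(rsi),
        rdi=float(rdi),
        n=int(x.size),
    )


_REQUIRED_COHORT_COLUMNS = ("wed_mm", "ed_mm", "ctdivol_mgy", "ri")


def compare_surrogates(
    cohort: pd.DataFrame,
    convention: str = "literal",
    model: NdcModel = TG204_32CM,
) -> pd.DataFrame:
    """Evaluate NDC/SSDE from WED and ED, and bare CTDIvol, as risk surrogates.

    ``cohort`` needs columns ``wed_mm``, ``ed_mm``, ``ctdivol_mgy``, ``ri``.
    Returns one row per metric with columns Metric, R2, RSI, RDI (plus the
    raw regression coefficients), mirroring a surrogate-comparison table.
    """
    for col in _REQUIRED_COHORT_COLUMNS:
        if col not in cohort.columns:
            raise KeyError(f"cohort table is missing required column {col!r}")
    ctdivol = cohort["ctdivol_mgy"].to_numpy(dtype=np.float64)
    ndc_wed = ndc(cohort["wed_mm"].to_numpy(dtype=np.float64) / 10.0, model)
    ndc_ed = ndc(cohort["ed_mm"].to_numpy(dtype=np.float64) / 10.0, model)
    metrics = {
        "NDC WED": ndc_wed,
        "SSDE WED": ndc_wed * ctdivol,
        "NDC ED": ndc_ed,
        "SSDE ED": ndc_ed * ctdivol,
        "CTDIvol": ctdivol,
    }
    ri = cohort["ri"].to_numpy(dtype=np.float64)
    rows = []
    for name, values in metrics.items():
        a = assess_risk_surrogate(values, ri, metric=name, convention=convention)
        rows.append(
            {
                "Metric": name,
                "R2": a.r_squared,
                "RSI": a.rsi,
                "RDI": a.rdi,
                "slope": a.slope,
                "intercept": a.intercept,
                "RMSE": a.rmse,
                "n": a.n,
            }
        )
    return pd.DataFrame(rows)
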