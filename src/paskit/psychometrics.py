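"""Validation statistics for the Physical Analogue Scale.

Covers the toolkit's psychometric battery: internal consistency (Cronbach's
alpha) of item matrices collected with the PAS or a Visual Analogue Scale,
PAS–VAS concordance (Pearson correlation), curve-estimation regressions to
check that the PAS–VAS relationship is linear (linear, logarithmic,
quadratic and exponential fits, SPSS-style), and an accuracy report for
angle-estimation studies against a target angle (e.g. "hold 45 degrees").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "cronbach_alpha",
    "pearson_r",
    "CurveFitReport",
    "curve_estimation",
    "AccuracyReport",
    "accuracy_report",
]


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a persons x items matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / var(row sums)), with sample
    (ddof=1) variances.  Rows with any missing item are dropped (listwise
    deletion).  Invariant under a common affine rescaling of all items.
    """
    m = pd.DataFrame(items).dropna(axis=0, how="any").to_numpy(dtype=float)
    n, k = m.shape
    if k < 2:
        raise InputError("alpha needs at least two items")
    if n < 2:
        raise InputError("alpha needs at least two complete persons")
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("zero variance of total scores; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def pearson_r(a, b) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be equal-length 1-d vectors")
    if a.size < 3:
        raise InputError("correlation needs at least three pairs")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    res = st.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CurveFitReport:
    """R-squared of the four SPSS-style curve-estimation fits of VAS on PAS.

    ``shifts`` records the +1 shift applied to make logarithm arguments
    positive on scales that include 0; ``skipped`` lists fits whose domain
    could not be repaired by the shift.
    """

    r2: dict[str, float]
    shifts: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"r2": dict(self.r2), "shifts": dict(self.shifts), "skipped": list(self.skipped)}


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.rsquared)


def curve_estimation(pas, vas) -> CurveFitReport:
    """Fit linear, logarithmic, quadratic and exponential curves of VAS on PAS.

    Models (SPSS curve-estimation conventions):

    - linear:      vas ~ pas
    - logarithmic: vas ~ ln(pas)
    - quadratic:   vas ~ pas + pas^2
    - exponential: ln(vas) ~ pas  (R^2 reported on the log scale)

    If any argument of a logarithm is <= 0 (both scales start at 0), the
    variable is shifted by +1 before taking logs; the shift is recorded.
    """
    x = np.asarray(pas, dtype=float)
    y = np.asarray(vas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pas and vas must be equal-length 1-d vectors")
    if x.size < 4:
        raise InputError("curve estimation needs at least four pairs")

    report = CurveFitReport(r2={})
    report.r2["linear"] = _ols_r2(y, x[:, None])
    report.r2["quadratic"] = _ols_r2(y, np.column_stack([x, x**2]))

    x_shift = 1.0 if x.min() <= 0 else 0.0
    if (x + x_shift).min() > 0:
        if x_shift:
            report.shifts["logarithmic"] = x_shift
        report.r2["logarithmic"] = _ols_r2(y, np.log(x + x_shift)[:, None])
    else:
        report.skipped.append("logarithmic")

    y_shift = 1.0 if y.min() <= 0 else 0.0
    if (y + y_shift).min() > 0:
        if y_shift:
            report.shifts["exponential"] = y_shift
        report.r2["exponential"] = _ols_r2(np.log(y + y_shift), x[:, None])
    else:
        report.skipped.append("exponential")
    return report


@dataclass
class AccuracyReport:
    """Angle-estimation accuracy against a reference target."""

    n: int
    mean: float
    sd: float
    median: float
    reference: float
    t: float
    p: float
    per_device: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "reference": self.reference,
            "t": self.t,
            "p": self.p,
        }
        if self.per_device is not None:
            d["per_device"] = self.per_device.to_dict(orient="records")
        return d


def accuracy_report(angles, reference: float = 45.0, device_ids=None) -> AccuracyReport:
    """Summarise how accurately a target angle was estimated.

    One-sample two-sided t-test of the angles against ``reference``; the
    sign of t matches the sign of (mean - reference).  With ``device_ids``
    given, a per-device breakdown (n, mean, SD) is included.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise InputError("accuracy report needs at least two angles")
    if a.std(ddof=1) == 0:
        # degenerate: constant sample; t is 0 on target, +/-inf off target
        diff = a.mean() - reference
        t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        p = 1.0 if diff == 0 else 0.0
    else:
        t, p = st.ttest_1samp(a, popmean=reference)
    per_device = None
    if device_ids is not None:
        df = pd.DataFrame({"device_id": list(device_ids), "angle": a})
        per_device = (
            df.groupby("device_id")["angle"]
            .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
            .reset_index()
        )
    return AccuracyReport(
        n=int(a.size),
        mean=float(a.mean()),
        sd=float(a.std(ddof=1)),
        median=float(np.median(a)),
        reference=float(reference),
        t=float(t),
        p=float(p),
        per_device=per_device,
    )
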