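"""Figures of merit and statistical validation.

Prediction quality of a multicomponent calibration is summarized per
component by: percentage recoveries on the validation set, their mean and
sample standard deviation, the root mean square error of prediction
RMSEP = sqrt(sum(e^2)/n), the standard error of prediction
SEP = sqrt(sum(e^2)/(n-2)) (so SEP/RMSEP = sqrt(n/(n-2)) on the same
residuals; their closeness is the usual overfitting check), the
predicted-versus-actual regression line (slope, intercept, Pearson r), and
detection/quantification limits LOD = 3.3*s/S and LOQ = 10*s/S with s the
regression residual standard deviation and S the slope (hence
LOQ = LOD*10/3.3 identically).

The SEP convention here uses the n-2 denominator with no bias subtraction:
it is the only convention consistent with published (SEP, RMSEP) pairs for
this assay at n=10. The bias-corrected n-1 alternative is available via
``sep(..., convention="biased-n1")`` for comparison.

Method comparison uses the pooled-variance two-sample t test (two-sided,
alpha=0.05) and the variance-ratio F test with the larger variance in the
numerator (one-tailed upper critical value at alpha=0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "recovery_percent",
    "summarize_recoveries",
    "rmsep",
    "sep",
    "pred_actual_regression",
    "lod_loq",
    "standard_addition",
    "compare_methods",
    "ComponentMerit",
    "MeritReport",
    "MethodComparison",
    "StandardAdditionResult",
    "build_merit_report",
]


def recovery_percent(predicted, actual):
    """100 x predicted / actual, elementwise; actual must be positive."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if np.any(actual <= 0):
        raise ValueError("actual concentrations must be > 0 for recovery")
    return 100.0 * predicted / actual


def summarize_recoveries(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of recoveries."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 recoveries to summarize")
    return float(values.mean()), float(values.std(ddof=1))


def _residuals(predicted, actual) -> np.ndarray:
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: predicted {predicted.shape}, actual {actual.shape}"
        )
    return predicted - actual


def rmsep(predicted, actual) -> float:
    """Root mean square error of prediction, sqrt(sum(e^2)/n)."""
    e = _residuals(predicted, actual)
    if e.size < 1:
        raise ValueError("need at least one residual")
    return float(np.sqrt(np.mean(e**2)))


def sep(predicted, actual, convention: str = "n-2") -> float:
    """Standard error of prediction.

    ``"n-2"`` (default): sqrt(sum(e^2)/(n-2)), no bias subtraction.
    ``"biased-n1"``: sqrt(sum((e - mean(e))^2)/(n-1)), the bias-corrected
    alternative, provided for comparison only.
    """
    e = _residuals(predicted, actual)
    if e.size < 3:
        raise ValueError("SEP requires at least 3 residuals")
    if convention == "n-2":
        return float(np.sqrt(np.sum(e**2) / (e.size - 2)))
    if convention == "biased-n1":
        return float(np.sqrt(np.sum((e - e.mean()) ** 2) / (e.size - 1)))
    raise ValueError(f"unknown SEP convention {convention!r}")


def pred_actual_regression(predicted, actual) -> tuple[float, float, float, float]:
    """OLS of predicted on actual: (slope, intercept, r, s_residual).

    s_residual is the standard deviation of the regression residuals with
    n-2 degrees of freedom.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.size != actual.size or predicted.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.var(actual) == 0:
        raise ValueError("actual values are degenerate (zero variance)")
    x = actual - actual.mean()
    y = predicted - predicted.mean()
    slope = float((x @ y) / (x @ x))
    intercept = float(predicted.mean() - slope * actual.mean())
    denom = np.sqrt((x @ x) * (y @ y))
    r = float((x @ y) / denom) if denom > 0 else 0.0
    resid = predicted - (intercept + slope * actual)
    s_resid = float(np.sqrt(np.sum(resid**2) / (predicted.size - 2)))
    return slope, intercept, r, s_resid


def lod_loq(s_residual: float, slope: float) -> tuple[float, float]:
    """ICH-style limits: LOD = 3.3 s/S, LOQ = 10 s/S (= LOD * 10/3.3)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if s_residual < 0:
        raise ValueError("residual standard deviation must be >= 0")
    lod = 3.3 * s_residual / slope
    return float(lod), float(lod * 10.0 / 3.3)


@dataclass(frozen=True)
class StandardAdditionResult:
    taken: float
    added_levels: np.ndarray
    recoveries: np.ndarray  # % of the added amount recovered, per level
    mean: float
    sd: float


def standard_addition(
    base_predicted_taken: float, spiked_predictions, added_levels
) -> StandardAdditionResult:
    """Recovery of spiked standard additions.

    recovery_i = 100 * (predicted_spiked_i - taken) / added_i, i.e. computed
    on the added increment only.
    """
    spiked = np.asarray(spiked_predictions, dtype=float)
    added = np.asarray(added_levels, dtype=float)
    if spiked.shape != added.shape:
        raise ValueError("spiked predictions and added levels must align")
    if np.any(added <= 0):
        raise ValueError("added amounts must be > 0")
    rec = 100.0 * (spiked - base_predicted_taken) / added
    mean, sd = summarize_recoveries(rec)
    return StandardAdditionResult(
        taken=float(base_predicted_taken),
        added_levels=added,
        recoveries=rec,
        mean=mean,
        sd=sd,
    )


@dataclass(frozen=True)
class MethodComparison:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    t_critical: float
    t_df: int
    f_statistic: float
    f_critical: float
    f_df: tuple[int, int]


def compare_methods(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    alpha: float = 0.05,
) -> MethodComparison:
    """Pooled-variance t test and variance-ratio F test from summary stats.

    t is two-sided with df = n1+n2-2; F puts the larger variance in the
    numerator with its df first and uses the one-tailed upper critical value.
    """
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be > 0")
    v1, v2 = sd1**2, sd2**2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t_stat = abs(mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    if v1 >= v2:
        f_stat, f_df = v1 / v2, (n1 - 1, n2 - 1)
    else:
        f_stat, f_df = v2 / v1, (n2 - 1, n1 - 1)
    f_crit = float(stats.f.ppf(1.0 - alpha, *f_df))
    return MethodComparison(
        mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2,
        t_statistic=float(t_stat), t_critical=t_crit, t_df=df,
        f_statistic=float(f_stat), f_critical=f_crit, f_df=f_df,
    )


@dataclass(frozen=True)
class ComponentMerit:
    name: str
    recoveries: np.ndarray
    mean_recovery: float
    sd_recovery: float
    slope: float
    intercept: float
    r: float
    s_residual: float
    sep: float
    rmsep: float
    lod: float
    loq: float


@dataclass(frozen=True)
class MeritReport:
    components: tuple[ComponentMerit, ...]

    def __getitem__(self, name: str) -> ComponentMerit:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        out = {}
        for c in self.components:
            out[c.name] = {
                "recoveries_percent": [float(v) for v in c.recoveries],
                "mean_recovery": c.mean_recovery,
                "sd_recovery": c.sd_recovery,
                "slope": c.slope,
                "intercept": c.intercept,
                "r": c.r,
                "sep": c.sep,
                "rmsep": c.rmsep,
                "lod": c.lod,
                "loq": c.loq,
            }
        return out


def build_merit_report(
    predicted: np.ndarray, actual: np.ndarray, component_names
) -> MeritReport:
    """Full per-component validation summary from predicted/actual matrices."""
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must share a shape")
    if predicted.shape[1] != len(tuple(component_names)):
        raise ValueError("component_names must match the number of columns")
    comps = []
    for j, name in enumerate(component_names):
        p, a = predicted[:, j], actual[:, j]
        rec = recovery_percent(p, a)
        mean, sd = summarize_recoveries(rec)
        slope, intercept, r, s_resid = pred_actual_regression(p, a)
        lod, loq = lod_loq(s_resid, slope)
        comps.append(
            ComponentMerit(
                name=name, recoveries=rec, mean_recovery=mean, sd_recovery=sd,
                slope=slope, intercept=intercept, r=r, s_residual=s_resid,
                sep=sep(p, a), rmsep=rmsep(p, a), lod=lod, loq=loq,
            )
        )
    return MeritReport(components=tuple(comps))
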