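"""Measurement-property statistics: ICC, SEM, MDC, sample size.

The reliability of repeated measurements (raters, sessions, or methods) is
modelled with the two-way crossed random-effects decomposition

    y_ij = mu + s_i + r_j + e_ij,   i = 1..n subjects, j = 1..k raters,

whose variance ratios define the intraclass correlation coefficient. Two
single-measure forms are provided (McGraw & Wong nomenclature):

* ``two_way_random_absolute_single`` — ICC(2,1), absolute agreement, raters
  a random sample (the default: raters are interchangeable);
* ``two_way_mixed_consistency_single`` — ICC(3,1), consistency, raters fixed.

Estimates come from the ANOVA mean squares (between-subjects MSB,
between-raters MSJ, residual MSE); 95% confidence intervals use the exact
F-distribution intervals for each form. Absolute measurement error is
summarised by the standard error of measurement, SEM = SD_pooled*sqrt(1-ICC)
(or sqrt(MSE)), and by the minimal detectable change, MDC = z*sqrt(2)*SEM
with z = 1 by default.

Usage follows the fitted-model idiom::

    res = ReliabilityModel.from_dataframe(df, "subject_id", "rater_id", "value").fit()
    res.icc, res.ci_low, res.ci_high, res.sem, res.mdc
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm

__all__ = [
    "ReliabilityModel",
    "ReliabilityResults",
    "SampleSizeSpec",
    "icc",
    "classify_icc",
    "sem",
    "mdc",
    "concurrent_validity",
    "sample_size_icc",
    "anova_mean_squares",
]

MODELS = ("two_way_random_absolute_single", "two_way_mixed_consistency_single")

#: Qualitative ICC bands; half-open at the midpoints of the published
#: cut-points (below 0.20 poor / 0.21-0.40 fair / 0.41-0.60 moderate /
#: 0.61-0.80 good / 0.81-1.00 very good) so every value gets a band.
_BAND_EDGES = (0.205, 0.405, 0.605, 0.805)
_BAND_NAMES = ("poor", "fair", "moderate", "good", "very_good")


class IncompleteDesignError(ValueError):
    """The ratings table is not a complete n x k crossed design."""


class DegenerateVarianceError(ValueError):
    """All measurements identical: ICC undefined."""


def anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (MSB, MSJ, MSE) of an n x k table."""
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssj = n * np.sum((rater_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssb - ssj
    msb = ssb / (n - 1)
    msj = ssj / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)  # guard tiny negative round-off
    return float(msb), float(msj), float(mse)


def classify_icc(icc_value: float) -> str:
    """Qualitative reliability band of an ICC value."""
    if not np.isfinite(icc_value) or icc_value > 1:
        raise ValueError(f"ICC must be finite and <= 1, got {icc_value}")
    for edge, name in zip(_BAND_EDGES, _BAND_NAMES):
        if icc_value < edge:
            return name
    return _BAND_NAMES[-1]


def mdc(sem_value: float, z: float = 1.0) -> float:
    """Minimal detectable change, MDC = z * sqrt(2) * SEM (default z = 1)."""
    if sem_value < 0:
        raise ValueError("SEM must be non-negative")
    if z <= 0:
        raise ValueError("z must be positive")
    return z * math.sqrt(2.0) * sem_value


@dataclass(frozen=True)
class ReliabilityResults:
    """Fitted reliability estimates for one n x k ratings table."""

    icc: float
    ci_low: float
    ci_high: float
    band: str
    sem: float
    mdc: float
    mean: float
    n_subjects: int
    k_raters: int
    model: str
    sem_method: str
    msb: float
    msj: float
    mse: float
    confidence: float = 0.95

    def summary(self) -> str:
        pct = int(round(self.confidence * 100))
        lines = [
            "Reliability (two-way ANOVA ICC)",
            "=" * 46,
            f"model:        {self.model}",
            f"n subjects:   {self.n_subjects}    k raters: {self.k_raters}",
            f"ICC:          {self.icc:.3f}  [{pct}% CI {self.ci_low:.3f}, "
            f"{self.ci_high:.3f}]  ({self.band})",
            f"mean:         {self.mean:.3f}",
            f"SEM ({self.sem_method}): {self.sem:.3f}",
            f"MDC:          {self.mdc:.3f}",
            f"mean squares: MSB={self.msb:.4g} MSJ={self.msj:.4g} "
            f"MSE={self.mse:.4g}",
        ]
        return "\n".join(lines)


class ReliabilityModel:
    """Two-way reliability model for an n-subject x k-rater ratings table.

    Parameters
    ----------
    data : (n, k) array_like
        One row per subject, one column per rater/session/method.
    """

    def __init__(self, data):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise IncompleteDesignError(f"expected n x k table, got {data.shape}")
        n, k = data.shape
        if n < 2 or k < 2:
            raise IncompleteDesignError(f"need n >= 2 subjects, k >= 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(data)):
            raise IncompleteDesignError("missing cells: design must be complete")
        self.data = data
        self.n, self.k = n, k

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject_id",
        rater_col: str = "rater_id",
        value_col: str = "value",
    ) -> "ReliabilityModel":
        """Build from a long table; each (subject, rater) must appear once."""
        if df.duplicated([subject_col, rater_col]).any():
            raise IncompleteDesignError("duplicate (subject, rater) cells")
        wide = df.pivot(index=subject_col, columns=rater_col, values=value_col)
        if wide.isna().any().any():
            raise IncompleteDesignError("missing cells: design must be complete")
        return cls(wide.to_numpy())

    def fit(
        self,
        model: str = "two_way_random_absolute_single",
        confidence: float = 0.95,
        sem_method: str = "sd_sqrt",
        mdc_z: float = 1.0,
    ) -> ReliabilityResults:
        """Estimate the ICC, its CI and the SEM/MDC error summaries."""
        if model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if sem_method not in ("sd_sqrt", "anova_error"):
            raise ValueError("sem_method must be 'sd_sqrt' or 'anova_error'")
        n, k = self.n, self.k
        msb, msj, mse = anova_mean_squares(self.data)
        if msb <= 0 and msj <= 0 and mse <= 0:
            raise DegenerateVarianceError("zero total variance: ICC undefined")
        alpha = 1.0 - confidence

        if model == "two_way_random_absolute_single":
            icc_val = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
            if mse == 0 and msj == 0:
                lo = hi = 1.0
            else:
                a = (k * icc_val) / (n * (1.0 - icc_val)) if icc_val < 1 else np.inf
                b = 1.0 + (k * icc_val * (n - 1)) / (n * (1.0 - icc_val)) if icc_val < 1 else np.inf
                if not np.isfinite(a):
                    lo = hi = 1.0
                else:
                    v = (a * msj + b * mse) ** 2 / (
                        (a * msj) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                    )
                    f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
                    f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
                    lo = n * (msb - f1 * mse) / (
                        f1 * (k * msj + (k * n - k - n) * mse) + n * msb
                    )
                    hi = n * (f2 * msb - mse) / (
                        k * msj + (k * n - k - n) * mse + n * f2 * msb
                    )
        else:  # two_way_mixed_consistency_single, ICC(3,1)
            icc_val = (msb - mse) / (msb + (k - 1) * mse)
            if mse == 0:
                lo = hi = 1.0
            else:
                fstat = msb / mse
                df2 = (n - 1) * (k - 1)
                fl = fstat / f_dist.ppf(1 - alpha / 2, n - 1, df2)
                fu = fstat * f_dist.ppf(1 - alpha / 2, df2, n - 1)
                lo = (fl - 1) / (fl + k - 1)
                hi = (fu - 1) / (fu + k - 1)

        icc_val = float(icc_val)
        lo = float(min(lo, icc_val))
        hi = float(min(max(hi, icc_val), 1.0))
        sem_val = self._sem(icc_val, sem_method, mse)
        return ReliabilityResults(
            icc=icc_val,
            ci_low=lo,
            ci_high=hi,
            band=classify_icc(icc_val),
            sem=sem_val,
            mdc=mdc(sem_val, z=mdc_z),
            mean=float(self.data.mean()),
            n_subjects=n,
            k_raters=k,
            model=model,
            sem_method=sem_method,
            msb=msb,
            msj=msj,
            mse=mse,
            confidence=confidence,
        )

    def _sem(self, icc_val: float, method: str, mse: float) -> float:
        # icc_val may fall below -1 for tiny-sample point estimates;
        # sqrt(1 - icc) is still well defined there
        if method == "anova_error":
            return float(math.sqrt(mse))
        sd_pooled = float(self.data.std(ddof=1))
        return sd_pooled * math.sqrt(max(1.0 - icc_val, 0.0))


def icc(
    data,
    model: str = "two_way_random_absolute_single",
    **fit_kwargs,
) -> ReliabilityResults:
    """Fit a reliability model to a wide (n, k) table or long DataFrame."""
    if isinstance(data, pd.DataFrame) and {"subject_id", "rater_id", "value"} <= set(
        data.columns
    ):
        m = ReliabilityModel.from_dataframe(data)
    else:
        m = ReliabilityModel(data)
    return m.fit(model=model, **fit_kwargs)


def sem(
    data,
    icc_value: float,
    method: str = "sd_sqrt",
) -> float:
    """Standard error of measurement for a ratings table at a given ICC.

    ``sd_sqrt``: SEM = pooled SD x sqrt(1 - ICC); ``anova_error``:
    SEM = sqrt(residual mean square).
    """
    if not -1.0 <= icc_value <= 1.0:
        raise ValueError(f"ICC outside [-1, 1]: {icc_value}")
    m = data if isinstance(data, ReliabilityModel) else (
        ReliabilityModel.from_dataframe(data)
        if isinstance(data, pd.DataFrame)
        else ReliabilityModel(data)
    )
    if method == "anova_error":
        return float(math.sqrt(anova_mean_squares(m.data)[2]))
    return m._sem(icc_value, method, anova_mean_squares(m.data)[2])


def concurrent_validity(
    method_a,
    method_b,
    model: str = "two_way_random_absolute_single",
    **fit_kwargs,
) -> ReliabilityResults:
    """Agreement between two measurement methods on the same subjects.

    The methods play the role of the two raters in the ICC model. Inputs are
    per-subject sequences aligned by position, or Series aligned by index.
    """
    if isinstance(method_a, pd.Series) and isinstance(method_b, pd.Series):
        joined = pd.concat([method_a, method_b], axis=1, join="outer")
        if joined.isna().any().any():
            raise IncompleteDesignError("methods cover different subjects")
        data = joined.to_numpy()
    else:
        a = np.asarray(method_a, dtype=np.float64)
        b = np.asarray(method_b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1:
            raise IncompleteDesignError(
                f"unpaired measurements: {a.shape} vs {b.shape}"
            )
        data = np.column_stack([a, b])
    return ReliabilityModel(data).fit(model=model, **fit_kwargs)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design of an ICC reliability study.

    rho0 — minimally acceptable (null) ICC; rho1 — expected ICC;
    alpha — one-sided type-I error; power — 1 - beta; k — ratings/subject.
    """

    rho0: float
    rho1: float
    alpha: float = 0.05
    power: float = 0.80
    k: int = 2

    def __post_init__(self):
        if not 0 <= self.rho0 < self.rho1 < 1:
            raise ValueError("need 0 <= rho0 < rho1 < 1")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0.5 < self.power < 1:
            raise ValueError("power must be in (0.5, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _fisher_icc(rho: float, k: int) -> float:
    # variance-stabilising transform of the intraclass correlation with k
    # replicates; reduces to the classic 0.5*ln((1+r)/(1-r)) at k = 2
    return 0.5 * math.log((1.0 + (k - 1) * rho) / (1.0 - rho))


def sample_size_icc(spec: SampleSizeSpec) -> int:
    """Subjects needed to show ICC > rho0 when the true ICC is rho1.

    Uses the variance-stabilising transform of the ICC, whose sampling
    variance is approximately k / (2 (k-1) (n-2)); the smallest integer n
    satisfying the one-sided normal-test power requirement is returned.
    """
    z0 = _fisher_icc(spec.rho0, spec.k)
    z1 = _fisher_icc(spec.rho1, spec.k)
    za = norm.ppf(1.0 - spec.alpha)
    zb = norm.ppf(spec.power)
    n_real = 2.0 + spec.k / (2.0 * (spec.k - 1)) * ((za + zb) / (z1 - z0)) ** 2
    return max(int(math.ceil(n_real)), 2)
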