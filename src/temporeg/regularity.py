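"""Temporal regularity (TR) of a visit series.

TR is the coefficient of variation (COV) of the intervals between
consecutive qualifying primary-care visits: the standard deviation of the
inter-visit interval divided by its mean.  TR = 0 means perfectly evenly
spaced visits; larger TR means a less temporally regular pattern.  Because
COV is scale-free it is comparable across patients with different absolute
visit frequencies.

The module also provides the distributional diagnostics used to justify
dichotomising TR (Jarque-Bera normality test with Q-Q pairs) and the
dichotomisation itself: either the empirical least-regular quintile
(flag the top 20% of COV values) or a fixed COV threshold (1.2 by default,
the quintile boundary observed in the reference cohort).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, InsufficientVisitsError


def inter_visit_intervals(dates) -> np.ndarray:
    """Consecutive differences, in whole days, of a sorted visit-date series.

    Requires at least three distinct dates (two intervals); duplicate dates
    must have been collapsed upstream.
    """
    d = np.asarray(dates, dtype="datetime64[D]")
    if d.size < 3:
        raise InsufficientVisitsError(
            f"need at least 3 visit dates to form intervals, got {d.size}")
    if np.any(d[1:] <= d[:-1]):
        raise ValueError("visit dates must be strictly increasing "
                         "(collapse same-day visits upstream)")
    return np.diff(d).astype("timedelta64[D]").astype(int)


def coefficient_of_variation(intervals, *, ddof: int = 1) -> float:
    """SD of the intervals divided by their mean.

    ``ddof=1`` (sample SD) is the default; ``ddof=0`` gives the population
    variant.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise InsufficientVisitsError("COV needs at least 2 intervals")
    if np.any(x <= 0):
        raise ValueError("intervals must be positive")
    return float(np.std(x, ddof=ddof) / np.mean(x))


@dataclass
class TRScore:
    """Per-patient temporal-regularity score."""

    patient_id: str
    n_visits: int
    intervals: np.ndarray
    mean_interval: float
    sd_interval: float
    cov: float
    flagged: bool | None = None

    @classmethod
    def from_dates(cls, patient_id, dates, *, ddof: int = 1) -> "TRScore":
        iv = inter_visit_intervals(dates)
        mean = float(np.mean(iv))
        sd = float(np.std(iv, ddof=ddof))
        return cls(patient_id=str(patient_id), n_visits=int(iv.size + 1),
                   intervals=iv, mean_interval=mean, sd_interval=sd,
                   cov=sd / mean)


def score_cohort(visit_dates: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """Compute TR for every patient of a long (patient_id, date) table.

    Vectorised over patients; returns one row per patient with columns
    ``patient_id, n_visits, mean_interval, sd_interval, tr``.
    """
    df = visit_dates.sort_values(["patient_id", "date"])
    dates = df["date"].to_numpy(dtype="datetime64[D]")
    pid = df["patient_id"].to_numpy()
    gaps = np.diff(dates).astype("timedelta64[D]").astype(float)
    same = pid[1:] == pid[:-1]
    g = pd.DataFrame({"patient_id": pid[1:][same], "gap": gaps[same]})
    agg = g.groupby("patient_id", sort=True)["gap"].agg(
        n_intervals="size", mean_interval="mean",
        sd_interval=lambda v: v.std(ddof=ddof))
    agg = agg[agg["n_intervals"] >= 2].reset_index()
    agg["n_visits"] = agg.pop("n_intervals").astype(int) + 1
    agg["tr"] = agg["sd_interval"] / agg["mean_interval"]
    return agg[["patient_id", "n_visits", "mean_interval", "sd_interval", "tr"]]


@dataclass
class NormalityReport:
    """Jarque-Bera normality assessment with Q-Q pairs for plotting."""

    variable_name: str
    n: int
    skewness: float
    kurtosis: float
    jb_statistic: float
    p_value: float
    transform: str = "none"
    qq_pairs: np.ndarray = field(default=None, repr=False)

    def to_text(self) -> str:
        lines = [
            f"variable: {self.variable_name}",
            f"transform: {self.transform}",
            f"n: {self.n}",
            f"skewness: {self.skewness:.6g}",
            f"kurtosis: {self.kurtosis:.6g}",
            f"jb_statistic: {self.jb_statistic:.6g}",
            f"p_value: {self.p_value:.6g}",
            "qq_pairs (theoretical, empirical):",
        ]
        lines += [f"  {t:.6f}\t{e:.6f}" for t, e in self.qq_pairs]
        return "\n".join(lines)


def jarque_bera(values, *, variable_name: str = "tr",
                transform: str = "none") -> NormalityReport:
    """Moment-based normality test, asymptotically chi-squared with 2 df.

    JB = n/6 * (S^2 + (K - 3)^2 / 4) with S the (biased) sample skewness
    and K the (biased) sample kurtosis.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("Jarque-Bera needs at least 8 observations")
    n = x.size
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if m2 == 0:
        raise DegenerateDistributionError("zero variance: JB undefined")
    s = np.mean((x - mu) ** 3) / m2 ** 1.5
    k = np.mean((x - mu) ** 4) / m2 ** 2
    jb = n / 6.0 * (s ** 2 + (k - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    order = np.sort(x)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, loc=mu,
                          scale=np.sqrt(m2))
    return NormalityReport(variable_name=variable_name, n=n, skewness=float(s),
                           kurtosis=float(k), jb_statistic=float(jb),
                           p_value=p, transform=transform,
                           qq_pairs=np.column_stack([theo, order]))


def dichotomize(tr_values, *, rule: str = "empirical_quintile",
                threshold: float = 1.2) -> tuple[np.ndarray, float]:
    """Flag the least temporally regular patients.

    ``empirical_quintile``: threshold is the 80th percentile of the TR
    values (linear-interpolation quantile) and patients with TR >= threshold
    are flagged — the least-regular quintile.  ``fixed_threshold``: flag
    TR >= ``threshold``.  Returns ``(flags, threshold_used)``.
    """
    x = np.asarray(tr_values, dtype=float)
    if x.size == 0:
        raise ValueError("no TR values to dichotomize")
    if rule == "empirical_quintile":
        if np.all(x == x[0]):
            raise DegenerateDistributionError(
                "all TR values identical: quintile threshold undefined")
        threshold_used = float(np.quantile(x, 0.8))
    elif rule == "fixed_threshold":
        threshold_used = float(threshold)
    else:
        raise ValueError(f"unknown dichotomization rule: {rule!r}")
    return x >= threshold_used, threshold_used
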