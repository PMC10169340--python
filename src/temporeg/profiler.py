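"""Case-mix-adjusted clinic profiling by observed/expected (O/E) ratio.

For each clinic, O is the observed number of patients flagged as least
temporally regular and E is the expected number — the sum of the adjusted
model's predicted probabilities over the clinic's patients.  O/E = 1 means
the clinic has as many least-regular patients as its case mix predicts;
above 1 more, below 1 fewer.  Clinics below a minimum size (30 patients by
default) are excluded because small-clinic ratios are unstable.

When the model is fit by maximum likelihood with an intercept on the same
population being profiled, sum(E) = sum(O) over all clinics (the intercept
score equation), so the E-weighted mean O/E is exactly 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

OE_BAND = (0.90, 1.10)  # "as expected" band, inclusive on both ends


def clinic_counts(clinic_ids, flags, probabilities) -> pd.DataFrame:
    """Per-clinic patient count, observed flagged count O and expected E."""
    clinic = np.asarray(clinic_ids)
    o = np.asarray(flags, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if not (len(clinic) == len(o) == len(p)):
        raise ValueError("clinic_ids, flags and probabilities must align")
    if np.any(np.isnan(p)):
        raise DataError("patient without predicted probability")
    df = pd.DataFrame({"clinic_id": clinic, "flag": o, "prob": p})
    out = df.groupby("clinic_id", sort=True).agg(
        n_patients=("flag", "size"), observed=("flag", "sum"),
        expected=("prob", "sum")).reset_index()
    out["observed"] = out["observed"].astype(int)
    return out


def oe_scores(counts: pd.DataFrame, *, min_n: int = 30,
              poisson_ci: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """O/E per clinic with the minimum-size rule.

    Returns ``(scores, excluded)``: clinics with ``n_patients < min_n`` go
    to the exclusion list.  ``poisson_ci=True`` adds an exact Poisson 95%
    CI on O/E (not part of the default replication output).
    """
    small = counts["n_patients"] < min_n
    excluded = counts[small].reset_index(drop=True)
    scores = counts[~small].reset_index(drop=True).copy()
    if (scores["expected"] <= 0).any():
        bad = scores.loc[scores["expected"] <= 0, "clinic_id"].tolist()
        raise DataError(f"zero expected count for included clinic(s): {bad}")
    scores["oe"] = scores["observed"] / scores["expected"]
    if poisson_ci:
        o = scores["observed"].to_numpy()
        e = scores["expected"].to_numpy()
        lo = np.where(o > 0, stats.chi2.ppf(0.025, 2 * o) / 2.0, 0.0)
        hi = stats.chi2.ppf(0.975, 2 * (o + 1)) / 2.0
        scores["oe_ci_low"] = lo / e
        scores["oe_ci_high"] = hi / e
    return scores, excluded


@dataclass
class ProfileSummary:
    """Distribution summary of the included-clinic O/E scores."""

    n_clinics: int
    oe_min: float
    oe_max: float
    oe_median: float
    band_low: float
    band_high: float
    n_in_band: int
    pct_in_band: float
    e_weighted_mean: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def profile_summary(scores: pd.DataFrame,
                    band: tuple[float, float] = OE_BAND) -> ProfileSummary:
    """Min / max / median O/E, the share of clinics inside the
    as-expected band (inclusive bounds) and the E-weighted mean O/E."""
    if not len(scores):
        raise DataError("no clinics included in profile")
    oe = scores["oe"].to_numpy()
    in_band = (oe >= band[0]) & (oe <= band[1])
    return ProfileSummary(
        n_clinics=len(scores),
        oe_min=float(oe.min()), oe_max=float(oe.max()),
        oe_median=float(np.median(oe)),
        band_low=band[0], band_high=band[1],
        n_in_band=int(in_band.sum()),
        pct_in_band=float(100.0 * in_band.mean()),
        e_weighted_mean=float(scores["observed"].sum()
                              / scores["expected"].sum()),
    )


def ranked_series(scores: pd.DataFrame) -> pd.DataFrame:
    """Clinics ordered by O/E with a rank column, for plotting."""
    out = scores.sort_values("oe").reset_index(drop=True).copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def plot_oe(scores: pd.DataFrame, path=None):
    """Ordered O/E scatter across clinics (one point per clinic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = ranked_series(scores)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(ranked["rank"], ranked["oe"], s=12)
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.axhspan(*OE_BAND, color="grey", alpha=0.15)
    ax.set_xlabel("clinic (ranked by O/E)")
    ax.set_ylabel("observed / expected least-regular patients")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
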