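"""Synthetic HMO extract generator with known ground truth.

Emulates the study conditions of a large Israeli HMO chronic-disease
cohort: marginal demographics and condition prevalences matching the
reference cohort profile, a gamma-renewal visit process whose inter-visit
COV is driven by a patient-level linear predictor (ground-truth log odds
ratios) plus clinic-level random effects, visit durations straddling the
5-minute qualification threshold, and configurable fractions of patients
deliberately failing each eligibility filter.

The visit mechanism: inter-visit gaps are gamma with shape k = 1/cov^2, so
the interval COV is exactly the target (constant gaps when the target is
0).  Each patient's target COV is chosen so that the probability their
*sample* COV reaches the dichotomisation threshold (1.2) equals
``logistic(intercept + lp + clinic_effect)``, with the intercept set to
give ``baseline_flag_rate`` at lp = clinic_effect = 0.  Because the sample
COV of a handful of integer-day intervals has no convenient closed form,
that mapping is calibrated by Monte Carlo with the same measurement
pipeline (day rounding, same-day collapse) the downstream scorer applies,
making the flag a Bernoulli draw with exactly the modelled probability —
which is what lets the risk model recover the ground-truth coefficients.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from . import terms
from .codes import load_code_lists
from .errors import ConfigError
from .io import write_table
from .model import DesignSpec, encode_design

_STREAM = {"assign": 1, "clinic": 2, "demo": 3, "cond": 4, "lab": 5,
           "visits": 6, "decoy": 7, "proc": 8, "diag": 9}
_CALIBRATION_SEED = 20180101  # fixed: the curve is part of the mechanism
_CALIBRATION_REPS = 40_000

_DEFAULT_INELIGIBLE = {"under_40": 0.05, "no_index_condition": 0.05,
                       "hemodialysis": 0.02, "under_3_visits": 0.05}
_MODALITY_LEVELS = ["in_person", "video", "phone", "text"]
_MODALITY_PROBS = [0.70, 0.05, 0.15, 0.10]
_EGFR_VALUE_RANGES = {"60+": (60.0, 110.0), "45-59": (45.0, 59.9),
                      "30-44": (30.0, 44.9), "<30": (8.0, 29.9)}
# share of patients with eGFR labs in 2018-19 / only 2016-17 / never
_LAB_AVAILABILITY = [("recent", 0.960), ("older_only", 0.029), ("none", 0.011)]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_patients: int = 70_095
    n_clinics: int = 330
    clinic_size_concentration: float = 1.0
    study_window: tuple[str, str] = ("2018-01-01", "2019-12-31")  # half-open
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(terms.DEFAULT_PREVALENCES))
    true_log_odds: dict[str, float] = field(
        default_factory=lambda: dict(terms.DEFAULT_TRUE_LOG_ODDS))
    clinic_effect_sd: float = 0.3
    baseline_flag_rate: float = 0.20
    cov_threshold: float = 1.2
    mean_visits_per_2y: float = 12.0
    visit_duration_lognormal_params: tuple[float, float] = (math.log(5.0), 0.6)
    ineligible_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INELIGIBLE))
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_clinics < 1:
            raise ConfigError("n_patients and n_clinics must be >= 1")
        if self.clinic_size_concentration <= 0:
            raise ConfigError("clinic_size_concentration must be positive")
        start, end = (pd.Timestamp(d) for d in self.study_window)
        if end <= start:
            raise ConfigError("study_window end must be after start")
        for name, p in {**self.prevalences, **self.ineligible_fractions,
                        "baseline_flag_rate": self.baseline_flag_rate}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability out of [0,1]: {name}={p}")
        if sum(self.ineligible_fractions.values()) > 1.0:
            raise ConfigError("ineligible fractions sum above 1")
        if self.clinic_effect_sd < 0:
            raise ConfigError("clinic_effect_sd must be nonnegative")
        if self.mean_visits_per_2y <= 0:
            raise ConfigError("mean_visits_per_2y must be positive")
        unknown = set(self.true_log_odds) - set(terms.model_terms())
        if unknown:
            raise ConfigError(f"unknown true_log_odds terms: {sorted(unknown)}")

    @property
    def window_days(self) -> int:
        start, end = (pd.Timestamp(d) for d in self.study_window)
        return int((end - start).days)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["study_window"] = list(d["study_window"])
        d["visit_duration_lognormal_params"] = list(
            d["visit_duration_lognormal_params"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("study_window", "visit_duration_lognormal_params"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortBundle:
    """The five extract tables plus ground truth."""

    demographics: pd.DataFrame
    visits: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    procedures: pd.DataFrame
    ground_truth_patients: pd.DataFrame
    ground_truth_clinics: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"demographics": self.demographics, "visits": self.visits,
                "diagnoses": self.diagnoses, "labs": self.labs,
                "procedures": self.procedures}

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        for name, df in self.tables().items():
            write_table(df, directory / f"{name}.csv")
        write_table(self.ground_truth_patients,
                    directory / "ground_truth_patients.csv")
        write_table(self.ground_truth_clinics,
                    directory / "ground_truth_clinics.csv")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


def _truncated_poisson(rng, mean: float, minimum: int, size: int) -> np.ndarray:
    out = rng.poisson(mean, size)
    bad = out < minimum
    while bad.any():
        out[bad] = rng.poisson(mean, int(bad.sum()))
        bad = out < minimum
    return out


def _renewal_positions(target_cov, n_visits, n_days: int, rng):
    """Vectorised gamma-renewal day offsets.

    Returns ``(pos, mask)`` of shape (M, max_n): integer day offsets in
    [0, n_days-1], first visit at day 0, series rescaled to span the
    window; rows with target COV 0 get exactly equal integer gaps.
    """
    cov = np.asarray(target_cov, dtype=float)
    nv = np.asarray(n_visits, dtype=int)
    if np.any(nv < 2):
        raise ValueError("renewal series needs n_visits >= 2")
    m = len(nv)
    maxg = int(nv.max()) - 1
    span = n_days - 1
    k = np.where(cov > 0, 1.0 / np.maximum(cov, 1e-12) ** 2, 1.0)
    gaps = rng.gamma(np.broadcast_to(k[:, None], (m, maxg)))
    col = np.arange(maxg)[None, :]
    gmask = col < (nv - 1)[:, None]
    cum = np.cumsum(np.where(gmask, gaps, 0.0), axis=1)
    total = cum[np.arange(m), nv - 2]
    pos = np.rint(cum / total[:, None] * span).astype(np.int64)
    zero = cov <= 0
    if zero.any():
        g0 = span // (nv - 1)
        pos[zero] = ((col + 1) * g0[:, None])[zero]
    pos = np.concatenate([np.zeros((m, 1), np.int64), pos], axis=1)
    mask = np.concatenate([np.ones((m, 1), bool), gmask], axis=1)
    return pos, mask


def _sample_cov(pos, mask):
    """Sample COV of each row's positive integer gaps (same-day collapsed).

    Rows with fewer than three distinct dates yield NaN (they would be
    excluded from the cohort).
    """
    g = np.diff(pos, axis=1).astype(float)
    valid = mask[:, 1:] & (g > 0)
    n = valid.sum(axis=1)
    s = np.where(valid, g, 0.0).sum(axis=1)
    ss = np.where(valid, g * g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        var = np.maximum((ss - n * mean ** 2) / (n - 1), 0.0)
        cov = np.sqrt(var) / mean
    cov[n < 2] = np.nan
    return cov


def sample_visit_series(target_cov: float, n_visits: int, window,
                        rng: np.random.Generator) -> np.ndarray:
    """Visit dates for one patient: gamma-renewal gaps (shape 1/cov^2)
    rescaled to span the half-open window, rounded to whole days.

    A target COV of 0 produces exactly equal integer gaps.
    """
    if n_visits < 2:
        raise ValueError("n_visits must be >= 2")
    if target_cov < 0:
        raise ValueError("target_cov must be nonnegative")
    start, end = (pd.Timestamp(d) for d in window)
    n_days = int((end - start).days)
    pos, _ = _renewal_positions([target_cov], [n_visits], n_days, rng)
    return (np.datetime64(start.date()) + pos[0].astype("timedelta64[D]"))


_curve_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _calibration_grid() -> np.ndarray:
    return np.concatenate([
        np.arange(0.0, 0.7, 0.1),
        np.arange(0.7, 2.2, 0.05),
        np.arange(2.2, 4.01, 0.15),
    ])


def calibration_curve(config: GeneratorConfig):
    """Monte-Carlo map from target COV to P(sample COV >= threshold).

    Computed under the configured visit-count distribution with the exact
    downstream measurement (integer days, same-day collapse), conditioned
    on the series remaining eligible (>= 3 distinct dates).  Uses a fixed
    internal seed — the curve is part of the data-generating mechanism, not
    of a particular run — and is cached per configuration.
    """
    key = (round(config.mean_visits_per_2y, 6), round(config.cov_threshold, 6),
           config.window_days)
    if key in _curve_cache:
        return _curve_cache[key]
    rng = np.random.default_rng([_CALIBRATION_SEED])
    grid = _calibration_grid()
    probs = np.empty_like(grid)
    for i, c in enumerate(grid):
        nv = _truncated_poisson(rng, config.mean_visits_per_2y, 3,
                                _CALIBRATION_REPS)
        pos, mask = _renewal_positions(np.full(nv.shape, c), nv,
                                       config.window_days, rng)
        cov = _sample_cov(pos, mask)
        ok = ~np.isnan(cov)
        probs[i] = np.mean(cov[ok] >= config.cov_threshold)
    probs = np.maximum.accumulate(probs)
    probs += np.arange(len(probs)) * 1e-12  # strictly increasing for interp
    _curve_cache[key] = (grid, probs)
    return grid, probs


def regularity_from_linear_predictor(lp, clinic_effect,
                                     config: GeneratorConfig) -> np.ndarray:
    """Target COV such that P(flag) = logistic(intercept + lp + clinic).

    The intercept is ``logit(baseline_flag_rate)``; probabilities outside
    the calibrated range clamp to the grid ends.
    """
    grid, probs = calibration_curve(config)
    p = expit(logit(config.baseline_flag_rate)
              + np.asarray(lp, dtype=float)
              + np.asarray(clinic_effect, dtype=float))
    return np.interp(p, probs, grid)


def flag_probability_from_cov(target_cov, config: GeneratorConfig) -> np.ndarray:
    """Forward direction of the calibration curve (mainly for tests)."""
    grid, probs = calibration_curve(config)
    return np.interp(np.asarray(target_cov, dtype=float), grid, probs)


def _conditioned_index_probs(prevalences: dict[str, float]) -> np.ndarray:
    """Joint law of the index-condition triple, conditioned on >= 1 present,
    whose marginals equal the configured prevalences.

    Solves q_i = p_i * Z, Z = 1 - prod(1 - q_i) by fixed point, then
    enumerates the 7 non-empty combinations.
    """
    p = np.array([prevalences[c] for c in terms.INDEX_CONDITIONS])
    if p.max() <= 0:
        raise ConfigError("at least one index-condition prevalence must be > 0")
    z = 1.0
    for _ in range(200):
        q = np.clip(p * z, 0.0, 1.0)
        z_new = 1.0 - np.prod(1.0 - q)
        if abs(z_new - z) < 1e-14:
            break
        z = z_new
    q = np.clip(p * z, 0.0, 1.0)
    combos = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
              if a or b or c]
    w = np.array([np.prod(np.where(np.array(cb, bool), q, 1 - q))
                  for cb in combos])
    return np.array(combos, dtype=bool), w / w.sum()


def _weights(counts: dict[str, int], keys: list[str]) -> np.ndarray:
    w = np.array([counts[k] for k in keys], dtype=float)
    return w / w.sum()


def generate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate the full synthetic extract; deterministic for a fixed seed."""
    n = config.n_patients
    seed = config.seed
    start = pd.Timestamp(config.study_window[0])
    n_days = config.window_days
    patient_id = np.array([f"P{i:06d}" for i in range(n)])

    # planned ineligibility: each category fails exactly one filter
    frac = config.ineligible_fractions
    cats = ["eligible", "under_40", "no_index_condition", "hemodialysis",
            "under_3_visits"]
    probs = [1.0 - sum(frac.values()), frac.get("under_40", 0.0),
             frac.get("no_index_condition", 0.0), frac.get("hemodialysis", 0.0),
             frac.get("under_3_visits", 0.0)]
    planned = np.array(cats)[_rng(seed, "assign").choice(len(cats), n, p=probs)]

    # clinics: Dirichlet-multinomial sizes, normal random effects
    rng_c = _rng(seed, "clinic")
    clinic_ids = np.array([f"C{i:03d}" for i in range(config.n_clinics)])
    sizes = rng_c.dirichlet(np.full(config.n_clinics,
                                    config.clinic_size_concentration))
    clinic_idx = rng_c.choice(config.n_clinics, n, p=sizes)
    clinic_eff = (rng_c.normal(0.0, config.clinic_effect_sd, config.n_clinics)
                  if config.clinic_effect_sd > 0
                  else np.zeros(config.n_clinics))

    # demographics
    rng_d = _rng(seed, "demo")
    band = np.array(terms.AGE_LEVELS)[rng_d.choice(
        len(terms.AGE_LEVELS), n, p=_weights(terms.AGE_COUNTS, terms.AGE_LEVELS))]
    lo = np.array([terms.BIRTH_YEAR_BANDS[b][0] for b in band])
    hi = np.array([terms.BIRTH_YEAR_BANDS[b][1] for b in band])
    birth_year = rng_d.integers(lo, hi + 1)
    under40 = planned == "under_40"
    birth_year[under40] = rng_d.integers(1976, 1986, int(under40.sum()))
    sex = np.array(terms.SEX_LEVELS)[rng_d.choice(
        2, n, p=_weights(terms.SEX_COUNTS, terms.SEX_LEVELS))]
    ethnic = np.array(terms.ETHNIC_LEVELS)[rng_d.choice(
        3, n, p=_weights(terms.ETHNIC_COUNTS, terms.ETHNIC_LEVELS))]
    region = np.array(terms.REGION_LEVELS)[rng_d.choice(
        4, n, p=_weights(terms.REGION_COUNTS, terms.REGION_LEVELS))]
    ses_group = np.array(terms.SES_LEVELS)[rng_d.choice(
        4, n, p=_weights(terms.SES_COUNTS, terms.SES_LEVELS))]
    dlo = np.array([terms.SES_DECILES[g][0] for g in ses_group])
    dhi = np.array([terms.SES_DECILES[g][1] for g in ses_group])
    ses_decile = rng_d.integers(dlo, dhi + 1)
    smoker = rng_d.random(n) < config.prevalences.get("current_smoker", 0.0)

    # condition flags: index triple conditioned on >= 1, rest independent
    rng_cond = _rng(seed, "cond")
    combos, combo_p = _conditioned_index_probs(config.prevalences)
    idx_draw = combos[rng_cond.choice(len(combo_p), n, p=combo_p)]
    flags: dict[str, np.ndarray] = {}
    for j, cond in enumerate(terms.INDEX_CONDITIONS):
        flags[cond] = idx_draw[:, j].copy()
        flags[cond][planned == "no_index_condition"] = False
    for cond, prev in sorted(config.prevalences.items()):
        if cond in terms.INDEX_CONDITIONS or cond == "current_smoker":
            continue
        flags[cond] = rng_cond.random(n) < prev

    # kidney function and lab availability
    rng_l = _rng(seed, "lab")
    egfr_cat = np.array(terms.EGFR_LEVELS)[rng_l.choice(
        4, n, p=_weights(terms.EGFR_COUNTS, terms.EGFR_LEVELS))]
    avail = np.array([a for a, _ in _LAB_AVAILABILITY])[rng_l.choice(
        3, n, p=[p for _, p in _LAB_AVAILABILITY])]
    effective_egfr = np.where(avail == "none", "60+", egfr_cat)

    # linear predictor via the same encoding the risk model uses
    attrs = pd.DataFrame({
        "age_group": np.where(under40, "40-49", band),  # placeholder level;
        # under-40 patients never reach the model, any valid level works
        "sex": sex, "ethnic_group": ethnic, "region": region,
        "ses_group": ses_group, "egfr_category": effective_egfr,
        "current_smoker": smoker,
    })
    for cond in terms.PHYSICAL_CONDITIONS + terms.MENTAL_CONDITIONS:
        attrs[cond] = flags[cond]
    X, _ = encode_design(attrs, DesignSpec.default(), outcome=None,
                         drop_empty=False)
    lp = np.zeros(n)
    for term, beta in config.true_log_odds.items():
        lp += beta * X[term].to_numpy()
    ce = clinic_eff[clinic_idx]
    p_flag = expit(logit(config.baseline_flag_rate) + lp + ce)
    target_cov = regularity_from_linear_predictor(
        lp, ce, config)

    # visit series
    rng_v = _rng(seed, "visits")
    n_visits = _truncated_poisson(rng_v, config.mean_visits_per_2y, 3, n)
    u3 = planned == "under_3_visits"
    n_visits[u3] = rng_v.integers(1, 3, int(u3.sum()))
    multi = n_visits >= 2
    pos, mask = _renewal_positions(target_cov[multi], n_visits[multi],
                                   n_days, rng_v)
    rows = np.repeat(np.where(multi)[0], mask.sum(axis=1))
    offs = pos[mask]
    single = np.where(~multi)[0]
    rows = np.concatenate([rows, single])
    offs = np.concatenate([offs, rng_v.integers(0, n_days, len(single))])
    mu, sigma = config.visit_duration_lognormal_params
    p5 = norm.cdf((math.log(5.0) - mu) / sigma)
    dur = np.exp(mu + sigma * norm.ppf(rng_v.uniform(p5, 1.0, len(rows))))
    modality = np.array(_MODALITY_LEVELS)[rng_v.choice(
        4, len(rows), p=_MODALITY_PROBS)]
    visits = pd.DataFrame({
        "patient_id": patient_id[rows],
        "clinic_id": clinic_ids[clinic_idx[rows]],
        "provider_role": "family_physician",
        "date": pd.Timestamp(start) + pd.to_timedelta(offs, unit="D"),
        "duration_minutes": np.round(dur, 1),
        "modality": modality,
    })

    # decoy visits: short family-physician contacts and non-FP encounters
    rng_x = _rng(seed, "decoy")
    n_extra = rng_x.poisson(2.0, n)
    xrows = np.repeat(np.arange(n), n_extra)
    m = len(xrows)
    short = rng_x.random(m) < 0.6
    u_short = rng_x.uniform(1e-9, p5, m)
    u_any = rng_x.uniform(1e-9, 1.0 - 1e-9, m)
    xdur = np.where(short,
                    np.exp(mu + sigma * norm.ppf(u_short)),
                    np.exp(mu + sigma * norm.ppf(u_any)))
    xdur = np.round(xdur, 1)
    xdur[short] = np.minimum(xdur[short], 4.9)  # rounding must not re-qualify
    decoys = pd.DataFrame({
        "patient_id": patient_id[xrows],
        "clinic_id": clinic_ids[clinic_idx[xrows]],
        "provider_role": np.where(short, "family_physician", "other"),
        "date": pd.Timestamp(start) + pd.to_timedelta(
            rng_x.integers(0, n_days, m), unit="D"),
        "duration_minutes": xdur,
        "modality": np.array(_MODALITY_LEVELS)[rng_x.choice(
            4, m, p=_MODALITY_PROBS)],
    })
    visits = (pd.concat([visits, decoys], ignore_index=True)
              .sort_values(["patient_id", "date", "duration_minutes"])
              .reset_index(drop=True))

    # hemodialysis procedures (2015-2019 span)
    rng_p = _rng(seed, "proc")
    hd = np.where(planned == "hemodialysis")[0]
    n_events = rng_p.integers(3, 11, len(hd))
    prow = np.repeat(hd, n_events)
    span_start = pd.Timestamp("2015-01-01")
    span_days = int((pd.Timestamp("2019-12-31") - span_start).days) + 1
    procedures = pd.DataFrame({
        "patient_id": patient_id[prow],
        "procedure": np.repeat("hemodialysis", len(prow)),
        "date": span_start + pd.to_timedelta(
            rng_p.integers(0, span_days, len(prow)), unit="D"),
    }).sort_values(["patient_id", "date"]).reset_index(drop=True)

    # labs: lowest value realises the drawn category, in the window that
    # matches the availability pattern
    has_lab = avail != "none"
    lrows = np.where(has_lab)[0]
    n_labs = rng_l.integers(1, 4, len(lrows))
    lrep = np.repeat(lrows, n_labs)
    vlo = np.array([_EGFR_VALUE_RANGES[c][0] for c in egfr_cat[lrep]])
    vhi = np.array([_EGFR_VALUE_RANGES[c][1] for c in egfr_cat[lrep]])
    # every value is >= the category floor and one value (the first) is
    # inside the category band, so the per-patient minimum lands in-band
    values = rng_l.uniform(vlo, vhi)
    first = np.r_[True, lrep[1:] != lrep[:-1]] if len(lrep) else np.empty(0, bool)
    values[~first] = values[~first] + rng_l.uniform(0, 25, int((~first).sum()))
    recent = avail[lrep] == "recent"
    win_start = np.where(recent, pd.Timestamp("2018-01-01").value,
                         pd.Timestamp("2016-01-01").value)
    lab_off = rng_l.integers(0, 729, len(lrep))
    labs = pd.DataFrame({
        "patient_id": patient_id[lrep],
        "egfr": np.round(values, 1),
        "date": pd.to_datetime(win_start) + pd.to_timedelta(lab_off, unit="D"),
    }).sort_values(["patient_id", "date"]).reset_index(drop=True)

    # diagnoses: concrete codes drawn from the condition code lists
    rng_dx = _rng(seed, "diag")
    code_lists = load_code_lists()
    cond_start = pd.Timestamp("2016-01-01")
    cond_days = int((pd.Timestamp("2019-12-31") - cond_start).days) + 1
    dx_parts = []
    for cond in sorted(code_lists):
        if cond not in flags:
            continue
        pool = code_lists[cond].example_codes()
        who = np.where(flags[cond])[0]
        if not len(who) or not pool:
            continue
        counts = 1 + rng_dx.poisson(0.8, len(who))
        rep = np.repeat(who, counts)
        dx_parts.append(pd.DataFrame({
            "patient_id": patient_id[rep],
            "code": np.array(pool)[rng_dx.integers(0, len(pool), len(rep))],
            "code_system": code_lists[cond].code_system,
            "date": cond_start + pd.to_timedelta(
                rng_dx.integers(0, cond_days, len(rep)), unit="D"),
        }))
    if dx_parts:
        diagnoses = (pd.concat(dx_parts, ignore_index=True)
                     .sort_values(["patient_id", "date", "code"])
                     .reset_index(drop=True))
    else:
        diagnoses = pd.DataFrame({"patient_id": pd.Series(dtype=str),
                                  "code": pd.Series(dtype=str),
                                  "code_system": pd.Series(dtype=str),
                                  "date": pd.Series(dtype="datetime64[ns]")})

    demographics = pd.DataFrame({
        "patient_id": patient_id,
        "clinic_id": clinic_ids[clinic_idx],
        "birth_year": birth_year,
        "sex": sex, "ethnic_group": ethnic, "region": region,
        "ses_decile": ses_decile,
        "current_smoker": smoker.astype(int),
    })
    gt_patients = pd.DataFrame({
        "patient_id": patient_id,
        "planned_ineligible": planned,
        "linear_predictor": lp,
        "clinic_effect": ce,
        "flag_probability": p_flag,
        "target_cov": target_cov,
        "n_planned_visits": n_visits,
    })
    gt_clinics = pd.DataFrame({"clinic_id": clinic_ids,
                               "clinic_effect": clinic_eff})
    return CohortBundle(demographics=demographics, visits=visits,
                        diagnoses=diagnoses, labs=labs, procedures=procedures,
                        ground_truth_patients=gt_patients,
                        ground_truth_clinics=gt_clinics)
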