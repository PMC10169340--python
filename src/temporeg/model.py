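"""Logistic modelling of least-temporally-regular care.

The binary outcome is membership in the least-regular quintile (highest COV
of inter-visit intervals).  Predictors are the patient characteristics:
age band, sex, ethnic/cultural group, region, area-SES group, kidney
function, smoking and the chronic-condition flags, each categorical
predictor encoded as indicators against its reference level (age 40-49,
female, general population, Central region, highest SES, eGFR 60+,
condition absent).

The API follows the Model / Results idiom: build a
:class:`LogisticModel` from a design matrix and outcome (or use
:func:`fit_adjusted` straight from a scored cohort), call ``fit()`` and
work with the returned :class:`LogisticResults` — coefficients, Wald
standard errors, odds ratios with 95% CIs, p-values, the c-statistic and a
``summary()`` table.  Fitting is maximum likelihood via iteratively
reweighted least squares with step-halving (so the deviance is
non-increasing), Wald standard errors from the observed information, and
separation detection via a coefficient-magnitude bound.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from . import terms
from .errors import CollinearityError, ConvergenceWarning, DataError

Z_95 = 1.96  # Wald 95% CI multiplier


@dataclass(frozen=True)
class DesignSpec:
    """Predictor set: categoricals as (column, levels, reference) plus
    binary indicator columns."""

    categoricals: tuple = ()
    binaries: tuple = ()

    @classmethod
    def default(cls) -> "DesignSpec":
        return cls(categoricals=tuple(terms.CATEGORICAL_PREDICTORS),
                   binaries=tuple(terms.BINARY_PREDICTORS))

    def term_names(self) -> list[str]:
        out = []
        for col, levels, ref in self.categoricals:
            out.extend(terms.term_name(col, lv) for lv in levels if lv != ref)
        out.extend(self.binaries)
        return out

    def predictors(self) -> list[str]:
        return [c for c, _, _ in self.categoricals] + list(self.binaries)

    def restrict(self, predictor: str) -> "DesignSpec":
        """A spec containing only one predictor (for bivariate models)."""
        cats = tuple(c for c in self.categoricals if c[0] == predictor)
        bins = tuple(b for b in self.binaries if b == predictor)
        if not cats and not bins:
            raise KeyError(predictor)
        return DesignSpec(categoricals=cats, binaries=bins)


def encode_design(cohort: pd.DataFrame, spec: DesignSpec | None = None, *,
                  outcome: str = "flagged",
                  drop_empty: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """One row per patient: intercept plus indicator terms; outcome vector.

    Raises :class:`DataError` on category levels outside the spec; warns and
    drops indicator columns that are identically zero (rank preservation).
    """
    spec = spec or DesignSpec.default()
    if not len(cohort):
        raise DataError("empty cohort")
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(cohort))}
    for col, levels, ref in spec.categoricals:
        values = cohort[col]
        unseen = set(values.unique()) - set(levels)
        if unseen:
            raise DataError(f"unseen level(s) in {col!r}: {sorted(unseen)}")
        for lv in levels:
            if lv == ref:
                continue
            cols[terms.term_name(col, lv)] = (values == lv).to_numpy(float)
    for col in spec.binaries:
        cols[col] = cohort[col].astype(bool).to_numpy(float)
    X = pd.DataFrame(cols, index=cohort.index)
    if drop_empty:
        empty = [c for c in X.columns[1:] if not X[c].any()]
        if empty:
            warnings.warn(f"dropping all-zero design columns: {empty}",
                          stacklevel=2)
            X = X.drop(columns=empty)
    y = None
    if outcome is not None and outcome in cohort:
        y = cohort[outcome].astype(bool).to_numpy(float)
    return X, y


def concordance(predicted, outcome) -> float:
    """c-statistic: P(random event outranks random non-event); ties count
    one half.  Rank-based, O(n log n)."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predicted and outcome must have equal length")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise DataError("degenerate outcome: need events and non-events")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _deviance(y, eta):
    # -2 loglik of Bernoulli with logit link, numerically stable
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


class LogisticModel:
    """Binary-outcome logistic model on an encoded design matrix."""

    def __init__(self, X: pd.DataFrame, y):
        self.X = X
        self.y = np.asarray(y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.y.sum() == 0 or self.y.sum() == len(self.y):
            raise DataError("outcome has no events or no non-events")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    spec: DesignSpec | None = None) -> "LogisticModel":
        X, y = encode_design(cohort, spec)
        if y is None:
            raise DataError("cohort has no 'flagged' outcome column")
        return cls(X, y)

    def fit(self, max_iter: int = 100, tol: float = 1e-10,
            separation_bound: float = 15.0) -> "LogisticResults":
        X = self.X.to_numpy(float)
        y = self.y
        names = list(self.X.columns)
        n, p = X.shape

        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int(np.sum(diag > diag.max() * max(n, p) * np.finfo(float).eps))
        if rank < p:
            raise CollinearityError([names[i] for i in piv[rank:]])

        beta = np.zeros(p)
        eta = X @ beta
        dev = _deviance(y, eta)
        trace = [dev]
        converged = False
        for _ in range(max_iter):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            Xw = X * w[:, None]
            try:
                beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
            except np.linalg.LinAlgError as exc:
                raise CollinearityError(names) from exc
            # step-halve if the Newton step overshoots, so deviance never rises
            step = beta_new - beta
            new_dev = _deviance(y, X @ beta_new)
            halvings = 0
            while new_dev > dev + 1e-12 and halvings < 30:
                step /= 2.0
                beta_new = beta + step
                new_dev = _deviance(y, X @ beta_new)
                halvings += 1
            beta, eta = beta_new, X @ beta_new
            trace.append(new_dev)
            if abs(dev - new_dev) < tol:
                converged = True
                dev = new_dev
                break
            dev = new_dev

        separated = bool(np.max(np.abs(beta)) > separation_bound)
        if separated or not converged:
            converged = False
            warnings.warn(
                "logistic fit did not converge"
                + (" (possible separation)" if separated else ""),
                ConvergenceWarning, stacklevel=2)

        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        info = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return LogisticResults(
            model=self,
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            converged=converged, deviance_trace=np.asarray(trace),
        )


@dataclass
class LogisticResults:
    """Fitted logistic model: estimates, Wald inference, diagnostics."""

    model: LogisticModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    converged: bool
    deviance_trace: np.ndarray = field(repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.model.y)

    @property
    def deviance(self) -> float:
        return float(self.deviance_trace[-1])

    @property
    def intercept(self) -> float:
        return float(self.params["intercept"])

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("intercept"))

    def conf_int(self) -> pd.DataFrame:
        lo = np.exp(self.params - Z_95 * self.bse).drop("intercept")
        hi = np.exp(self.params + Z_95 * self.bse).drop("intercept")
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def c_statistic(self) -> float:
        return concordance(self.fittedvalues, self.model.y)

    def predict(self, X: pd.DataFrame, *, allow_unconverged: bool = False
                ) -> np.ndarray:
        """Predicted probability for encoded patient rows."""
        if not self.converged and not allow_unconverged:
            warnings.warn("predicting from an unconverged fit",
                          ConvergenceWarning, stacklevel=2)
        missing = [c for c in self.params.index if c not in X.columns]
        if missing:
            raise DataError(f"design is missing features: {missing}")
        return expit(X[self.params.index].to_numpy(float)
                     @ self.params.to_numpy())

    def table(self) -> pd.DataFrame:
        """OR table (term, OR, 95% CI, p, marker) mirroring the adjusted
        model report; markers * p<0.05, † p<0.001."""
        tab = pd.DataFrame({
            "coefficient": self.params.drop("intercept"),
            "se": self.bse.drop("intercept"),
            "or": self.odds_ratios,
        }).join(self.conf_int())
        tab["p_value"] = self.pvalues.drop("intercept")
        tab["marker"] = np.where(tab["p_value"] < 0.001, "†",
                                 np.where(tab["p_value"] < 0.05, "*", ""))
        tab.index.name = "term"
        return tab

    def summary(self) -> str:
        tab = self.table()
        lines = [
            "Least-regular-care logistic model",
            f"  n = {self.n_obs}, events = {int(self.model.y.sum())}, "
            f"converged = {self.converged}",
            f"  deviance = {self.deviance:.2f}, c-statistic = "
            f"{self.c_statistic:.3f}",
            f"  intercept = {self.intercept:+.4f}",
            "",
            f"{'term':<34}{'OR':>7}{'95% CI':>16}{'p':>11}",
        ]
        for term, row in tab.iterrows():
            ci = f"{row['ci_low']:.2f}, {row['ci_high']:.2f}"
            lines.append(f"{term:<34}{row['or']:>7.2f}{ci:>16}"
                         f"{row['p_value']:>10.2g} {row['marker']}")
        lines.append("")
        lines.append("* p < 0.05   † p < 0.001")
        return "\n".join(lines)

    def profile_clinics(self, clinic_ids, flags, *, min_n: int = 30,
                        design: pd.DataFrame | None = None):
        """Case-mix-adjusted clinic O/E profile from this fit (see
        :mod:`temporeg.profiler`)."""
        from .profiler import clinic_counts, oe_scores
        probs = (self.fittedvalues if design is None
                 else self.predict(design))
        counts = clinic_counts(clinic_ids, flags, probs)
        return oe_scores(counts, min_n=min_n)


def fit_adjusted(cohort: pd.DataFrame, spec: DesignSpec | None = None,
                 **fit_kw) -> LogisticResults:
    """Encode and fit the fully adjusted model on a scored cohort (needs a
    boolean ``flagged`` column)."""
    return LogisticModel.from_cohort(cohort, spec).fit(**fit_kw)


def bivariate_table(cohort: pd.DataFrame,
                    spec: DesignSpec | None = None) -> pd.DataFrame:
    """One unadjusted model per predictor; rows mirror the adjusted table.

    A predictor whose model fails (e.g. no variation) yields rows with NaN
    estimates and the error message, without aborting the other predictors.
    """
    spec = spec or DesignSpec.default()
    rows = []
    for predictor in spec.predictors():
        sub = spec.restrict(predictor)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_adjusted(cohort, sub)
            tab = res.table().reset_index()
            tab.insert(0, "predictor", predictor)
            tab["error"] = ""
            rows.append(tab)
        except Exception as exc:  # noqa: BLE001 - propagate per-predictor
            rows.append(pd.DataFrame([{
                "predictor": predictor, "term": predictor,
                "coefficient": np.nan, "se": np.nan, "or": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "marker": "", "error": str(exc)}]))
    return pd.concat(rows, ignore_index=True)
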