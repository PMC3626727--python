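"""Outcome estimation: bivariate tests, adjusted odds ratios, gamma cost model
with recycled predictions, and bias-corrected paired bootstrap intervals.

The modelling surface follows the Model/Results convention: a model object is
built from a patient-record table plus an outcome and covariate list, its
``fit()`` returns a results object carrying coefficient estimates, their
covariance, dispersion (gamma) and convenience methods (``odds_ratios``,
``adjusted_means``, ``summary``).

Fitting is maximum likelihood by IRLS through statsmodels GLM (binomial logit
for binary utilization/pattern outcomes; gamma with log link for costs, with
Pearson dispersion). Categorical covariates expand against fixed reference
levels: age 18-35, male, Northeast, employee, FFS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.96  # Wald multiplier used throughout, matching the reported intervals

DEFAULT_COVARIATES = ["age_group", "sex", "region", "employment", "plan_type",
                      "cci", "any_ms_symptom", "any_dmt_use",
                      "baseline_er", "baseline_hosp"]

_CATEGORICAL = {
    "age_group": ("18-35", ["36-45", "46-55", "56-65", "65+"]),
    "sex": ("male", ["female"]),
    "region": ("northeast", ["north_central", "south", "west", "unknown"]),
    "employment": ("employee", ["other"]),
    "plan_type": ("ffs", ["non_ffs", "missing"]),
}


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by the design; the MLE diverges."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the aliased terms."""


def build_design(records: pd.DataFrame, terms: list[str],
                 drop_constant: bool = False, check_rank: bool = True) -> pd.DataFrame:
    """Expand ``terms`` into a numeric design matrix with an intercept.

    Categorical terms expand to indicator columns against their fixed
    reference level; only levels observed in the data produce columns.
    With ``drop_constant=True``, indicator columns that are constant in this
    sample are silently dropped (useful inside subgroup fits where a level is
    structurally empty); otherwise constants surface as rank deficiency.
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(records))}
    for term in terms:
        if term in _CATEGORICAL:
            ref, levels = _CATEGORICAL[term]
            observed = set(records[term].unique())
            unexpected = observed - {ref} - set(levels)
            if unexpected:
                raise ValueError(f"unknown level(s) {sorted(unexpected)} in {term!r}")
            for lv in levels:
                if lv in observed:
                    cols[f"{term}[{lv}]"] = (records[term] == lv).to_numpy(float)
        else:
            cols[term] = records[term].to_numpy(float)
    X = pd.DataFrame(cols, index=records.index)
    if drop_constant:
        keep = ["const"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
        X = X[keep]
    if check_rank and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        aliased = _aliased_columns(X)
        raise RankDeficiencyError(f"design matrix rank deficient; aliased terms: {aliased}")
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns made redundant by earlier columns (pivoted QR surrogate)."""
    arr = X.to_numpy()
    aliased = []
    kept: list[int] = []
    for j in range(arr.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) < len(trial):
            aliased.append(X.columns[j])
        else:
            kept.append(j)
    return aliased


@dataclass
class GlmResults:
    """Estimates from a fitted GLM.

    Attributes mirror the usual results-object vocabulary: ``params`` and
    ``bse`` are Series indexed by term label, ``cov_params`` the coefficient
    covariance, ``dispersion`` the Pearson scale (gamma only).
    """

    outcome: str
    family: str                     # "logistic" | "gamma_log"
    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float
    n_obs: int
    n_iter: int
    converged: bool
    model: "OutcomeModel" = field(repr=False, default=None)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def conf_int(self) -> pd.DataFrame:
        lo = self.params - Z95 * self.bse
        hi = self.params + Z95 * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self) -> pd.DataFrame:
        """exp(beta) with Wald 95% intervals, per term (logistic fits)."""
        if self.family != "logistic":
            raise ValueError("odds ratios are defined for logistic fits only")
        ci = self.conf_int()
        with np.errstate(over="ignore"):  # a quasi-separated sparse level may
            out = pd.DataFrame({          # legitimately report an inf bound
                "term": self.params.index,
                "odds_ratio": np.exp(self.params.to_numpy()),
                "ci_lower": np.exp(ci["lower"].to_numpy()),
                "ci_upper": np.exp(ci["upper"].to_numpy()),
            })
        return out[out["term"] != "const"].reset_index(drop=True)

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        X = self.model.design_for(records)
        eta = X.to_numpy() @ self.params.reindex(X.columns).to_numpy()
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return np.exp(eta)

    def adjusted_means(self, exposure: str = "hra") -> tuple[float, float, float]:
        """Recycled predictions: average predicted outcome with the exposure
        forced to 1 for everyone, then to 0, and their difference."""
        rec = self.model.records
        r1 = rec.assign(**{exposure: 1})
        r0 = rec.assign(**{exposure: 0})
        m1 = float(self.predict(r1).mean())
        m0 = float(self.predict(r0).mean())
        return m1, m0, m1 - m0

    def summary(self) -> str:
        lines = [f"{self.family} fit: {self.outcome}  (n={self.n_obs}, "
                 f"iterations={self.n_iter}, dispersion={self.dispersion:.4g})",
                 f"{'term':<24}{'coef':>10}{'se':>10}{'lower':>10}{'upper':>10}"]
        ci = self.conf_int()
        for t in self.params.index:
            lines.append(f"{t:<24}{self.params[t]:>10.4f}{self.bse[t]:>10.4f}"
                         f"{ci.loc[t, 'lower']:>10.4f}{ci.loc[t, 'upper']:>10.4f}")
        return "\n".join(lines)


class OutcomeModel:
    """Base GLM over a patient-record table (one row per patient)."""

    family_name = ""

    def __init__(self, records: pd.DataFrame, outcome: str,
                 exposure: str = "hra",
                 covariates: list[str] | None = None,
                 drop_constant: bool = False):
        self.records = records.reset_index(drop=True)
        self.outcome = outcome
        self.exposure = exposure
        self.covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
        self.drop_constant = drop_constant
        self.terms = ([exposure] if exposure else []) + [t for t in self.covariates
                                                         if t != exposure]
        self.X = build_design(self.records, self.terms, drop_constant=drop_constant)

    @classmethod
    def from_records(cls, records, outcome, **kw):
        return cls(records, outcome, **kw)

    def design_for(self, records: pd.DataFrame) -> pd.DataFrame:
        X = build_design(records, self.terms, drop_constant=False, check_rank=False)
        return X.reindex(columns=self.X.columns, fill_value=0.0)

    def _family(self):
        raise NotImplementedError

    def _response(self) -> np.ndarray:
        return self.records[self.outcome].to_numpy(float)

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> GlmResults:
        y = self._response()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, self.X, family=self._family())
            res = glm.fit(maxiter=maxiter, tol=tol)
        self._check(res, y)
        try:
            n_iter = int(res.fit_history["iteration"])
        except (AttributeError, KeyError, TypeError):
            n_iter = 0
        return GlmResults(
            outcome=self.outcome, family=self.family_name,
            params=pd.Series(res.params, index=self.X.columns),
            cov_params=pd.DataFrame(np.asarray(res.cov_params()),
                                    index=self.X.columns, columns=self.X.columns),
            dispersion=float(res.scale), n_obs=len(y),
            n_iter=n_iter, converged=bool(res.converged), model=self)

    def _check(self, res, y) -> None:
        pass


class UtilizationModel(OutcomeModel):
    """Logistic regression for a binary outcome (utilization or treatment pattern)."""

    family_name = "logistic"

    def _family(self):
        return sm.families.Binomial()

    def _response(self):
        y = self.records[self.outcome].to_numpy(float)
        if not np.isin(y, [0.0, 1.0]).all():
            raise ValueError(f"outcome {self.outcome!r} is not binary")
        return y

    def _check(self, res, y) -> None:
        # complete separation: the MLE diverges and the fit reproduces every
        # observation. Quasi-separation on a sparse indicator (a huge but
        # finite coefficient with a huge SE) is kept, mirroring how sparse
        # categories are conventionally reported with very wide intervals.
        mu = np.asarray(res.fittedvalues)
        if 0.0 < y.mean() < 1.0 and np.all(np.abs(mu - y) < 1e-6):
            raise SeparationError(f"perfect separation fitting {self.outcome!r}")


class CostModel(OutcomeModel):
    """Gamma GLM with log link for strictly positive cost outcomes.

    Zero costs are handled before fitting per ``zero_policy``:
    ``half_min_positive`` (default) replaces zeros with half the smallest
    positive observed cost; ``exclude`` drops zero-cost rows.
    """

    family_name = "gamma_log"

    def __init__(self, records, outcome, exposure="hra", covariates=None,
                 zero_policy: str = "half_min_positive", drop_constant=False):
        records = records.copy()
        y = records[outcome].to_numpy(float)
        if (y < 0).any():
            raise ValueError("negative costs are not supported")
        if (y == 0).any():
            if zero_policy == "half_min_positive":
                pos = y[y > 0]
                if len(pos) == 0:
                    raise ValueError("all costs are zero; nothing to model")
                records.loc[records[outcome] == 0, outcome] = pos.min() / 2.0
            elif zero_policy == "exclude":
                records = records[records[outcome] > 0]
            else:
                raise ValueError(f"unknown zero_policy {zero_policy!r}")
        super().__init__(records, outcome, exposure=exposure,
                         covariates=covariates, drop_constant=drop_constant)
        self.zero_policy = zero_policy

    def _family(self):
        return sm.families.Gamma(link=sm.families.links.Log())

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> GlmResults:
        y = self._response()
        if np.ptp(y) == 0:
            # degenerate zero-dispersion sample: the ML solution is exact
            params = pd.Series(0.0, index=self.X.columns)
            params["const"] = math.log(float(y[0]))
            return GlmResults(outcome=self.outcome, family=self.family_name,
                              params=params,
                              cov_params=pd.DataFrame(0.0, index=self.X.columns,
                                                      columns=self.X.columns),
                              dispersion=0.0, n_obs=len(y), n_iter=0,
                              converged=True, model=self)
        return super().fit(maxiter=maxiter, tol=tol)


# ---------------------------------------------------------------------------
# bivariate (Table-1-style) summaries

def bivariate_table(records: pd.DataFrame, exposure: str = "hra",
                    continuous: tuple[str, ...] = ("age", "cci"),
                    categorical: tuple[str, ...] = ("age_group", "sex", "region",
                                                    "employment", "plan_type",
                                                    "any_ms_symptom", "any_dmt_use",
                                                    "baseline_er", "baseline_hosp"),
                    ) -> pd.DataFrame:
    """Group summaries with p-values: t-tests for continuous variables,
    chi-square tests for categorical ones. Degenerate variables (zero
    variance / single category) report a missing p-value rather than failing.
    """
    g1 = records[records[exposure] == 1]
    g0 = records[records[exposure] == 0]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both exposure groups must be non-empty")
    rows = []
    for var in continuous:
        x0, x1 = g0[var].to_numpy(float), g1[var].to_numpy(float)
        if np.ptp(x0) == 0 and np.ptp(x1) == 0:
            p = np.nan
            note = "degenerate"
        else:
            p = float(stats.ttest_ind(x1, x0, equal_var=True).pvalue)
            note = ""
        rows.append((var, "mean (SD)",
                     f"{x0.mean():.2f} ({x0.std(ddof=1):.2f})",
                     f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})", p, "t-test", note))
    for var in categorical:
        levels = sorted(records[var].astype(str).unique())
        tab = np.array([[(g[var].astype(str) == lv).sum() for g in (g0, g1)]
                        for lv in levels])
        if len(levels) < 2 or (tab.sum(axis=1) == 0).any():
            p, note = np.nan, "degenerate"
        else:
            p = float(stats.chi2_contingency(tab, correction=False)[1])
            note = ""
        for lv, (n0, n1) in zip(levels, tab):
            rows.append((var, lv,
                         f"{n0} ({100 * n0 / len(g0):.1f})",
                         f"{n1} ({100 * n1 / len(g1):.1f})", p, "chi-square", note))
    return pd.DataFrame(rows, columns=["variable", "level", "non_exposed",
                                       "exposed", "p_value", "test", "note"])


# ---------------------------------------------------------------------------
# bias-corrected paired bootstrap

@dataclass
class BootstrapResult:
    """Bias-corrected percentile bootstrap interval for one scalar estimate."""

    point: float
    se: float
    z0: float
    ci_lower: float
    ci_upper: float
    B: int
    seed: int | None
    replicates: np.ndarray = field(repr=False, default=None)


def _bc_interval(reps: np.ndarray, point: float, level: float = 0.95
                 ) -> tuple[float, float, float]:
    """Bias-corrected percentile interval from replicate estimates."""
    B = len(reps)
    if np.ptp(reps) == 0:
        warnings.warn("degenerate bootstrap distribution; zero-width interval")
        return 0.0, float(reps[0]), float(reps[0])
    prop = np.mean(reps < point)
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = float(stats.norm.ppf(prop))
    zc = stats.norm.ppf(0.5 + level / 2)
    a_lo = float(stats.norm.cdf(2 * z0 - zc))
    a_hi = float(stats.norm.cdf(2 * z0 + zc))
    lo, hi = np.quantile(reps, [a_lo, a_hi])
    return z0, float(lo), float(hi)


def bc_bootstrap(estimator, records: pd.DataFrame, B: int = 1000,
                 seed: int | None = None, max_failure_rate: float = 0.01):
    """Paired nonparametric bootstrap with bias-corrected percentile intervals.

    ``estimator`` maps a record table to a scalar or a vector of scalars; each
    of the B resamples of patients (with replacement) drives the whole
    estimator, so multi-component estimates (e.g. both recycled-prediction
    arms and their difference) stay paired. Reproducible from ``seed``.
    Returns a :class:`BootstrapResult`, or a list of them for vector
    estimators.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    point = np.atleast_1d(np.asarray(estimator(records), dtype=float))
    scalar = point.size == 1
    rng = np.random.default_rng(seed)
    n = len(records)
    reps, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx].reset_index(drop=True)
        try:
            reps.append(np.atleast_1d(np.asarray(estimator(sample), dtype=float)))
        except Exception:
            failures += 1
            if failures > max_failure_rate * B:
                raise RuntimeError(
                    f"estimator failed on {failures}/{B} bootstrap resamples") from None
    reps = np.asarray(reps)
    results = []
    for k in range(point.size):
        col = reps[:, k]
        se = float(col.std(ddof=1))
        z0, lo, hi = _bc_interval(col, float(point[k]))
        results.append(BootstrapResult(point=float(point[k]), se=se, z0=z0,
                                       ci_lower=lo, ci_upper=hi, B=B, seed=seed,
                                       replicates=col))
    return results[0] if scalar else results


def bootstrap_adjusted_costs(records: pd.DataFrame, outcome: str = "fu_cost_nondmt",
                             exposure: str = "hra",
                             covariates: list[str] | None = None,
                             B: int = 1000, seed: int | None = None,
                             zero_policy: str = "half_min_positive",
                             drop_constant: bool = False) -> dict[str, BootstrapResult]:
    """Adjusted mean costs under exposure/no-exposure and their difference,
    each with a paired bias-corrected bootstrap interval (Table-3 layout)."""

    def estimator(rec):
        fit = CostModel(rec, outcome, exposure=exposure, covariates=covariates,
                        zero_policy=zero_policy, drop_constant=drop_constant).fit()
        m1, m0, diff = fit.adjusted_means(exposure)
        return np.array([m1, m0, diff])

    exposed, unexposed, difference = bc_bootstrap(estimator, records, B=B, seed=seed)
    return {"exposed": exposed, "unexposed": unexposed, "difference": difference}
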