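"""Statistical inference: 2x2 odds ratios, chi-square and t tests, and
maximum-likelihood logistic regression.

The odds ratio convention throughout treats *high* quality of life as the
outcome success and guideline compliance (>= 600 MET-minutes/week) as the
exposure, so an OR > 1 means compliant participants have higher odds of high
QoL.  Crude OR confidence intervals use the Woolf (log-OR) method,
``exp(ln OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.

The logistic regression is fitted by iteratively reweighted least squares
(Fisher scoring), converging when the maximum absolute score falls below
``tol`` (default 1e-8) within ``max_iter`` (default 25) iterations, with
Wald 95% confidence intervals on exponentiated coefficients.  Perfect
separation and rank deficiency are detected and reported by covariate name.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

Z95 = 1.96  # Woolf CI critical value


class SeparationError(RuntimeError):
    """The likelihood is maximized at infinity for some covariate."""

    def __init__(self, term: str):
        super().__init__(
            f"perfect or quasi-perfect separation detected (term {term!r}); "
            "the odds ratio for this term is not identifiable"
        )
        self.term = term


class RankDeficiencyError(np.linalg.LinAlgError):
    """The design matrix has collinear columns."""

    def __init__(self, terms: Sequence[str]):
        super().__init__(f"collinear design columns: {', '.join(terms)}")
        self.terms = list(terms)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts.

    ``a`` = unexposed & low outcome, ``b`` = exposed & low, ``c`` = unexposed
    & high, ``d`` = exposed & high, so rows are exposure (< 600 / >= 600
    MET-minutes) and columns are outcome (low / high QoL).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_labels(cls, exposed, outcome_high) -> "ContingencyTable2x2":
        exposed = np.asarray(exposed, dtype=bool)
        high = np.asarray(outcome_high, dtype=bool)
        return cls(
            a=int(np.sum(~exposed & ~high)),
            b=int(np.sum(exposed & ~high)),
            c=int(np.sum(~exposed & high)),
            d=int(np.sum(exposed & high)),
        )

    def as_array(self) -> np.ndarray:
        """Rows = exposure (unexposed, exposed); columns = (low, high)."""
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to a zero cell


def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Crude odds ratio of high outcome for exposed vs unexposed, with the
    Woolf 95% CI.  Zero cells get the Haldane-Anscombe 0.5 correction and
    the result is flagged ``corrected``."""
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log((d / b) / (c / a))
    se = np.sqrt((1.0 / cells).sum())
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        corrected=corrected,
    )


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(statistic, df, p)``; no continuity correction.  A zero row or
    column marginal raises ``ValueError``.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def two_sample_t(
    x, y, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sample t test; pooled-variance by default, Welch otherwise.

    Returns ``(t, df, two-sided p)``.  Groups need n >= 2 and non-degenerate
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("degenerate variance in both groups")
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = float((x.mean() - y.mean()) / se)
    return t, float(df), float(2 * stats.t.sf(abs(t), df))


class LogisticRegressionIRLS(BaseEstimator):
    """Binary logistic regression by iteratively reweighted least squares.

    A scikit-learn style estimator exposing maximum-likelihood inference:
    after ``fit(X, y)`` the fitted attributes are ``params_`` (log-odds per
    term, intercept first when ``add_intercept``), ``cov_params_`` (inverse
    observed information), ``bse_``, ``converged_`` and ``n_iter_``.
    ``X`` may be a DataFrame (column names become term names) or an array.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the maximum absolute score (gradient).
    max_iter : int
        Fisher-scoring iteration cap.
    add_intercept : bool
        Prepend a constant column named ``intercept``.
    """

    def __init__(
        self, tol: float = 1e-8, max_iter: int = 25, add_intercept: bool = True
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.add_intercept = add_intercept

    # -- internal helpers -------------------------------------------------
    def _design(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            names = [f"x{i}" for i in range(mat.shape[1])]
        if self.add_intercept:
            mat = np.column_stack([np.ones(len(mat)), mat])
            names = ["intercept"] + names
        return mat, names

    @staticmethod
    def _check_rank(mat: np.ndarray, names: list[str]) -> None:
        # scale columns so pivoted QR flags near-collinearity meaningfully
        norms = np.linalg.norm(mat, axis=0)
        norms[norms == 0] = 1.0
        from scipy.linalg import qr

        r = qr(mat / norms, mode="r", pivoting=True)
        rdiag = np.abs(np.diag(r[0]))
        pivots = r[1]
        keep = rdiag > max(mat.shape) * np.finfo(float).eps * rdiag.max()
        if not keep.all():
            bad = [names[p] for p in pivots[~keep]]
            raise RankDeficiencyError(bad)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y) -> "LogisticRegressionIRLS":
        mat, names = self._design(X)
        yv = np.asarray(y, dtype=float)
        if set(np.unique(yv)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if yv.min() == yv.max():
            raise ValueError("outcome has no variation")
        self._check_rank(mat, names)

        beta = np.zeros(mat.shape[1])
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = mat @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            score = mat.T @ (yv - mu)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = mu * (1.0 - mu)
            info = (mat * w[:, None]).T @ mat
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                self._raise_separation(beta, names)
                raise
            beta = beta + step
            if np.max(np.abs(beta)) > 30:
                self._raise_separation(beta, names)
        if not converged and np.max(np.abs(beta)) > 10:
            self._raise_separation(beta, names)

        eta = mat @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (mat * w[:, None]).T @ mat
        cov = np.linalg.inv(info)

        self.term_names_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_params_ = pd.DataFrame(cov, index=names, columns=names)
        self.bse_ = pd.Series(np.sqrt(np.diag(cov)), index=names)
        self.converged_ = converged
        self.n_iter_ = it
        self.n_obs_ = len(yv)
        self.llf_ = float(
            np.sum(yv * np.log(mu + 1e-300) + (1 - yv) * np.log(1 - mu + 1e-300))
        )
        # sklearn-style aliases
        if self.add_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        return self

    @staticmethod
    def _raise_separation(beta: np.ndarray, names: list[str]):
        worst = int(np.argmax(np.abs(beta)))
        raise SeparationError(names[worst])

    def predict_proba(self, X) -> np.ndarray:
        mat, _ = self._design(X)
        p = 1.0 / (1.0 + np.exp(-(mat @ self.params_.to_numpy())))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params_ - z * self.bse_
        hi = self.params_ + z * self.bse_
        return pd.DataFrame({"lower": lo, "upper": hi})

    def or_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Exponentiated coefficients with Wald CIs (odds-ratio scale)."""
        ci = self.conf_int(alpha)
        with np.errstate(over="ignore"):  # huge CIs exponentiate to inf
            return pd.DataFrame(
                {
                    "odds_ratio": np.exp(self.params_),
                    "ci_low": np.exp(ci["lower"]),
                    "ci_high": np.exp(ci["upper"]),
                }
            )


# ---------------------------------------------------------------------------
# Model specification for the cohort analysis
# ---------------------------------------------------------------------------

#: Reference level per categorical covariate (first-listed category of the
#: descriptive table).
REFERENCE_LEVELS: dict[str, str] = {
    "sex": "male",
    "marital_status": "single",
    "education": "middle_school_or_less",
    "employment": "white_collar",
    "income": "low",
    "residence": "urban",
    "smoking": "nonsmoker",
    "alcohol": "abstainer",
    "stress": "little_stressful",
    "subjective_health": "poor",
    "depression": "no",
}

#: Socioeconomic adjustment set (Model 1); age enters continuously.
MODEL1_COVARIATES = [
    "age",
    "sex",
    "marital_status",
    "education",
    "employment",
    "income",
]

#: Model 1 plus mental-health covariates (Model 2).
MODEL2_COVARIATES = MODEL1_COVARIATES + [
    "stress",
    "subjective_health",
    "depression",
]


@dataclass
class LogisticModelSpec:
    """Outcome, exposure, and covariate specification for a cohort fit.

    ``outcome`` must be binary or the strings low/high (high = success);
    categorical covariates are dummy-encoded against ``reference_levels``.
    """

    outcome: str = "qol_label"
    exposure: str = "meets_ab"
    covariates: list[str] = field(default_factory=list)
    reference_levels: Mapping[str, str] = field(
        default_factory=lambda: dict(REFERENCE_LEVELS)
    )


@dataclass
class LogisticFit:
    """Result of a cohort logistic fit."""

    params: pd.Series
    cov_params: pd.DataFrame
    or_table: pd.DataFrame
    converged: bool
    iterations: int
    n_obs: int
    exposure_term: str

    def exposure_or(self) -> tuple[float, float, float]:
        row = self.or_table.loc[self.exposure_term]
        return float(row["odds_ratio"]), float(row["ci_low"]), float(row["ci_high"])


def _encode_outcome(series: pd.Series) -> np.ndarray:
    if series.dtype == object:
        mapping = {"low": 0, "high": 1}
        if not set(series.dropna().unique()) <= set(mapping):
            raise ValueError("string outcome must use labels 'low'/'high'")
        return series.map(mapping).to_numpy(dtype=float)
    return series.astype(float).to_numpy()


def build_design(
    data: pd.DataFrame, spec: LogisticModelSpec
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (exposure first, then covariates) and 0/1 outcome."""
    y = _encode_outcome(data[spec.outcome])
    cols: dict[str, np.ndarray] = {}
    cols[spec.exposure] = data[spec.exposure].astype(float).to_numpy()
    for cov in spec.covariates:
        series = data[cov]
        if cov in spec.reference_levels and (
            series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype)
        ):
            ref = spec.reference_levels[cov]
            levels = [lv for lv in pd.unique(series.dropna()) if lv != ref]
            if ref not in set(series.dropna().unique()):
                raise ValueError(
                    f"reference level {ref!r} absent from covariate {cov!r}"
                )
            for lv in sorted(map(str, levels)):
                cols[f"{cov}[{lv}]"] = (series == lv).to_numpy(dtype=float)
        else:
            cols[cov] = series.astype(float).to_numpy()
    X = pd.DataFrame(cols, index=data.index)
    if X.isna().any().any() or np.isnan(y).any():
        missing = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in model columns: {missing or [spec.outcome]}")
    return X, y


def fit_logistic(spec: LogisticModelSpec, data: pd.DataFrame) -> LogisticFit:
    """Fit the cohort model by maximum likelihood (IRLS).

    The exposure coefficient exponentiates to the adjusted odds ratio of
    high QoL for guideline compliance.
    """
    X, y = build_design(data, spec)
    est = LogisticRegressionIRLS().fit(X, y)
    return LogisticFit(
        params=est.params_,
        cov_params=est.cov_params_,
        or_table=est.or_table(),
        converged=est.converged_,
        iterations=est.n_iter_,
        n_obs=est.n_obs_,
        exposure_term=spec.exposure,
    )
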