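"""First-year cost regression: gamma GLM with log link on multiply-imputed data.

The model for patient i's first-year total cost y_i > 0 is

    E[y_i] = exp(x_i' beta),    y_i ~ Gamma,

fitted by maximum likelihood (statsmodels IRLS) on each of M completed data
sets produced by chained-equation imputation of missing biomarkers, then
pooled with Rubin's rules:

    Q̄ = mean_m(β̂_m),  W = mean_m(V̂_m),  B = var_m(β̂_m),  T = W + (1 + 1/M)·B.

Coefficient effects are transformed to natural-scale £ increments by recycled
prediction: the increment for a covariate is the cohort average of the
difference in predicted cost with the covariate switched on versus off (or
shifted by its reporting unit for continuous covariates); confidence limits
are obtained by applying the same transform at the pooled CI bounds of the
coefficient (endpoint transformation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import ConfigurationError, ConvergenceError, SingularDesignError
from .params import design_matrix, glm_covariates

DEFAULT_M = 5  # number of imputed data sets


# ---------------------------------------------------------------------------
# Multiple imputation: chained equations with predictive mean matching


def impute(
    baseline: pd.DataFrame,
    m: int = DEFAULT_M,
    seed: int = 0,
    columns: list[str] | None = None,
    n_iter: int = 5,
    pmm_donors: int = 5,
) -> list[pd.DataFrame]:
    """Multiply impute missing values by chained equations.

    Continuous columns use predictive mean matching (Bayesian-perturbed OLS
    prediction, donor pool of the ``pmm_donors`` nearest observed predictions);
    binary columns use logistic draws. Observed entries are identical across
    the returned ``m`` completed copies; imputations are deterministic given
    ``seed`` and stochastic across copies.
    """
    if m < 2:
        raise ConfigurationError(f"m must be >= 2, got {m}")
    if columns is None:
        columns = [c for c in baseline.columns if baseline[c].isna().any()]
    fully_missing = [c for c in columns if baseline[c].isna().all()]
    if fully_missing:
        raise ConfigurationError(
            f"cannot impute fully missing column(s): {fully_missing}")
    if not columns:
        return [baseline.copy() for _ in range(m)]

    numeric = baseline.select_dtypes(include=[np.number]).columns
    predictors = [c for c in numeric if c not in columns and baseline[c].notna().all()
                  and c != "patient_id" and baseline[c].nunique() > 1]
    if not predictors:
        raise ConfigurationError("imputation requires at least one fully observed covariate")

    rng = np.random.default_rng([seed, 11])
    out = []
    for _ in range(m):
        out.append(_chained_imputation(baseline, columns, predictors, rng, n_iter, pmm_donors))
    return out


def _chained_imputation(data, columns, predictors, rng, n_iter, pmm_donors):
    df = data.copy()
    masks = {c: data[c].isna().to_numpy() for c in columns}
    # initial fill: draw from observed values
    for c in columns:
        obs = data.loc[~masks[c], c].to_numpy()
        df.loc[masks[c], c] = rng.choice(obs, size=masks[c].sum(), replace=True)
    for _ in range(n_iter):
        for c in columns:
            miss = masks[c]
            if not miss.any():
                continue
            others = [o for o in columns if o != c]
            X = df[predictors + others].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(X)), X])
            y = data[c].to_numpy(dtype=float)
            is_binary = set(np.unique(y[~miss])) <= {0.0, 1.0}
            if is_binary:
                df.loc[miss, c] = _logistic_draw(X, y, miss, rng)
            else:
                df.loc[miss, c] = _pmm_draw(X, y, miss, rng, pmm_donors)
    return df


def _pmm_draw(X, y, miss, rng, donors):
    Xo, yo = X[~miss], y[~miss]
    XtX = Xo.T @ Xo
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma2 = resid @ resid / dof
    # Bayesian parameter perturbation (normal approximation)
    cov = sigma2 * np.linalg.pinv(XtX)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    pred_obs = Xo @ beta_star
    pred_mis = X[miss] @ beta_star
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    idx = np.searchsorted(sorted_pred, pred_mis)
    picks = np.empty(len(pred_mis))
    for j, (p, i0) in enumerate(zip(pred_mis, idx)):
        lo = max(0, i0 - donors)
        hi = min(len(sorted_pred), i0 + donors)
        cand = order[lo:hi]
        d = np.abs(pred_obs[cand] - p)
        best = cand[np.argsort(d, kind="stable")[:donors]]
        picks[j] = yo[best[rng.integers(len(best))]]
    return picks


def _logistic_draw(X, y, miss, rng):
    try:
        fit = sm.Logit(y[~miss], X[~miss]).fit(disp=0)
        p = fit.predict(X[miss])
    except Exception:  # separation etc. -> fall back to observed prevalence
        p = np.full(miss.sum(), y[~miss].mean())
    return (rng.random(miss.sum()) < p).astype(float)


# ---------------------------------------------------------------------------
# Gamma GLM and Rubin pooling


def fit_gamma_log(data: pd.DataFrame, response: str = "total_cost",
                  covariates: list[str] | None = None, floor: float = 0.01):
    """Fit a gamma GLM with log link; returns the statsmodels results object.

    ``data`` must contain the response and raw baseline columns; the design is
    built by :func:`scadcost.params.design_matrix`. Zero responses are floored
    at ``floor`` (gamma support excludes 0); pass ``floor=None`` to require
    strictly positive responses instead.
    """
    if covariates is None:
        covariates = list(glm_covariates())
    y = data[response].to_numpy(dtype=float)
    if floor is not None:
        y = np.maximum(y, floor)
    if (y <= 0).any():
        raise ConfigurationError("gamma GLM requires strictly positive responses")
    X = design_matrix(data, covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        aliased = _aliased_columns(X)
        raise SingularDesignError(f"design is rank deficient; aliased columns: {aliased}")
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover
        raise ConvergenceError(f"gamma GLM failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError(f"gamma GLM produced non-finite estimates: {res.params}")
    return res


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    aliased = []
    kept: list[str] = []
    for c in cols:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(c)
        else:
            kept.append(c)
    return aliased


@dataclass
class PooledFit:
    """Rubin-pooled coefficients on the log scale."""

    params: pd.Series                 # Q-bar
    within: pd.Series                 # W
    between: pd.Series                # B
    total_var: pd.Series              # T = W + (1 + 1/M) B
    m: int
    ci_level: float = 0.95
    df: pd.Series | None = None       # Barnard–Rubin small-sample df (inf when B=0)

    @property
    def bse(self) -> pd.Series:
        return np.sqrt(self.total_var)

    def conf_int(self) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(0.5 + self.ci_level / 2)
        se = self.bse
        return pd.DataFrame({"lower": self.params - z * se,
                             "upper": self.params + z * se})


def pool_rubin(fits: list) -> PooledFit:
    """Combine per-imputation fits with Rubin's rules.

    ``fits`` are statsmodels results (or any objects with aligned ``params``
    Series and ``cov_params()``). T = W + (1 + 1/M)·B with B the n−1 sample
    variance of the estimates.
    """
    if len(fits) < 2:
        raise ConfigurationError("pooling requires at least two fits")
    params = [pd.Series(f.params) for f in fits]
    index = params[0].index
    for p in params[1:]:
        if not p.index.equals(index):
            raise ConfigurationError("fits have non-conformable coefficient vectors")
    Q = pd.concat(params, axis=1)
    variances = pd.concat(
        [pd.Series(np.diag(f.cov_params()), index=index) for f in fits], axis=1)
    m = len(fits)
    qbar = Q.mean(axis=1)
    W = variances.mean(axis=1)
    B = Q.var(axis=1, ddof=1)
    T = W + (1 + 1 / m) * B
    return PooledFit(params=qbar, within=W, between=B, total_var=T, m=m)


# ---------------------------------------------------------------------------
# Natural-scale effects


@dataclass
class NaturalScaleEffect:
    covariate: str
    increment: float
    ci_lower: float
    ci_upper: float
    reference: str
    unit: float = 1.0


#: reporting units for continuous covariates: £ increments are per this shift
DEFAULT_UNITS = {"age_c": 10.0}


def to_natural_scale(
    pooled: PooledFit,
    baseline: pd.DataFrame,
    covariates: list[str] | None = None,
    units: dict[str, float] | None = None,
) -> list[NaturalScaleEffect]:
    """Transform pooled log-scale coefficients to £ increments.

    Binary covariates: cohort-average difference in predicted cost with the
    covariate set to 1 vs 0 (recycled predictions). Continuous covariates: the
    same with the covariate shifted by its reporting unit (default 10 years
    for age, one observed SD for biomarkers). CI bounds by endpoint
    transformation of the coefficient's pooled CI.
    """
    if covariates is None:
        covariates = [c for c in pooled.params.index if c != "const"]
    X = design_matrix(baseline, covariates)
    units = {**DEFAULT_UNITS, **(units or {})}
    beta = pooled.params
    ci = pooled.conf_int()
    Xc = sm.add_constant(X, has_constant="add")
    eta = Xc.to_numpy() @ beta.reindex(Xc.columns).to_numpy()

    out = []
    for c in covariates:
        if c not in beta.index:
            raise ConfigurationError(f"covariate {c!r} absent from the pooled fit")
        col = X[c].to_numpy()
        is_binary = set(np.unique(col)) <= {0.0, 1.0}
        unit = 1.0 if is_binary else units.get(c, float(np.std(col, ddof=1)) or 1.0)

        def increment(b):
            if is_binary:
                eta0 = eta - beta[c] * col           # covariate off
                return float(np.mean(np.exp(eta0 + b) - np.exp(eta0)))
            return float(np.mean(np.exp(eta + b * unit) - np.exp(eta)))

        lo, hi = sorted((increment(ci.loc[c, "lower"]), increment(ci.loc[c, "upper"])))
        ref = "absent" if is_binary else f"per +{unit:g}"
        out.append(NaturalScaleEffect(covariate=c, increment=increment(beta[c]),
                                      ci_lower=lo, ci_upper=hi, reference=ref, unit=unit))
    return out


# ---------------------------------------------------------------------------
# Model / Results facade


class GammaCostModel:
    """First-year cost model: gamma GLM with log link on M imputed data sets.

    Parameters
    ----------
    data : baseline table augmented with a ``total_cost`` column (one row per
        patient with a complete first-year window).
    covariates : design covariate names (default :func:`glm_covariates`).
    """

    def __init__(self, data: pd.DataFrame, covariates: list[str] | None = None,
                 response: str = "total_cost", floor: float = 0.01):
        if response not in data.columns:
            raise ConfigurationError(f"data must contain the response column {response!r}")
        self.data = data.reset_index(drop=True)
        self.covariates = list(covariates) if covariates is not None else list(glm_covariates())
        self.response = response
        self.floor = floor

    @classmethod
    def from_tables(cls, baseline, panel, windows, **kwargs):
        from .costing import first_year_totals

        totals = first_year_totals(panel, windows)
        data = baseline.merge(totals[["patient_id", "total_cost"]], on="patient_id")
        return cls(data, **kwargs)

    def fit(self, m: int = DEFAULT_M, seed: int = 0) -> "GammaCostResults":
        raw_cols = {c[:-2] if c.endswith("_c") else c for c in self.covariates}
        impute_cols = [c for c in self.data.columns
                       if c in raw_cols and self.data[c].isna().any()]
        if impute_cols:
            completed = impute(self.data, m=m, seed=seed, columns=impute_cols)
        else:
            completed = [self.data.copy() for _ in range(m)]
        fits = [fit_gamma_log(d, response=self.response,
                              covariates=self.covariates, floor=self.floor)
                for d in completed]
        pooled = pool_rubin(fits)
        return GammaCostResults(self, pooled, fits)


class GammaCostResults:
    """Pooled results of :class:`GammaCostModel`."""

    def __init__(self, model: GammaCostModel, pooled: PooledFit, fits: list):
        self.model = model
        self.pooled = pooled
        self.fits = fits

    @property
    def params(self) -> pd.Series:
        return self.pooled.params

    @property
    def bse(self) -> pd.Series:
        return self.pooled.bse

    def conf_int(self) -> pd.DataFrame:
        return self.pooled.conf_int()

    def natural_effects(self, units: dict[str, float] | None = None) -> pd.DataFrame:
        effs = to_natural_scale(self.pooled, self.model.data,
                                self.model.covariates, units=units)
        return pd.DataFrame([{
            "covariate": e.covariate, "increment": e.increment,
            "ci_lower": e.ci_lower, "ci_upper": e.ci_upper,
            "reference": e.reference, "unit": e.unit,
        } for e in effs])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "ci_lower": ci["lower"],
            "ci_upper": ci["upper"],
            "within_var": self.pooled.within,
            "between_var": self.pooled.between,
        })

    def __repr__(self):
        return (f"<GammaCostResults: n={len(self.model.data)}, "
                f"m={self.pooled.m}, {len(self.params)} coefficients>")
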