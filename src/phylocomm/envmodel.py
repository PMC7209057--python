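"""PD ~ environment regression with screening and backward elimination.

The response (per-sample Faith's PD) is modelled on %TOC, CPE and
sqrt(%Mud) starting from the full factorial

    PD ~ TOC + CPE + Mud_sqrt + TOC:CPE + TOC:Mud_sqrt + CPE:Mud_sqrt
         + TOC:CPE:Mud_sqrt

and the term with the highest non-significant p-value is removed one at
a time (respecting marginality: a term is protected while any retained
higher-order interaction contains it) until every remaining term is
significant at ``alpha``. Screening covers a Levene test of each
covariate across areas, the Pearson correlation matrix, variance
inflation factors, a 3-sd outlier rule on the response, and a Shapiro
test of the final residuals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .io import EnvTable, ValidationError

__all__ = [
    "ScreeningReport",
    "RegressionReport",
    "transform_env",
    "screen_variables",
    "outlier_filter",
    "backward_eliminate",
]

BASE_VARS = ("TOC", "CPE", "Mud_sqrt")


@dataclass(frozen=True)
class ScreeningReport:
    levene_p: dict[str, float]
    pearson: pd.DataFrame
    vif: dict[str, float]
    flagged: tuple[str, ...]  # variables with VIF >= threshold or undefined


@dataclass(frozen=True)
class RegressionReport:
    trace: tuple[tuple[str, float], ...]  # (term removed, p at removal)
    final_terms: tuple[str, ...]
    coefficients: pd.DataFrame  # term, coef, se, t, p
    r_squared: float
    adj_r_squared: float
    full_r_squared: float
    outliers_removed: tuple[tuple[str, float], ...]
    shapiro_residuals_p: float
    start_terms: tuple[str, ...] = ()
    n_used: int = 0

    @property
    def significant(self) -> bool:
        return len(self.final_terms) > 0


def transform_env(env: EnvTable | pd.DataFrame) -> pd.DataFrame:
    """Numeric covariates with %Mud replaced by its square root."""
    df = env.variables.copy() if isinstance(env, EnvTable) else env.copy()
    if "Mud" in df.columns:
        df["Mud_sqrt"] = np.sqrt(df.pop("Mud"))
    return df


def screen_variables(
    env: EnvTable, vif_threshold: float = 10.0
) -> ScreeningReport:
    """Levene (across areas), Pearson matrix and VIF for each covariate."""
    x = transform_env(env)
    area = env.area
    levene_p = {}
    for col in x.columns:
        groups = [g.to_numpy() for _, g in x[col].groupby(area) if len(g) >= 2]
        levene_p[col] = (
            float(stats.levene(*groups).pvalue) if len(groups) >= 2 else np.nan
        )
    pearson = x.corr(method="pearson")
    design = sm.add_constant(x.to_numpy(dtype=float))
    vif, flagged = {}, []
    for i, col in enumerate(x.columns):
        if np.ptp(x[col].to_numpy()) == 0:
            vif[col] = np.inf
            flagged.append(col)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = variance_inflation_factor(design, i + 1)
        vif[col] = float(v)
        if not np.isfinite(v) or v >= vif_threshold:
            flagged.append(col)
    return ScreeningReport(levene_p, pearson, vif, tuple(flagged))


def outlier_filter(
    values: pd.Series, n_sd: float = 3.0, centred: bool = True
) -> tuple[pd.Series, tuple[tuple[str, float], ...]]:
    """Single-pass removal of points more than ``n_sd`` SDs out.

    The deviation of each point is judged against the mean and standard
    deviation of the *other* points (leave-one-out): the naive rule
    |x - mean| > n_sd * sd can never fire on small samples because a
    gross outlier inflates the very sd it is compared against (the
    maximum attainable z is (n-1)/sqrt(n), below 3 for n <= 10).
    centred=False judges |x| itself (not the centred deviation) against
    the leave-one-out sd.
    """
    v = values.astype(float)
    n = len(v)
    if n < 4:
        raise ValidationError("outlier_filter needs at least 4 data points")
    x = v.to_numpy()
    total, total_sq = x.sum(), (x**2).sum()
    loo_mean = (total - x) / (n - 1)
    loo_var = np.maximum(
        (total_sq - x**2 - (n - 1) * loo_mean**2) / (n - 2), 0.0
    )
    loo_sd = np.sqrt(loo_var)
    dev = np.abs(x - loo_mean) if centred else np.abs(x)
    mask = dev > n_sd * loo_sd
    removed = tuple((str(i), float(val)) for i, val in v[mask].items())
    kept = v[~mask]
    if len(kept) == 0:
        raise ValidationError("outlier rule removed every data point")
    return kept, removed


def _interaction_terms(base=BASE_VARS) -> list[str]:
    terms = list(base)
    for k in (2, 3):
        for combo in itertools.combinations(base, k):
            terms.append(":".join(combo))
    return terms


def _design(x: pd.DataFrame, terms) -> pd.DataFrame:
    cols = {}
    for term in terms:
        parts = term.split(":")
        col = x[parts[0]].astype(float).copy()
        for p in parts[1:]:
            col = col * x[p].astype(float)
        cols[term] = col
    d = pd.DataFrame(cols, index=x.index)
    d.insert(0, "Intercept", 1.0)
    return d


def _protected(term: str, terms) -> bool:
    """A term is protected while a retained interaction strictly contains it."""
    parts = set(term.split(":"))
    for other in terms:
        if other == term:
            continue
        if parts < set(other.split(":")):
            return True
    return False


def backward_eliminate(
    response: pd.Series,
    env: EnvTable | pd.DataFrame,
    alpha: float = 0.05,
    outlier_sd: float = 3.0,
    centred_outliers: bool = True,
) -> RegressionReport:
    """Fit the full-interaction model and strip non-significant terms.

    The response is screened with the outlier rule first; the starting
    model is the full factorial over TOC, CPE and sqrt(Mud), trimmed to
    the largest estimable model when n is too small (highest-order
    interactions dropped first, logged in the trace with p = NaN). Each
    step refits by OLS and removes the non-protected term with the
    largest p >= alpha; an empty final model is reported as "no
    significant model" via ``significant == False``.
    """
    x = transform_env(env)
    missing = sorted(set(BASE_VARS) - set(x.columns))
    if missing:
        raise ValidationError(f"environment table lacks variables: {missing}")
    y, removed = outlier_filter(
        response.astype(float), n_sd=outlier_sd, centred=centred_outliers
    )
    x = x.loc[y.index]
    terms = _interaction_terms()
    trace: list[tuple[str, float]] = []
    # ensure estimability: drop highest-order terms until n > p
    while len(y) <= len(terms) + 1 and terms:
        drop = max(terms, key=lambda t: (t.count(":"), t))
        terms.remove(drop)
        trace.append((drop, float("nan")))
    start_terms = tuple(terms)

    def fit(ts):
        return sm.OLS(y.to_numpy(), _design(x, ts).to_numpy()).fit()

    full_r2 = float(fit(terms).rsquared) if terms else 0.0
    while terms:
        res = fit(terms)
        pvals = dict(zip(terms, res.pvalues[1:]))
        candidates = {
            t: p
            for t, p in pvals.items()
            if not _protected(t, terms) and (p >= alpha or np.isnan(p))
        }
        if not candidates:
            break
        worst = max(candidates, key=lambda t: (np.inf if np.isnan(candidates[t]) else candidates[t]))
        trace.append((worst, float(candidates[worst])))
        terms.remove(worst)
    if terms:
        res = fit(terms)
        coefs = pd.DataFrame(
            {
                "term": ["Intercept"] + terms,
                "coef": res.params,
                "se": res.bse,
                "t": res.tvalues,
                "p": res.pvalues,
            }
        )
        r2, adj = float(res.rsquared), float(res.rsquared_adj)
        resid = res.resid
    else:
        mean = y.mean()
        coefs = pd.DataFrame(
            {"term": ["Intercept"], "coef": [mean], "se": [y.sem()],
             "t": [np.nan], "p": [np.nan]}
        )
        r2 = adj = 0.0
        resid = (y - mean).to_numpy()
    shapiro_p = (
        float(stats.shapiro(resid).pvalue) if len(resid) >= 3 and np.ptp(resid) > 0
        else np.nan
    )
    return RegressionReport(
        trace=tuple(trace),
        final_terms=tuple(terms),
        coefficients=coefs,
        r_squared=r2,
        adj_r_squared=adj,
        full_r_squared=full_r2,
        outliers_removed=removed,
        shapiro_residuals_p=shapiro_p,
        start_terms=start_terms,
        n_used=len(y),
    )
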