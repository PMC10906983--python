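"""Constraint models: normalization, linear fits, contrasts, effect sizes.

The response throughout is gene-level mean PhyloP (a -log10-scale
constraint score), normalized with the ordered-quantile (rank-based
inverse normal) transform.  Three models are fitted:

* the *metrics model* — normalized constraint on ASPL, BC and NC, testing
  whether network position predicts constraint;
* the *category model* — one-way ANOVA of constraint on node class
  (H/I/P) with Tukey-adjusted pairwise contrasts and Cohen's d;
* the *focal-set model* — constraint on node class and rate direction
  (accelerated/decelerated) for an adaptation-associated gene set,
  additive by default since such sets are small.

Whole-model effect size is Cohen's f = sqrt(R^2 / (1 - R^2)); pairwise
effect sizes are Cohen's d with Sawilowsky's magnitude ladder
(negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large < 1.2 <=
very large < 2.0 <= huge).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModelResult",
    "ContrastResult",
    "order_quantile_normalize",
    "cohens_f_from_r2",
    "effect_magnitude",
    "fit_metrics_model",
    "fit_category_model",
    "fit_hibernation_model",
]


@dataclass
class ModelResult:
    formula: str
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    r_squared: float
    cohens_f: float
    coefficients: dict[str, tuple[float, float, float]]  # term -> (est, SE, p)
    n: int

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "F": self.f_stat,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "p": self.p_value,
            "r_squared": self.r_squared,
            "cohens_f": self.cohens_f,
            "n": self.n,
            "coefficients": {
                k: {"estimate": e, "se": s, "p": p}
                for k, (e, s, p) in self.coefficients.items()
            },
        }


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    estimate: float          # difference of marginal means, normalized scale
    p_adjusted: float
    cohens_d: float
    magnitude: str

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "estimate": self.estimate,
            "p_adjusted": self.p_adjusted,
            "cohens_d": self.cohens_d,
            "magnitude": self.magnitude,
        }


def order_quantile_normalize(values) -> np.ndarray:
    """Ordered-quantile (rank-based inverse normal) transform.

    Maps value of rank r (average ranks for ties) to the standard normal
    quantile at r / (n + 1).  Monotone in the input; the output of a
    tie-free sample is exactly normal-scores distributed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d vector of at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values cannot be rank-normalized")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks are degenerate")
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf(ranks / (len(x) + 1))


def cohens_f_from_r2(r_squared: float) -> float:
    """Cohen's f for a whole-model effect: sqrt(R^2 / (1 - R^2))."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("R^2 must be in [0, 1]")
    if r_squared == 1.0:  # perfect fit (noise-free input)
        return float("inf")
    return float(np.sqrt(r_squared / (1.0 - r_squared)))


_MAGNITUDE_LADDER = [
    (2.0, "huge"), (1.2, "very large"), (0.8, "large"),
    (0.5, "medium"), (0.2, "small"),
]


def effect_magnitude(d: float) -> str:
    """Sawilowsky's extended label for a Cohen's d value."""
    a = abs(d)
    for cut, name in _MAGNITUDE_LADDER:
        if a >= cut:
            return name
    return "negligible"


def _pooled_cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    if na + nb < 3:
        return 0.0
    ss_a = (na - 1) * np.var(a, ddof=1) if na > 1 else 0.0
    ss_b = (nb - 1) * np.var(b, ddof=1) if nb > 1 else 0.0
    pooled = np.sqrt((ss_a + ss_b) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def _model_result(fit, formula: str) -> ModelResult:
    r2 = float(fit.rsquared)
    coefs = {
        term: (float(fit.params[term]), float(fit.bse[term]),
               float(fit.pvalues[term]))
        for term in fit.params.index
    }
    return ModelResult(
        formula=formula,
        f_stat=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        r_squared=r2,
        cohens_f=cohens_f_from_r2(r2),
        coefficients=coefs,
        n=int(fit.nobs),
    )


def _complete_cases(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = table[cols].dropna()
    dropped = len(table) - len(sub)
    if dropped:
        logger.info("listwise deletion dropped %d incomplete rows", dropped)
    return sub


def fit_metrics_model(table: pd.DataFrame,
                      response: str = "phylop_norm") -> ModelResult:
    """OLS of normalized constraint on the three topology metrics.

    ``table`` must hold ``response``, ``aspl``, ``bc`` and ``nc``
    columns; incomplete rows are dropped (listwise, logged).
    """
    cols = [response, "aspl", "bc", "nc"]
    data = _complete_cases(table, cols)
    if len(data) < 5:
        raise ValueError(f"only {len(data)} complete rows; cannot fit 4 parameters")
    formula = f"{response} ~ aspl + bc + nc"
    fit = smf.ols(formula, data=data).fit()
    return _model_result(fit, formula)


def fit_category_model(
    table: pd.DataFrame,
    response: str = "phylop_norm",
    label_col: str = "label",
) -> tuple[ModelResult, list[ContrastResult]]:
    """One-way ANOVA of constraint on node category with Tukey post hocs.

    Rows labeled ``uncertain`` are excluded before fitting.  Pairwise
    contrasts are Tukey-HSD adjusted differences of category means, each
    with a pooled-SD Cohen's d and a magnitude label.
    """
    data = _complete_cases(table, [response, label_col])
    data = data[data[label_col] != "uncertain"]
    levels = sorted(data[label_col].unique())
    missing = [c for c in ("H", "I", "P") if c not in levels]
    if missing:
        raise ValueError(f"node categories absent from table: {missing}")
    if data.groupby(label_col).size().min() < 2:
        raise ValueError("each category needs >= 2 nodes")
    formula = f"{response} ~ C({label_col})"
    fit = smf.ols(formula, data=data).fit()
    result = _model_result(fit, formula)

    tukey = pairwise_tukeyhsd(data[response].to_numpy(),
                              data[label_col].to_numpy())
    contrasts = []
    for row in tukey.summary().data[1:]:
        g1, g2, diff, _, p_adj = str(row[0]), str(row[1]), float(row[2]), row[3], float(row[4])
        a = data.loc[data[label_col] == g1, response].to_numpy()
        b = data.loc[data[label_col] == g2, response].to_numpy()
        d = _pooled_cohens_d(b, a)  # tukey diff is mean(g2) - mean(g1)
        contrasts.append(ContrastResult(
            pair=(g1, g2), estimate=diff, p_adjusted=p_adj,
            cohens_d=d, magnitude=effect_magnitude(d)))
    return result, contrasts


def fit_hibernation_model(
    table: pd.DataFrame,
    response: str = "phylop_norm",
    label_col: str = "label",
    direction_col: str = "direction",
) -> tuple[ModelResult, list[ContrastResult]]:
    """Additive model of focal-gene constraint on node class and rate direction.

    ``direction`` distinguishes genes whose evolutionary rate
    accelerated vs decelerated with the phenotype.  A factor with a
    single observed level is dropped with a warning rather than
    silently.  Post hoc contrasts cover the direction pair and the
    category pairs (estimated-marginal-mean differences, Holm-adjusted),
    each with a raw-group Cohen's d.
    """
    data = _complete_cases(table, [response, label_col, direction_col])
    data = data[data[label_col] != "uncertain"]
    terms = []
    for col in (label_col, direction_col):
        if data[col].nunique() < 2:
            warnings.warn(f"factor {col!r} has a single level and was dropped",
                          UserWarning, stacklevel=2)
        else:
            terms.append(f"C({col})")
    if not terms:
        raise ValueError("no factor with two or more levels; nothing to fit")
    formula = f"{response} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    result = _model_result(fit, formula)

    contrasts = _emm_contrasts(fit, data, response,
                               [c for c in (direction_col, label_col)
                                if f"C({c})" in terms])
    return result, contrasts


def _emm_contrasts(fit, data: pd.DataFrame, response: str,
                   factors: list[str]) -> list[ContrastResult]:
    """Pairwise EMM contrasts per factor from an additive OLS fit.

    For each factor, every level pair is contrasted by the difference of
    estimated marginal means (marginalized over the other factor's
    observed levels with equal weights).  p-values come from model
    t-tests, Holm-adjusted within factor.
    """
    out: list[ContrastResult] = []
    exog_names = list(fit.model.exog_names)
    for factor in factors:
        levels = sorted(data[factor].unique())
        pairs = list(combinations(levels, 2))
        rows, raw_p = [], []
        for a, b in pairs:
            vec = np.zeros(len(exog_names))
            for lvl, sign in ((b, 1.0), (a, -1.0)):
                name = f"C({factor})[T.{lvl}]"
                if name in exog_names:
                    vec[exog_names.index(name)] = sign
            tt = fit.t_test(vec)
            est = float(np.atleast_1d(tt.effect)[0])
            p = float(np.atleast_1d(tt.pvalue).ravel()[0])
            ga = data.loc[data[factor] == a, response].to_numpy()
            gb = data.loc[data[factor] == b, response].to_numpy()
            d = _pooled_cohens_d(gb, ga)
            rows.append(((a, b), est, d))
            raw_p.append(p)
        adj = multipletests(raw_p, method="holm")[1] if raw_p else []
        for (pair, est, d), p_adj in zip(rows, adj):
            out.append(ContrastResult(
                pair=pair, estimate=est, p_adjusted=float(p_adj),
                cohens_d=d, magnitude=effect_magnitude(d)))
    return out
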