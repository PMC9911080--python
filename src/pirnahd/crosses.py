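"""Hybrid-dysgenesis cross statistics and qPCR expression analysis.

Covers the cross-level inference chain: per-cross dysgenic proportions,
Fisher's exact test between reciprocal crosses, a binomial GLM (logistic
regression by IRLS) testing for a maternal-line effect via a likelihood
ratio against a tester-subline-only model, Pearson correlation between
replicate screens, extreme-line classification, and the qPCR side:
delta-Ct relative quantification against a reference gene, spliced/total
splicing efficiency, Box-Cox transformation by profile likelihood, and a
sequential (type-I) ANOVA of direction + temperature + line.

"Resistance" throughout is 1 - mean dysgenic proportion across replicate
crosses in the dysgenic direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
import statsmodels.api as sm
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# proportions and resistance
# ---------------------------------------------------------------------------


def dysgenic_proportion(n_dysgenic: int, n_normal: int) -> float:
    """Fraction of scored F1 females lacking two well-formed ovaries."""
    total = n_dysgenic + n_normal
    if total < 1:
        raise ValueError("at least one scored female required")
    if n_dysgenic < 0 or n_normal < 0:
        raise ValueError("counts must be nonnegative")
    return n_dysgenic / total


def line_resistance(crosses: pd.DataFrame,
                    log_transform: bool = False) -> pd.Series:
    """Per-line resistance = 1 - mean dysgenic proportion (dysgenic direction).

    The mean is taken across replicate crosses (tester sublines); the
    log-transformed variant returns log(resistance).
    """
    dys = crosses[crosses["direction"] == "dysgenic"].copy()
    if dys.empty:
        raise ValueError("no dysgenic-direction rows")
    dys["prop"] = dys.apply(
        lambda r: dysgenic_proportion(r["n_dysgenic"], r["n_normal"]), axis=1)
    res = 1.0 - dys.groupby("line")["prop"].mean()
    res.name = "resistance"
    return np.log(res) if log_transform else res


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, probability ordering)
# ---------------------------------------------------------------------------


_LOGFACT = np.array([0.0])


def _logfact(n: int) -> float:
    """Cached log n! (log-factorials keep hypergeometric terms stable)."""
    global _LOGFACT
    if n >= len(_LOGFACT):
        _LOGFACT = gammaln(np.arange(max(n + 1, 2 * len(_LOGFACT))) + 1.0)
    return float(_LOGFACT[n])


def _log_hyper(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(table) for the 2x2 table with first cell a and fixed margins."""
    n = r1 + r2
    return (_logfact(r1) + _logfact(r2) + _logfact(c1) + _logfact(n - c1)
            - _logfact(n) - _logfact(a) - _logfact(r1 - a)
            - _logfact(c1 - a) - _logfact(r2 - c1 + a))


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities, over all tables with the
    same margins, of the tables whose probability does not exceed that of
    the observed table (within relative tolerance).  Log-factorials keep
    the computation stable for large counts.  The all-zero table has p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 + r2 == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    log_obs = _log_hyper(a, r1, r2, c1)
    cutoff = log_obs + math.log1p(rel_tol)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hyper(k, r1, r2, c1)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


def reciprocal_fisher(crosses: pd.DataFrame) -> pd.DataFrame:
    """Per-line Fisher p comparing dysgenic vs reciprocal cross outcomes.

    Counts are pooled over tester sublines within each direction.
    """
    rows = []
    for line, sub in crosses.groupby("line"):
        dys = sub[sub["direction"] == "dysgenic"]
        rec = sub[sub["direction"] == "reciprocal"]
        if dys.empty or rec.empty:
            continue
        a, b = int(dys["n_dysgenic"].sum()), int(dys["n_normal"].sum())
        c, d = int(rec["n_dysgenic"].sum()), int(rec["n_normal"].sum())
        rows.append({
            "line": line,
            "dysgenic_prop": dysgenic_proportion(a, b),
            "reciprocal_prop": dysgenic_proportion(c, d),
            "fisher_p": fisher_exact_2x2(a, b, c, d),
        })
    return pd.DataFrame(rows).set_index("line")


# ---------------------------------------------------------------------------
# binomial GLM for the maternal-line effect
# ---------------------------------------------------------------------------


@dataclass
class GlmResult:
    coefficients: pd.Series
    deviance: float
    null_deviance: float  # tester-subline-only model
    lrt_stat: float
    df: int
    p_value: float
    deviance_trace: list[float]
    separation: bool = False
    converged: bool = True


def _irls_binomial(X: np.ndarray, successes: np.ndarray,
                   totals: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 50) -> tuple[np.ndarray, float, list[float],
                                                bool]:
    """Logistic regression on grouped binomial counts by IRLS.

    Returns (beta, deviance, deviance trace, converged).  The deviance uses
    the saturated binomial log-likelihood, so nested-model differences are
    likelihood-ratio statistics.
    """
    n, p = X.shape
    y = successes / totals
    beta = np.zeros(p)
    eps = 1e-10

    def deviance(mu: np.ndarray) -> float:
        mu = np.clip(mu, eps, 1 - eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(successes > 0,
                          successes * np.log(successes / (totals * mu)), 0.0)
            fails = totals - successes
            t2 = np.where(fails > 0,
                          fails * np.log(fails / (totals * (1 - mu))), 0.0)
        return 2.0 * float((t1 + t2).sum())

    trace: list[float] = []
    dev = math.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, eps, 1 - eps)
        w = totals * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        new_dev = deviance(1.0 / (1.0 + np.exp(-(X @ beta))))
        trace.append(new_dev)
        if abs(dev - new_dev) < tol:
            converged = True
            dev = new_dev
            break
        dev = new_dev
    return beta, dev, trace, converged


def line_effect_glm(crosses: pd.DataFrame,
                    separation_threshold: float = 15.0) -> GlmResult:
    """Binomial GLM: dysgenic vs normal ~ line + tester subline.

    Fit by IRLS on the dysgenic-direction rows; the likelihood-ratio test
    compares against the tester-subline-only model (chi-square, df = number
    of lines - 1).  The first line and subline (lexicographic) are the
    reference levels.  Coefficients beyond ``separation_threshold`` in
    absolute value flag quasi-separation; the p-value is still reported.
    """
    dys = crosses[crosses["direction"] == "dysgenic"]
    lines = sorted(dys["line"].unique())
    subs = sorted(dys["tester_subline"].unique())
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    succ = dys["n_dysgenic"].to_numpy(dtype=float)
    totals = (dys["n_dysgenic"] + dys["n_normal"]).to_numpy(dtype=float)
    if (totals < 1).any():
        raise ValueError("every row needs at least one scored female")

    def dummies(values, levels):
        return np.column_stack([
            (values == lv).astype(float) for lv in levels[1:]
        ]) if len(levels) > 1 else np.empty((len(values), 0))

    line_d = dummies(dys["line"].to_numpy(), lines)
    sub_d = dummies(dys["tester_subline"].to_numpy(), subs)
    intercept = np.ones((len(dys), 1))
    X_full = np.hstack([intercept, line_d, sub_d])
    X_null = np.hstack([intercept, sub_d])

    beta_f, dev_f, trace, conv_f = _irls_binomial(X_full, succ, totals)
    _, dev_0, _, conv_0 = _irls_binomial(X_null, succ, totals)
    lrt = max(dev_0 - dev_f, 0.0)
    df = len(lines) - 1
    p = float(sps.chi2.sf(lrt, df))
    names = (["intercept"] + [f"line[{lv}]" for lv in lines[1:]]
             + [f"subline[{lv}]" for lv in subs[1:]])
    coefs = pd.Series(beta_f, index=names)
    return GlmResult(coefs, dev_f, dev_0, lrt, df, p, trace,
                     separation=bool((np.abs(beta_f) > separation_threshold)
                                     .any()),
                     converged=conv_f and conv_0)


# ---------------------------------------------------------------------------
# screen concordance and extreme lines
# ---------------------------------------------------------------------------


def screen_correlation(x, y) -> tuple[float, float]:
    """Pearson r between two per-line proportion screens with t-based p.

    t = r sqrt((n-2)/(1-r^2)), two-sided p from the t distribution with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def replicate_concordance(x, y) -> tuple[float, float]:
    """Paired t-test between matched replicate measurements (t, two-sided p)."""
    t, p = sps.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(t), float(p)


@dataclass
class ExtremeLines:
    resistant: list[str]  # k lines with the lowest dysgenic proportion
    susceptible: list[str]  # k lines with the highest
    tied: bool = False


def classify_extremes(line_means: dict[str, float], k: int) -> ExtremeLines:
    """The k most and least resistant lines by mean dysgenic proportion.

    Ties at either boundary are broken lexicographically and flagged.
    """
    n = len(line_means)
    if k > n // 2:
        raise ValueError("k must be <= half the number of lines")
    asc = sorted(line_means, key=lambda name: (line_means[name], name))
    desc = sorted(line_means, key=lambda name: (-line_means[name], name))
    resistant, susceptible = asc[:k], desc[:k]
    tied = (line_means[asc[k - 1]] == line_means[asc[k]]
            or line_means[desc[k - 1]] == line_means[desc[k]]) if k < n else False
    return ExtremeLines(resistant, susceptible, tied)


# ---------------------------------------------------------------------------
# qPCR: relative quantification and splicing efficiency
# ---------------------------------------------------------------------------


def relative_expression(qpcr: pd.DataFrame,
                        efficiency: float = 2.0) -> pd.DataFrame:
    """Delta-Ct relative expression against the reference gene.

    Per (line, direction, temperature, replicate):
    expr(target) = efficiency ** -(Ct_target - Ct_reference);
    splicing_efficiency = spliced_expr / total_expr.  Expression is
    reported relative to the reference gene only (no second, calibrator
    delta), which suffices for ratios and ANOVA.
    """
    keys = ["line", "direction", "temperature", "replicate"]
    wide = qpcr.pivot_table(index=keys, columns="target", values="ct",
                            aggfunc="mean")
    if "reference" not in wide.columns or wide["reference"].isna().any():
        raise ValueError("missing reference-gene Ct for some condition")
    out = pd.DataFrame(index=wide.index)
    for target in ("spliced", "total"):
        if target in wide.columns:
            out[f"{target}_expr"] = efficiency ** -(wide[target]
                                                    - wide["reference"])
    if {"spliced_expr", "total_expr"} <= set(out.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            out["splicing_efficiency"] = np.where(
                out["total_expr"] > 0,
                out["spliced_expr"] / out["total_expr"], np.nan)
    return out.reset_index()


def boxcox_lambda(x, grid: tuple[float, float, float] = (-2.0, 2.0, 0.01)
                  ) -> tuple[float, np.ndarray]:
    """Box-Cox lambda by profile log-likelihood over a grid, plus transform.

    y = (x^lambda - 1)/lambda for lambda != 0, ln x at lambda = 0; the
    profile log-likelihood is -(n/2) ln(sigma_hat^2(y)) +
    (lambda - 1) sum(ln x).
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("Box-Cox requires strictly positive data")
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    logx = np.log(x)
    lo, hi, step = grid
    lams = np.arange(lo, hi + step / 2, step)
    n = len(x)
    best_lam, best_ll = lams[0], -math.inf
    for lam in lams:
        y = logx if abs(lam) < 1e-12 else (x ** lam - 1.0) / lam
        var = y.var()
        if var <= 0:
            continue
        ll = -0.5 * n * math.log(var) + (lam - 1.0) * logx.sum()
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    y = logx if abs(best_lam) < 1e-12 else (x ** best_lam - 1.0) / best_lam
    return best_lam, y


def splicing_anova(data: pd.DataFrame, response: str,
                   factors: tuple[str, ...] = ("direction", "temperature",
                                               "line")) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of the response on the given factor order.

    Factors enter as categorical terms in the stated order, matching a
    model of the form response ~ direction + temperature + line.
    """
    df = data.copy()
    terms = " + ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"Q('{response}') ~ {terms}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table.index = [i.replace("C(Q('", "").replace("'))", "")
                   for i in table.index]
    return table
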