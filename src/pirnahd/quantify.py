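"""Per-family small-RNA quantification and precision-weighted differential
abundance.

Counts are partitioned by read-length class (piRNA 23-31 nt by default,
siRNA 20-22 nt), normalized to reads per million (RPM), and tested for
association with a per-line resistance covariate using a voom-style model:
log2 counts-per-million are fit per family by least squares, the
mean-variance trend is estimated by locally weighted regression of
sqrt(residual sd) on mean log-cpm, and observation-level precision weights
(predicted sd to the -4 power) feed a weighted linear model.  The t
statistics are ordinary (not empirical-Bayes moderated); p-values are
Benjamini-Hochberg adjusted across families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .readproc import AlignmentRecord

PIRNA_WINDOW = (23, 31)
SIRNA_WINDOW = (20, 22)


@dataclass
class CountMatrix:
    """Per-family x per-library counts with library sizes and metadata."""

    counts: pd.DataFrame  # families x libraries, nonnegative integers
    library_sizes: pd.Series  # per library, > 0
    metadata: pd.DataFrame  # indexed by library: line, replicate, resistance
    length_class: str = "piRNA"
    window: tuple[int, int] = PIRNA_WINDOW

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.library_sizes.index)
        if missing:
            raise ValueError(f"library sizes missing for {sorted(missing)}")
        if (self.library_sizes[self.counts.columns] <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DifferentialResult:
    """Per-family effect of the resistance covariate."""

    table: pd.DataFrame  # family, effect, t, p, p_adj

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.sort_values("p").head(n)


def count_by_family(alignments: Mapping[str, Sequence[AlignmentRecord]],
                    window: tuple[int, int] = PIRNA_WINDOW,
                    library_sizes: Mapping[str, int] | None = None,
                    metadata: pd.DataFrame | None = None,
                    length_class: str = "piRNA",
                    families: Sequence[str] | None = None) -> CountMatrix:
    """Count alignments per (family, library) within a read-length window.

    ``alignments`` maps library id -> alignment records; one increment per
    aligned read whose read_length lies in [lo, hi].  ``library_sizes``
    defaults to the number of alignment records per library (callers doing
    study-level accounting should pass the post-filter read totals).
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("invalid length window")
    fams = set(families or [])
    tallies: dict[str, dict[str, int]] = {}
    for lib, recs in alignments.items():
        t: dict[str, int] = {}
        for rec in recs:
            fams.add(rec.family)
            if lo <= rec.read_length <= hi:
                t[rec.family] = t.get(rec.family, 0) + 1
        tallies[lib] = t
    fam_order = sorted(fams)
    lib_order = list(alignments)
    counts = pd.DataFrame(
        [[tallies[lib].get(f, 0) for lib in lib_order] for f in fam_order],
        index=fam_order, columns=lib_order, dtype=int)
    if library_sizes is None:
        sizes = pd.Series({lib: max(len(alignments[lib]), 1)
                           for lib in lib_order})
    else:
        sizes = pd.Series(dict(library_sizes))
    if metadata is None:
        metadata = pd.DataFrame(index=lib_order)
    else:
        metadata = metadata.copy()
        if "library" in metadata.columns:
            metadata = metadata.set_index("library")
    return CountMatrix(counts, sizes, metadata, length_class, (lo, hi))


def normalize_rpm(matrix: CountMatrix,
                  average_replicates: bool = False) -> pd.DataFrame:
    """Reads per million: count / library_size * 1e6.

    With ``average_replicates`` the per-library RPMs are averaged within
    each line (metadata must carry a ``line`` column).
    """
    sizes = matrix.library_sizes[matrix.counts.columns]
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rpm = matrix.counts / sizes * 1e6
    if average_replicates:
        if "line" not in matrix.metadata.columns:
            raise ValueError("replicate averaging needs 'line' metadata")
        lines = matrix.metadata.loc[rpm.columns, "line"]
        rpm = rpm.T.groupby(lines.values).mean().T
        rpm.columns.name = "line"
    return rpm


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------

_MIN_SQRT_SD = 1e-4  # floor keeps weights finite on degenerate perfect fits


def _design(covariate: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(covariate), covariate])


def voom_fit(matrix: CountMatrix,
             covariate: Sequence[float] | pd.Series,
             span: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-cpm values and observation-level precision weights.

    log-cpm = log2((count + 0.5) / (library_size + 1) * 1e6).  Per family a
    linear model on (intercept, covariate) yields residual sd; the
    sqrt(sd) ~ mean log-cpm trend is smoothed by lowess (fraction ``span``)
    and evaluated at each cell's fitted log-cpm; the weight is that
    predicted sqrt-sd to the -4 power (i.e. predicted variance to the -2).
    """
    libs = matrix.libraries
    if len(libs) < 2:
        raise ValueError("voom needs at least 2 libraries")
    cov = np.asarray(pd.Series(covariate, index=libs)
                     if not isinstance(covariate, pd.Series)
                     else covariate.loc[libs], dtype=float)
    X = _design(cov)
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer libraries than model parameters")
    sizes = matrix.library_sizes[libs].to_numpy(dtype=float)
    counts = matrix.counts[libs].to_numpy(dtype=float)
    logcpm = np.log2((counts + 0.5) / (sizes + 1.0) * 1e6)

    pinv = np.linalg.pinv(X)
    beta = logcpm @ pinv.T  # (G, p)
    fitted = beta @ X.T  # (G, n)
    resid = logcpm - fitted
    sd = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(sd)
    mean_logcpm = logcpm.mean(axis=1)

    uniq = np.unique(mean_logcpm)
    if len(uniq) >= 4:
        trend = lowess(sqrt_sd, mean_logcpm, frac=span, return_sorted=True)
        tx, ty = trend[:, 0], trend[:, 1]
        pred = np.interp(fitted, tx, ty)  # flat extrapolation at both ends
    else:
        pred = np.full_like(fitted, float(np.mean(sqrt_sd)))
    pred = np.maximum(pred, _MIN_SQRT_SD)
    weights = pred ** -4.0
    if not np.all(np.isfinite(weights)) or (weights <= 0).any():
        raise RuntimeError("non-finite or nonpositive voom weights")

    idx = matrix.counts.index
    return (pd.DataFrame(logcpm, index=idx, columns=libs),
            pd.DataFrame(weights, index=idx, columns=libs))


def differential_abundance(logcpm: pd.DataFrame,
                           weights: pd.DataFrame,
                           covariate: Sequence[float] | pd.Series
                           ) -> DifferentialResult:
    """Weighted least squares of log-cpm on (intercept, covariate) per family.

    t = slope / se with n - 2 degrees of freedom, two-sided p, and
    Benjamini-Hochberg adjustment across families.
    """
    libs = list(logcpm.columns)
    cov = np.asarray(pd.Series(covariate, index=libs)
                     if not isinstance(covariate, pd.Series)
                     else covariate.loc[libs], dtype=float)
    if np.allclose(cov, cov[0]):
        raise ValueError("covariate is constant")
    X = _design(cov)
    n = len(libs)
    rows = []
    for fam in logcpm.index:
        y = logcpm.loc[fam].to_numpy(dtype=float)
        w = weights.loc[fam].to_numpy(dtype=float)
        XtW = X.T * w
        xtwx = XtW @ X
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design") from exc
        beta = xtwx_inv @ (XtW @ y)
        resid = y - X @ beta
        df = n - 2
        sigma2 = float((w * resid ** 2).sum() / df)
        se = math.sqrt(max(sigma2 * xtwx_inv[1, 1], 0.0))
        if se == 0.0:
            t = math.inf if beta[1] != 0 else 0.0
            pval = 0.0 if beta[1] != 0 else 1.0
        else:
            t = float(beta[1] / se)
            pval = 2.0 * float(sps.t.sf(abs(t), df))
        rows.append({"family": fam, "effect": float(beta[1]),
                     "t": t, "p": pval})
    table = pd.DataFrame(rows).set_index("family")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return DifferentialResult(table)


def group_contrast(logcpm: pd.DataFrame, weights: pd.DataFrame,
                   groups: Sequence[str] | pd.Series) -> pd.DataFrame:
    """Two-sample weighted Welch t per family for a two-level grouping.

    Provided for extreme-line contrasts (most vs least resistant lines);
    group means and variances use the precision weights, degrees of freedom
    by Satterthwaite.
    """
    g = pd.Series(groups, index=logcpm.columns) \
        if not isinstance(groups, pd.Series) else groups.loc[logcpm.columns]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("group contrast needs exactly two levels")
    a_cols = g[g == levels[0]].index
    b_cols = g[g == levels[1]].index
    rows = []
    for fam in logcpm.index:
        out = {"family": fam}
        stats_ab = []
        for cols in (a_cols, b_cols):
            y = logcpm.loc[fam, cols].to_numpy(float)
            w = weights.loc[fam, cols].to_numpy(float)
            wsum = w.sum()
            m = float((w * y).sum() / wsum)
            neff = wsum ** 2 / (w ** 2).sum()
            var = float((w * (y - m) ** 2).sum() / wsum) * neff / (neff - 1)
            stats_ab.append((m, var, neff))
        (ma, va, na), (mb, vb, nb) = stats_ab
        se2 = va / na + vb / nb
        t = (mb - ma) / math.sqrt(se2) if se2 > 0 else 0.0
        df = (se2 ** 2 / ((va / na) ** 2 / (na - 1)
                          + (vb / nb) ** 2 / (nb - 1))) if se2 > 0 else 1.0
        out.update(effect=mb - ma, t=t,
                   p=2.0 * float(sps.t.sf(abs(t), df)), df=df)
        rows.append(out)
    table = pd.DataFrame(rows).set_index("family")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table
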