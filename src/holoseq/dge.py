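"""Differential expression for RNA-seq counts.

Implements the standard count-based DE stack for the host transcriptome:
minimum-count filtering, TMM (trimmed mean of M-values) normalization,
logCPM, leading-logFC multidimensional scaling, mean-variance precision
weights (voom), per-gene weighted linear models with empirical-Bayes
variance moderation, and Benjamini-Hochberg FDR calling.

The moderation shrinks each gene's residual variance s_g^2 (d residual
df) toward a prior s0^2 with d0 prior df estimated by matching the first
two moments of log s^2 through digamma/trigamma identities; the
moderated statistic

    t_g = beta_c / (se_c * s_tilde_g / s_g),
    s_tilde_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

is referred to a t distribution with d0 + d degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


def filter_min_count(counts: pd.DataFrame, min_count: int = 1,
                     min_samples: int = 3) -> list:
    """Genes with count >= min_count in at least min_samples samples."""
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return list(counts.index[keep])


def _quantile_colwise(x: np.ndarray, p: float) -> np.ndarray:
    return np.quantile(x, p, axis=0)


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> pd.Series:
    """TMM normalization factors correcting library composition bias.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean of those.  For every other sample, gene-wise
    log2 count-fraction ratios (M) and average log2 abundances (A) are
    computed over genes positive in both libraries, doubly trimmed
    (30% on M, 5% on A by default), and combined by a precision-weighted
    mean with inverse approximate-binomial-variance weights.  Factors
    are scaled so their geometric mean is 1.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    f75 = _quantile_colwise(x / lib, 0.75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    for s in range(x.shape[1]):
        if s == ref:
            continue
        obs, nobs = x[:, s], lib[s]
        refc, nref = x[:, ref], lib[ref]
        pos = (obs > 0) & (refc > 0)
        if not pos.any():
            raise ValueError(f"sample {counts.columns[s]!r} shares no "
                             "positive genes with the reference")
        o, r = obs[pos], refc[pos]
        M = np.log2((o / nobs) / (r / nref))
        A = 0.5 * np.log2((o / nobs) * (r / nref))
        v = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        if np.max(np.abs(M)) < 1e-6:
            continue
        n = M.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(M)
        ra = stats.rankdata(A)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
            if np.isfinite(f):
                factors[s] = 2.0 ** f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(counts: pd.DataFrame, factors: pd.Series | None = None,
           prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    log2((count + prior) / (lib * factor + 2 * prior) * 1e6).
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    f = np.ones_like(lib) if factors is None else factors.loc[counts.columns].to_numpy()
    if np.any(f <= 0):
        raise ValueError("normalization factors must be positive")
    eff = lib * f + 2 * prior_count
    return pd.DataFrame(np.log2((x + prior_count) / eff * 1e6),
                        index=counts.index, columns=counts.columns)


@dataclass
class MdsCoordinates:
    coordinates: pd.DataFrame  # samples x 2
    distances: pd.DataFrame  # pairwise leading-logFC distances


def mds_coordinates(log_expr: pd.DataFrame, top: int = 500) -> MdsCoordinates:
    """Classical metric MDS of leading log-fold-change distances.

    The distance between two samples is the root mean square of the
    ``top`` largest squared logCPM differences for that pair (genes
    selected pairwise).  Coordinates are the first two principal
    coordinates of the double-centered squared distance matrix.
    """
    y = log_expr.to_numpy(dtype=float)
    g, n = y.shape
    if n < 3:
        raise ValueError("MDS needs at least three samples")
    t = min(top, g)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sq = (y[:, i] - y[:, j]) ** 2
            sel = np.partition(sq, g - t)[g - t:]
            d[i, j] = d[j, i] = np.sqrt(sel.mean())
    j_mat = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j_mat @ (d ** 2) @ j_mat
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    return MdsCoordinates(
        pd.DataFrame(coords, index=log_expr.columns, columns=["dim1", "dim2"]),
        pd.DataFrame(d, index=log_expr.columns, columns=log_expr.columns))


def _ols_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray | None = None):
    """Row-wise (weighted) least squares of y (genes x samples) on X."""
    G, S = y.shape
    p = X.shape[1]
    beta = np.empty((G, p))
    sigma2 = np.empty(G)
    fitted = np.empty_like(y)
    cov_unscaled = np.empty((G, p, p))
    if w is None:
        xtx_inv = np.linalg.inv(X.T @ X)
        proj = xtx_inv @ X.T
        beta = y @ proj.T
        fitted = beta @ X.T
        resid = y - fitted
        sigma2 = (resid ** 2).sum(axis=1) / (S - p)
        cov_unscaled[:] = xtx_inv
    else:
        for g in range(G):
            wg = w[g]
            xw = X * wg[:, None]
            xtx_inv = np.linalg.inv(X.T @ xw)
            b = xtx_inv @ (xw.T @ y[g])
            beta[g] = b
            fitted[g] = X @ b
            sigma2[g] = (wg * (y[g] - fitted[g]) ** 2).sum() / (S - p)
            cov_unscaled[g] = xtx_inv
    return beta, sigma2, fitted, cov_unscaled


def voom_weights(counts: pd.DataFrame, design: np.ndarray,
                 factors: pd.Series | None = None, span: float = 0.5):
    """Mean-variance precision weights for log-counts.

    Per-gene square-root residual standard deviations from an unweighted
    fit of logCPM on the design are lowess-smoothed (span 0.5) against
    average log2 count; the trend is evaluated at each observation's
    fitted log2 count (clipped to the trend's observed range) and the
    weight is trend^-4.  Returns (logcpm DataFrame, weights array).
    """
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    y = logcpm(counts, factors).to_numpy()
    lib = counts.to_numpy(dtype=float).sum(axis=0)
    f = np.ones_like(lib) if factors is None else factors.loc[counts.columns].to_numpy()
    eff = lib * f + 1.0
    _, sigma2, fitted, _ = _ols_fit(y, X)
    sx = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    sy = np.sqrt(np.sqrt(sigma2))
    smooth = lowess(sy, sx, frac=span, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    fitted_logcount = fitted + (np.log2(eff) - np.log2(1e6))[None, :]
    trend = np.interp(fitted_logcount, xs, ys)  # clipped at ends (rule=2)
    w = np.maximum(trend, 1e-8) ** -4
    return pd.DataFrame(y, index=counts.index, columns=counts.columns), w


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def squeeze_var(sigma2: np.ndarray, df: float):
    """Estimate prior df d0 and variance s0^2 by moment matching log s^2.

    Returns (d0, s0sq); d0 = inf when the excess variance of log s^2 is
    non-positive (variances effectively identical).
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return 0.0, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(emean)
    return float(d0), float(s0sq)


@dataclass
class DgeFit:
    coefficients: pd.Series  # contrast estimate, log2 scale
    stdev_unscaled: pd.Series
    sigma2: pd.Series
    df_residual: float
    d0: float
    s0sq: float
    t: pd.Series
    p: pd.Series
    fdr: pd.Series


def fit_and_moderate(log_expr: pd.DataFrame, weights, design,
                     contrast, d0: float | None = None) -> DgeFit:
    """Per-gene weighted least squares with empirical-Bayes moderation.

    ``contrast`` is a vector of design-column coefficients.  ``d0`` may
    be forced (numpy.inf gives the fully shrunk limit, 0 the ordinary
    t-test); by default it is estimated from the data.
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    y = log_expr.to_numpy(dtype=float)
    S, p_dim = X.shape
    d = S - p_dim
    if d <= 0:
        raise ValueError("no residual degrees of freedom")
    w = None if weights is None else np.asarray(weights, dtype=float)
    beta, sigma2, _, cov = _ols_fit(y, X, w)
    bc = beta @ c
    vc = np.einsum("i,gij,j->g", c, cov, c)
    se_unscaled = np.sqrt(vc)
    if d0 is None:
        d0, s0sq = squeeze_var(sigma2, d)
    else:
        _, s0sq = squeeze_var(sigma2, d)
    if np.isinf(d0):
        s2_tilde = np.full_like(sigma2, s0sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0sq + d * sigma2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = bc / (se_unscaled * np.sqrt(s2_tilde))
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df_total)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    idx = log_expr.index
    return DgeFit(
        coefficients=pd.Series(bc, idx), stdev_unscaled=pd.Series(se_unscaled, idx),
        sigma2=pd.Series(sigma2, idx), df_residual=float(d), d0=float(d0),
        s0sq=float(s0sq), t=pd.Series(t, idx), p=pd.Series(pvals, idx),
        fdr=pd.Series(fdr, idx))


def call_degs(fit: DgeFit, alpha: float = 0.05):
    """Significant genes at FDR < alpha, split by contrast sign."""
    sig = fit.fdr < alpha
    up = set(fit.fdr.index[sig & (fit.coefficients > 0)])
    down = set(fit.fdr.index[sig & (fit.coefficients < 0)])
    return up, down


def set_overlap(named_sets: dict) -> dict:
    """Venn-region counts for any number of named gene sets.

    Returns {tuple(names in region): count} for every region with the
    element present in exactly those sets (regions of the full Venn
    diagram, including empty ones for represented combinations).
    """
    from itertools import combinations

    names = sorted(named_sets)
    regions: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set().union(*(named_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions[combo] = len(inside - outside)
    return regions


def flag_expression_outliers(log_expr: pd.DataFrame, z: float = 2.0) -> list:
    """Flag (never drop) samples unusually far from the rest.

    Average Euclidean distance on logCPM columns; samples whose mean
    distance to the others exceeds the across-sample mean by ``z``
    standard deviations are flagged.
    """
    y = log_expr.to_numpy(dtype=float)
    n = y.shape[1]
    d = np.sqrt(((y[:, :, None] - y[:, None, :]) ** 2).sum(axis=0))
    mean_d = (d.sum(axis=0)) / (n - 1)
    zscores = (mean_d - mean_d.mean()) / mean_d.std(ddof=1)
    return [s for s, v in zip(log_expr.columns, zscores) if v > z]
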