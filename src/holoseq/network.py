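"""Weighted gene coexpression network analysis (WGCNA-style).

Builds an unsigned correlation network on log2(FPKM + 1) expression:
soft-threshold selection by the scale-free topology fit index,
adjacency a_ij = |cor(x_i, x_j)|^beta, topological overlap similarity,
module detection by average-linkage clustering of the TOM
dissimilarity with eigengene-based merging, module eigengenes (first
principal component of standardized module expression), module-trait
regression with BH correction, and connectivity statistics (kTotal,
kWithin, module membership).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def filter_fpkm(fpkm: pd.DataFrame, min_value: float = 1.0,
                min_samples: int = 3) -> list:
    """Genes with FPKM >= min_value in at least min_samples samples."""
    keep = (fpkm >= min_value).sum(axis=1) >= min_samples
    return list(fpkm.index[keep])


def log_fpkm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1), the network's input scale."""
    return np.log2(fpkm + 1.0)


def _abs_cor(expr: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between genes (rows of expr)."""
    sd = expr.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene rows; filter them first")
    c = np.corrcoef(expr)
    np.fill_diagonal(c, 1.0)
    return np.abs(np.clip(c, -1.0, 1.0))


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |cor|^beta on log-scale expression (genes x samples)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = _abs_cor(expr.to_numpy(dtype=float)) ** beta
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree distribution over 10 bins.

    Connectivities are cut into ``n_bins`` equal-width bins; the fit
    index is the R^2 of log10(freq) on log10(mean k) over non-empty
    bins, signed by the negative of the slope (scale-free networks have
    decreasing log-log fits).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    total = k.size
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / total))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(r):
        return 0.0
    return float(r ** 2 * -np.sign(slope))


def pick_soft_threshold(expr: pd.DataFrame, candidates=range(1, 21),
                        target: float = 0.8, n_bins: int = 10):
    """Smallest beta whose scale-free fit index reaches ``target``.

    Returns (beta, fit_table) where fit_table has columns beta,
    fit_index, mean_k.  If no candidate reaches the target the beta with
    the maximum fit is returned with a warning.
    """
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("excluding zero-variance genes from soft-threshold scan")
        x = x[sd > 0]
    base = _abs_cor(x)
    rows = []
    for beta in candidates:
        a = base ** beta
        k = a.sum(axis=1) - 1.0
        rows.append((beta, scale_free_fit(k, n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["beta", "fit_index", "mean_k"])
    reaching = table[table["fit_index"] >= target]
    if len(reaching):
        beta = int(reaching["beta"].iloc[0])
    else:
        beta = int(table.loc[table["fit_index"].idxmax(), "beta"])
        warnings.warn(f"no candidate reached fit {target}; using beta={beta}")
    return beta, table


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k the connectivity (row sum minus self) and TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def module_eigengene(expr: pd.DataFrame, module_genes) -> tuple[np.ndarray, float]:
    """First-principal-component summary of a module's expression.

    Genes are standardized across samples; the per-sample scores of the
    first right singular vector are returned with the share of variance
    explained.  The sign is fixed so the eigengene correlates positively
    with mean module expression.  Zero-variance genes are dropped with a
    warning.
    """
    sub = expr.loc[list(module_genes)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("module needs at least two genes")
    sd = sub.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("dropping zero-variance genes from module eigengene")
        sub = sub[sd > 0]
        sd = sd[sd > 0]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return scores, var_explained


def detect_modules(tom: pd.DataFrame, min_module_size: int = 30,
                   merge_cor: float = 0.85, cut_fraction: float = 0.998,
                   expr: pd.DataFrame | None = None,
                   membership_min: float = 0.6) -> pd.Series:
    """Module assignments from average-linkage clustering of 1 - TOM.

    Without expression data a static tree cut at ``cut_fraction`` of the
    maximum merge height is used; clusters smaller than
    ``min_module_size`` go to module 0 (unassigned).

    With ``expr``, a simplified dynamic cut walks the dendrogram from
    the root: a cluster is split whenever its two subclusters'
    eigengenes correlate below ``merge_cor`` (they carry distinct
    signals), and kept as one module once they agree.  Unassigned genes
    whose module membership reaches ``membership_min`` are then adopted
    by their best-matching module, and modules with eigengene
    correlation above ``merge_cor`` are merged back.  Module ids are
    renumbered 1.. by decreasing size.
    """
    genes = list(tom.index)
    if len(genes) < min_module_size:
        return pd.Series(0, index=genes, name="module")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    if expr is None:
        height = cut_fraction * link[:, 2].max()
        raw = hierarchy.fcluster(link, t=height, criterion="distance")
        labels = pd.Series(raw, index=genes)
        sizes = labels.value_counts()
        small = sizes[sizes < min_module_size].index
        labels[labels.isin(small)] = 0
    else:
        labels = _split_by_eigengene(link, genes, expr, min_module_size,
                                     merge_cor)
        labels = _adopt_by_membership(labels, expr, membership_min)
        labels = _merge_correlated(labels, expr, merge_cor)
    # renumber by decreasing size, 0 stays unassigned
    sizes = labels[labels != 0].value_counts()
    remap = {old: new for new, old in enumerate(sizes.index, start=1)}
    remap[0] = 0
    return labels.map(remap).rename("module")


def _node_scores(expr_z: np.ndarray, ids) -> np.ndarray:
    """Eigengene-like summary of a set of standardized gene profiles."""
    sub = expr_z[ids]
    if sub.shape[0] == 1:
        return sub[0]
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    scores = vt[0]
    if np.dot(scores, sub.mean(axis=0)) < 0:
        scores = -scores
    return scores


def _split_by_eigengene(link, genes, expr: pd.DataFrame, min_size: int,
                        merge_cor: float) -> pd.Series:
    """Top-down dendrogram walk: split while subcluster signals disagree."""
    x = expr.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    root = hierarchy.to_tree(link)
    labels = pd.Series(0, index=genes, name="module")
    next_id = 1
    stack = [root]
    while stack:
        node = stack.pop()
        if node.count < min_size:
            continue
        if node.is_leaf():
            continue
        left_ids = node.left.pre_order(lambda n: n.id)
        right_ids = node.right.pre_order(lambda n: n.id)
        r = np.corrcoef(_node_scores(z, left_ids),
                        _node_scores(z, right_ids))[0, 1]
        if abs(r) >= merge_cor:
            labels.iloc[left_ids + right_ids] = next_id
            next_id += 1
        else:
            stack.append(node.left)
            stack.append(node.right)
    return labels


def _adopt_by_membership(labels: pd.Series, expr: pd.DataFrame,
                         membership_min: float) -> pd.Series:
    """Assign grey (module-0) genes to the module they best correlate with."""
    mods = [m for m in labels.unique() if m != 0]
    grey = labels.index[labels == 0]
    if not mods or not len(grey):
        return labels
    labels = labels.copy()
    eig = np.column_stack([module_eigengene(expr, labels.index[labels == m])[0]
                           for m in mods])
    x = expr.loc[grey].to_numpy(dtype=float)
    xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
    ez = (eig - eig.mean(0, keepdims=True)) / eig.std(0, keepdims=True)
    kme = xz @ ez / x.shape[1]
    best = np.abs(kme).argmax(axis=1)
    ok = np.abs(kme)[np.arange(len(grey)), best] >= membership_min
    labels.loc[grey[ok]] = np.asarray(mods)[best[ok]]
    return labels


def _merge_correlated(labels: pd.Series, expr: pd.DataFrame,
                      merge_cor: float) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != 0]
        if len(mods) < 2:
            return labels
        eig = {m: module_eigengene(expr, labels.index[labels == m])[0]
               for m in mods}
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = np.corrcoef(eig[a], eig[b])[0, 1]
                if r > merge_cor and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


@dataclass
class ModuleSet:
    assignments: pd.Series
    eigengenes: pd.DataFrame  # samples x modules
    variance_explained: dict
    k_total: pd.Series = None  # type: ignore[assignment]
    k_within: pd.Series = None  # type: ignore[assignment]
    module_membership: pd.DataFrame = None  # type: ignore[assignment]
    sizes: dict = field(default_factory=dict)


def build_module_set(expr: pd.DataFrame, adj: pd.DataFrame,
                     assignments: pd.Series) -> ModuleSet:
    """Eigengenes, connectivity and membership for detected modules."""
    mods = sorted(m for m in assignments.unique() if m != 0)
    eig = {}
    varexp = {}
    for m in mods:
        scores, ve = module_eigengene(expr, assignments.index[assignments == m])
        eig[f"M{m}"] = scores
        varexp[f"M{m}"] = ve
    eigengenes = pd.DataFrame(eig, index=expr.columns)
    k_total, k_within, mm = connectivity(adj, assignments, expr, eigengenes)
    sizes = assignments[assignments != 0].value_counts().to_dict()
    return ModuleSet(assignments, eigengenes, varexp, k_total, k_within, mm,
                     {f"M{m}": int(n) for m, n in sizes.items()})


def connectivity(adj: pd.DataFrame, assignments: pd.Series,
                 expr: pd.DataFrame | None = None,
                 eigengenes: pd.DataFrame | None = None):
    """kTotal, kWithin and (optionally) module membership per gene.

    kTotal_i is the sum of adjacencies to all other genes; kWithin_i
    restricts the sum to gene i's module (0 for unassigned genes).
    Module membership is the correlation of each gene's profile with
    each module eigengene.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    genes = list(adj.index)
    lab = assignments.loc[genes].to_numpy()
    k_total = pd.Series(a.sum(axis=1), index=genes, name="kTotal")
    same = lab[:, None] == lab[None, :]
    k_within = pd.Series((a * same).sum(axis=1), index=genes, name="kWithin")
    k_within[lab == 0] = 0.0
    mm = None
    if expr is not None and eigengenes is not None and len(eigengenes.columns):
        x = expr.loc[genes].to_numpy(dtype=float)
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        e = eigengenes.to_numpy(dtype=float)
        ez = (e - e.mean(0, keepdims=True)) / e.std(0, keepdims=True)
        mm = pd.DataFrame(xz @ ez / x.shape[1], index=genes,
                          columns=eigengenes.columns)
    return k_total, k_within, mm


def module_trait_association(eigengenes: pd.DataFrame,
                             trait: pd.Series) -> pd.DataFrame:
    """OLS of each module eigengene on a (binary-coded or numeric) trait.

    Returns a table with module, r_squared, p (two-sided, from the
    regression F/t statistic) and BH-adjusted FDR across modules.
    """
    t = pd.Series(trait).loc[eigengenes.index].astype(float).to_numpy()
    if np.std(t) == 0:
        raise ValueError("constant trait")
    rows = []
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(dtype=float)
        slope, _, r, p, _ = stats.linregress(t, e)
        rows.append((m, float(r ** 2), float(p)))
    out = pd.DataFrame(rows, columns=["module", "r_squared", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
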