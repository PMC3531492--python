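"""Weighted co-expression network construction.

Implements the unsigned variant: Pearson correlation, soft-threshold power
chosen by the scale-free topology criterion, adjacency a_ij = |r_ij|^beta,
topological overlap

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu,

average-linkage clustering of the dissimilarity d = 1 - omega, a two-stage
branch cut (static height cut plus recursive gap splitting — a simplified
stand-in for dynamic branch cutting whose adequacy is defined by the
module-recovery tests), module eigengenes as first principal components, kME
tables, and eigengene-based module merging. Module labels are renumbered by
descending size; 0 means unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)


def correlation_matrix(expr, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix across strains.

    Zero-variance genes get correlation 0 against everything (diagonal kept
    at 1) with a warning; missing values are handled pairwise-complete, and
    genes missing in more than ``max_missing_frac`` of strains are dropped.
    """
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "annotation") else expr
    values = pd.DataFrame(values)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 strains for correlations")

    miss = values.isna().mean(axis=1)
    if (miss > max_missing_frac).any():
        dropped = values.index[miss > max_missing_frac]
        logger.warning("dropping %d genes with >%.0f%% missing values",
                       len(dropped), 100 * max_missing_frac)
        values = values.drop(index=dropped)

    if values.isna().any().any():
        cor = values.T.corr()  # pairwise-complete
        cor = cor.fillna(0.0)
        np.fill_diagonal(cor.values, 1.0)
    else:
        X = values.to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning("%d zero-variance genes; correlations recorded as 0", zero.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
        C[np.isnan(C)] = 0.0
        np.fill_diagonal(C, 1.0)
        C = np.clip(C, -1.0, 1.0)
        cor = pd.DataFrame(C, index=values.index, columns=values.index)
    return cor


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate power and the chosen beta."""

    beta: float
    satisfied: bool
    fits: pd.DataFrame  # power, r2, slope, mean_k


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple:
    """R^2 and slope of log10(freq) on log10(mean k) over connectivity bins."""
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


def pick_soft_threshold(
    cor: pd.DataFrame,
    candidate_powers=DEFAULT_POWERS,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Smallest power meeting the scale-free topology criterion.

    For each candidate power the whole-network connectivity distribution is
    binned and log10(freq) regressed on log10(k); the smallest power whose
    fit reaches R^2 >= ``r2_target`` with negative slope wins. If none
    qualifies the power maximizing R^2 is returned with ``satisfied=False``.
    """
    if any(p <= 0 for p in candidate_powers):
        raise ValueError("candidate powers must be positive")
    A0 = np.abs(np.asarray(cor, dtype=float))
    if not (A0 > 0).any():
        raise ValueError("all-zero correlation matrix")
    if A0.shape[0] < 50:
        logger.warning("fewer than 50 genes: scale-free fit is unreliable")
    np.fill_diagonal(A0, 0.0)
    rows = []
    for p in candidate_powers:
        k = (A0 ** p).sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": p, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    fits = pd.DataFrame(rows)
    ok = fits[(fits.r2 >= r2_target) & (fits.slope < 0)]
    if len(ok):
        beta = float(ok.power.iloc[0])
        return SoftThresholdReport(beta=beta, satisfied=True, fits=fits)
    best = fits.loc[fits.r2.idxmax()]
    logger.warning("no power reached scale-free R^2 >= %.2f; using beta=%g (max R^2=%.2f)",
                   r2_target, best.power, best.r2)
    return SoftThresholdReport(beta=float(best.power), satisfied=False, fits=fits)


def adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned adjacency |r|^beta, symmetric, diagonal 1."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = np.abs(np.asarray(cor, dtype=float)) ** beta
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return pd.DataFrame(A)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from an adjacency matrix.

    Diagonal is 1 by convention and excluded from k and l sums.
    """
    A = np.asarray(adj, dtype=float).copy()
    if ((A < -1e-12) | (A > 1 + 1e-12)).any():
        raise ValueError("adjacency values must lie in [0, 1]")
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # L[i,j] = sum_u a_iu a_uj, includes u=i,j terms via zeroed diag -> none
    # with zeroed diagonal, (A@A)[i,j] = sum_{u != i? } ... a_iu a_uj; terms u=i and u=j
    # vanish because a_ii = a_jj = 0, so L already excludes u in {i, j}.
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (L + A) / denom
    omega[denom == 0] = 0.0
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    omega = (omega + omega.T) / 2.0
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(omega, index=adj.index, columns=adj.columns)
    return pd.DataFrame(omega)


@dataclass
class ModulePartition:
    """Module labels (0 = unassigned), eigengenes and kME for a network."""

    labels: pd.Series
    eigengenes: pd.DataFrame = None  # modules x strains
    var_explained: pd.Series = None
    kme: pd.DataFrame = None  # genes x modules
    linkage: np.ndarray = field(default=None, repr=False)

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        counts.index.name = "module"
        return counts


def _first_pc(X: np.ndarray) -> tuple:
    """First-PC scores over columns of a rows-standardized matrix.

    Returns (scores, var_explained). Scores have unit variance (ddof=1) and
    are sign-oriented so the mean row correlation is >= 0; exact antipodal
    ties fall back to orienting against the first row.
    """
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if Z.shape[0] == 1:
        v = Z[0]
        return v / v.std(ddof=1) if v.std(ddof=1) > 0 else v, 1.0
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0
    sdv = scores.std(ddof=1)
    if sdv > 0:
        scores = (scores - scores.mean()) / sdv
    # rows of Z and the scores are standardized, so this is the correlation
    member_cor = (Z @ scores) / (Z.shape[1] - 1)
    mean_cor = member_cor.mean()
    if mean_cor < 0 or (mean_cor == 0 and member_cor[0] < 0):
        scores = -scores
    return scores, var_explained


def module_eigengenes(expr, labels: pd.Series) -> tuple:
    """Eigengene (first PC over strains) and variance explained per module.

    Genes are standardized before the decomposition; eigengenes have unit
    variance and are oriented so the mean member correlation is >= 0.
    """
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    labels = labels.reindex(values.index).fillna(0).astype(int)
    mods = sorted(set(labels[labels > 0]))
    eig_rows, ve = {}, {}
    for mod in mods:
        X = values.loc[labels[labels == mod].index].to_numpy(dtype=float)
        scores, var_explained = _first_pc(X)
        eig_rows[mod] = scores
        ve[mod] = var_explained
    eigengenes = pd.DataFrame(eig_rows, index=values.columns).T
    eigengenes.index.name = "module"
    return eigengenes, pd.Series(ve, name="var_explained")


def intramodular_connectivity(expr, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: signed Pearson correlation of every gene with every eigengene."""
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    if list(values.columns) != list(eigengenes.columns):
        eigengenes = eigengenes[values.columns]
    X = values.to_numpy(dtype=float)
    E = eigengenes.to_numpy(dtype=float)
    Xz = X - X.mean(axis=1, keepdims=True)
    Ez = E - E.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xz, axis=1)
    en = np.linalg.norm(Ez, axis=1)
    xn[xn == 0] = np.inf
    en[en == 0] = np.inf
    K = (Xz @ Ez.T) / np.outer(xn, en)
    kme = pd.DataFrame(K, index=values.index, columns=eigengenes.index)
    kme.columns.name = "module"
    return kme


def _gap_split(node, cut_height: float, gap: float, min_size: int):
    """Recursively split a dendrogram branch at large internal height gaps."""
    if node.is_leaf():
        return [[node.id]]
    hl = 0.0 if node.left.is_leaf() else node.left.dist
    hr = 0.0 if node.right.is_leaf() else node.right.dist
    if node.dist - max(hl, hr) > gap and min(node.left.count, node.right.count) >= min_size:
        return (_gap_split(node.left, cut_height, gap, min_size)
                + _gap_split(node.right, cut_height, gap, min_size))
    return [node.pre_order(lambda leaf: leaf.id)]


def detect_modules(
    expr,
    tom: pd.DataFrame,
    min_module_size: int = 20,
    merge_cut: float = 0.25,
    cut_height_frac: float = 0.99,
    split_gap: float = 0.1,
    kme_threshold: float = 0.3,
) -> ModulePartition:
    """Cluster the TOM dissimilarity into modules and summarize them.

    Average-linkage hierarchical clustering of d = 1 - omega; a static cut at
    ``cut_height_frac`` of the maximum merge height defines initial branches,
    branches containing an internal merge-height gap larger than ``split_gap``
    are recursively split, clusters smaller than ``min_module_size`` are
    dissolved to label 0, genes whose within-module kME falls below
    ``kme_threshold`` are returned to label 0 (weakly attached leaves picked
    up by the branch cut), and modules whose eigengene dissimilarity
    (1 - correlation) is below ``merge_cut`` are merged (eigengenes
    recomputed). Labels are renumbered by descending module size.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    genes = list(tom.index)
    n = len(genes)
    if n < min_module_size:
        logger.warning("fewer genes (%d) than min_module_size; all unassigned", n)
        labels = pd.Series(0, index=genes)
        return ModulePartition(labels=labels,
                               eigengenes=pd.DataFrame(columns=values.columns),
                               var_explained=pd.Series(dtype=float),
                               kme=pd.DataFrame(index=genes))

    D = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    cut_height = cut_height_frac * Z[:, 2].max()

    # static-cut branches, each recursively gap-split
    tree = sch.to_tree(Z)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    for node in _collect_cut_nodes(tree, cut_height):
        for leaf_ids in _gap_split(node, cut_height, split_gap, min_module_size):
            if len(leaf_ids) >= min_module_size:
                labels[leaf_ids] = next_label
                next_label += 1

    label_s = pd.Series(labels, index=genes)
    label_s = _kme_filter(values, label_s, kme_threshold, min_module_size)
    label_s = _merge_similar(values, label_s, merge_cut)
    label_s = _renumber_by_size(label_s)
    eigengenes, ve = module_eigengenes(values, label_s)
    kme = intramodular_connectivity(values, eigengenes) if len(eigengenes) else \
        pd.DataFrame(index=genes)
    return ModulePartition(labels=label_s, eigengenes=eigengenes, var_explained=ve,
                           kme=kme, linkage=Z)


def _collect_cut_nodes(tree, cut_height: float):
    """Subtree roots at or below the static cut height (the initial branches)."""
    out = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.dist <= cut_height:
            out.append(node)
        else:
            stack.extend([node.left, node.right])
    return out


def _kme_filter(values: pd.DataFrame, labels: pd.Series, kme_threshold: float,
                min_module_size: int, rescue_threshold: float = 0.5) -> pd.Series:
    """kME-based membership cleanup.

    Genes whose kME to their own module eigengene falls below
    ``kme_threshold`` are unassigned (weakly attached leaves picked up by the
    branch cut); unassigned genes whose best |kME| reaches
    ``rescue_threshold`` are assigned to that module (tight members dropped
    by the cut). Modules falling below the minimum size are dissolved.
    """
    if kme_threshold <= 0 or (labels > 0).sum() == 0:
        return labels
    labels = labels.copy()
    eigengenes, _ = module_eigengenes(values, labels)
    kme = intramodular_connectivity(values, eigengenes)
    for mod in eigengenes.index:
        members = labels[labels == mod].index
        weak = members[kme.loc[members, mod] < kme_threshold]
        labels[weak] = 0
    grey = labels[labels == 0].index
    if len(grey) and len(eigengenes):
        best = kme.loc[grey].abs().idxmax(axis=1)
        best_val = kme.loc[grey].abs().max(axis=1)
        rescued = grey[best_val >= rescue_threshold]
        labels[rescued] = best[rescued].astype(int)
    sizes = labels[labels > 0].value_counts()
    for mod, size in sizes.items():
        if size < min_module_size:
            labels[labels == mod] = 0
    return labels


def _merge_similar(values: pd.DataFrame, labels: pd.Series, merge_cut: float,
                   max_rounds: int = 10) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < merge_cut."""
    labels = labels.copy()
    for _ in range(max_rounds):
        mods = sorted(set(labels[labels > 0]))
        if len(mods) < 2:
            return labels
        eigengenes, _ = module_eigengenes(values, labels)
        E = eigengenes.to_numpy(dtype=float)
        C = np.corrcoef(E)
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            return labels
        keep, absorb = mods[i], mods[j]
        labels[labels == absorb] = keep
    return labels


def _renumber_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels > 0].value_counts()
    # descending size; ties broken by old label for determinism
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(lambda v: remap.get(v, 0)).astype(int)


def tom_similarity_bruteforce(adj) -> np.ndarray:
    """Triple-loop reference TOM, for small instances only (test oracle)."""
    A = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                if u != i and u != j:
                    l_ij += A[i, u] * A[u, j]
            k_i = sum(A[i, u] for u in range(n) if u != i)
            k_j = sum(A[j, u] for u in range(n) if u != j)
            denom = min(k_i, k_j) + 1.0 - A[i, j]
            omega[i, j] = (l_ij + A[i, j]) / denom if denom != 0 else 0.0
    return omega
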