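"""Marker-anchored module significance and cell-type contrasts.

Gene Significance (GS) of a gene is the absolute Pearson correlation of its
expression with the eigengene of a literature-derived marker-gene set (here,
osteoblast/osteocyte markers). Module Significance (MS) is the mean GS over a
module's members; its null distribution is built by repeatedly drawing
module-sized GS sets from the pool of network (module-assigned) GS scores.
The permutation p-value follows the strict counting rule
p = #(random mean > observed MS) / n_perm, which can be exactly zero; a
conservative (count+1)/(n_perm+1) estimate is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netbuild import _first_pc

logger = logging.getLogger(__name__)


def marker_eigengene(expr, markers) -> pd.Series:
    """First principal component of the standardized marker submatrix.

    Oriented so the mean marker correlation is >= 0, unit variance.
    """
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    markers = [m for m in markers if m in values.index]
    if len(markers) < 2:
        raise ValueError("need at least 2 resolvable marker genes")
    X = values.loc[markers].to_numpy(dtype=float)
    scores, _ = _first_pc(X)
    return pd.Series(scores, index=values.columns, name="marker_eigengene")


def gene_significance(expr, marker_eig: pd.Series) -> pd.Series:
    """GS_g = |Pearson r(x_g, marker eigengene)| in [0, 1]."""
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    e = marker_eig.reindex(values.columns).to_numpy(dtype=float)
    X = values.to_numpy(dtype=float)
    Xz = X - X.mean(axis=1, keepdims=True)
    ez = e - e.mean()
    xn = np.linalg.norm(Xz, axis=1)
    en = np.linalg.norm(ez)
    zero = xn == 0
    if zero.any():
        logger.warning("%d zero-variance genes: GS recorded as 0", zero.sum())
    xn[zero] = np.inf
    gs = np.abs(Xz @ ez) / (xn * en)
    return pd.Series(np.clip(gs, 0.0, 1.0), index=values.index, name="GS")


@dataclass
class SignificanceReport:
    """Per-module MS with permutation p-values and Bonferroni flags."""

    gs: pd.Series
    table: pd.DataFrame  # module, size, MS, p, p_conservative, significant
    n_permutations: int
    seed: int
    bonferroni_threshold: float


def _perm_mean_pvalues(pool: np.ndarray, observed: float, size: int,
                       n_perm: int, rng: np.random.Generator) -> tuple:
    """Strict-greater permutation p for a mean of ``size`` draws from pool."""
    count = 0
    for _ in range(n_perm):
        draw = pool[rng.choice(pool.size, size=size, replace=False)]
        if draw.mean() > observed:
            count += 1
    return count / n_perm, (count + 1) / (n_perm + 1)


def module_significance_test(gs: pd.Series, labels: pd.Series,
                             n_perm: int = 10_000, seed: int = 0) -> SignificanceReport:
    """MS per module with the module-sized resampling null.

    The null pool is the GS scores of module-assigned genes only (the network
    pool). p counts random means strictly greater than the observed MS.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; permutation p is coarse", n_perm)
    labels = labels.reindex(gs.index).fillna(0).astype(int)
    pool = gs[labels > 0].to_numpy(dtype=float)
    if pool.size == 0:
        raise ValueError("no module-assigned genes: empty null pool")
    mods = sorted(set(labels[labels > 0]))
    n_modules = len(mods)
    thresh = 0.05 / n_modules
    rng = np.random.default_rng(seed)
    rows = []
    for mod in mods:
        members = gs[labels == mod]
        if len(members) == 0:
            continue
        ms = float(members.mean())
        p, p_cons = _perm_mean_pvalues(pool, ms, len(members), n_perm, rng)
        rows.append({"module": mod, "size": len(members), "MS": ms,
                     "p": p, "p_conservative": p_cons,
                     "p_annotation": f"<{1 / n_perm:g}" if p == 0 else "",
                     "significant": p < thresh})
    table = pd.DataFrame(rows).set_index("module")
    return SignificanceReport(gs=gs, table=table, n_permutations=n_perm,
                              seed=seed, bonferroni_threshold=thresh)


def celltype_contrast_test(network_labels: pd.Series, reference,
                           target_type: str, n_perm: int = 10_000,
                           seed: int = 0) -> pd.DataFrame:
    """Per-module expression contrast of the target cell type vs all others.

    Per gene, the target value is the max over the target type's time-point
    means ("highest of the time points"); the contrast is that value minus
    the mean over all non-target samples. Module contrasts are means over
    member genes, with a permutation p from resampling module-sized gene sets
    out of all network genes present in the reference.
    """
    values, samples = reference.values, reference.samples
    shared = [g for g in network_labels.index if g in values.index]
    if not shared:
        raise ValueError("no genes shared between network and reference")
    labels = network_labels.loc[shared].astype(int)
    V = values.loc[shared]

    is_target = samples["cell_type"] == target_type
    if not is_target.any():
        raise ValueError(f"target type {target_type!r} absent from reference")
    tp_means = []
    for tp, cols in samples[is_target].groupby("time_point").groups.items():
        tp_means.append(V[list(cols)].mean(axis=1))
    target_val = pd.concat(tp_means, axis=1).max(axis=1)
    other_cols = samples.index[~is_target]
    other_val = V[list(other_cols)].mean(axis=1)
    contrast = (target_val - other_val).to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    mods = sorted(set(labels[labels > 0]))
    rows = []
    pool = contrast  # all network genes present in the reference
    for mod in mods:
        mask = (labels == mod).to_numpy()
        obs = float(contrast[mask].mean())
        size = int(mask.sum())
        count = 0
        for _ in range(n_perm):
            draw = pool[rng.choice(pool.size, size=size, replace=False)]
            if draw.mean() >= obs:
                count += 1
        p = count / n_perm
        rows.append({"module": mod, "size": size, "mean_log2_diff": obs,
                     "p": p, "p_annotation": f"<{1 / n_perm:g}" if p == 0 else "",
                     "comparator": "all_other_samples"})
    return pd.DataFrame(rows).set_index("module")
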