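"""Module-trait association and perturbation-concordance statistics.

The module eigengene is regressed on the trait and its square (the module
may track a trait non-monotonically, e.g. a U-shaped eigengene-BMD
relationship); significance is the overall F-test of the quadratic model
against the intercept-only model. Genotype-stratified percent differences
and the per-module correlation between panel differences and perturbation
(e.g. siRNA knockdown) differences follow the conventions:

    panel difference  = 100 * (mean_ref - mean_other) / mean_ref
    perturbation diff = 100 * (perturbed - control) / perturbed

with the reference group named explicitly in every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class QuadraticFit:
    intercept: float
    linear: float
    quadratic: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    coef_pvalues: tuple


def quadratic_association(eigengene, trait) -> QuadraticFit:
    """Least-squares fit of eigengene on (trait, trait^2), overall F-test."""
    if isinstance(eigengene, pd.Series) and isinstance(trait, pd.Series):
        shared = eigengene.index.intersection(trait.index)
        eigengene = eigengene.loc[shared]
        trait = trait.loc[shared]
    y = np.asarray(eigengene, dtype=float).ravel()
    t = np.asarray(trait, dtype=float).ravel()
    if len(y) != len(t):
        raise ValueError("eigengene and trait must cover the same strains")
    if len(y) < 5:
        raise ValueError("need at least 5 strains")
    if t.var() == 0:
        raise ValueError("constant trait: quadratic model undefined")
    X = sm.add_constant(np.column_stack([t, t**2]))
    fit = sm.OLS(y, X).fit()
    return QuadraticFit(
        intercept=float(fit.params[0]), linear=float(fit.params[1]),
        quadratic=float(fit.params[2]), r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue), p_value=float(fit.f_pvalue),
        n=len(y), coef_pvalues=tuple(float(p) for p in fit.pvalues),
    )


def genotype_stratified_percent_diff(values, genotype, reference: int = 1) -> float:
    """100 * (mean_ref - mean_other) / mean_ref across the two genotype groups."""
    v = np.asarray(values, dtype=float).ravel()
    g = np.asarray(genotype).ravel()
    ref = v[g == reference]
    other = v[g != reference]
    if len(ref) == 0 or len(other) == 0:
        raise ValueError("both genotype groups must be non-empty")
    mref = ref.mean()
    if mref == 0:
        logger.warning("reference group mean is 0: percent difference undefined")
        return np.nan
    return float(100.0 * (mref - other.mean()) / mref)


def perturbation_percent_diff(perturbed, control) -> np.ndarray:
    """Per-gene 100 * (perturbed - control) / perturbed (perturbed denominator)."""
    p = np.asarray(perturbed, dtype=float)
    c = np.asarray(control, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * (p - c) / p


def knockdown_contrast_correlation(hmdp_diff: pd.Series, perturb_diff: pd.Series,
                                   labels: pd.Series) -> pd.DataFrame:
    """Per-module concordance between panel and perturbation differences.

    For each module: the mean of both per-gene percent-difference vectors
    over shared member genes, and the Pearson correlation between them with
    its p-value, Bonferroni-flagged at 0.05 / n_modules. Modules with fewer
    than 3 shared genes are reported with an undefined correlation.
    """
    shared = hmdp_diff.index.intersection(perturb_diff.index)
    labels = labels.reindex(shared).fillna(0).astype(int)
    mods = sorted(set(labels[labels > 0]))
    if not mods:
        raise ValueError("no module-assigned genes among shared genes")
    threshold = 0.05 / len(mods)
    rows = []
    for mod in mods:
        genes = labels[labels == mod].index
        h = hmdp_diff.loc[genes].to_numpy(dtype=float)
        s = perturb_diff.loc[genes].to_numpy(dtype=float)
        row = {"module": mod, "n_genes": len(genes),
               "mean_hmdp_diff": float(np.nanmean(h)) if len(h) else np.nan,
               "mean_perturb_diff": float(np.nanmean(s)) if len(s) else np.nan}
        if len(genes) < 3 or np.std(h) == 0 or np.std(s) == 0:
            row.update({"diff_r": np.nan, "diff_p": np.nan,
                        "significant": False, "undefined": True})
        else:
            r, p = stats.pearsonr(h, s)
            row.update({"diff_r": float(r), "diff_p": float(p),
                        "significant": bool(p < threshold), "undefined": False})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("module")
    out["threshold"] = threshold
    return out
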