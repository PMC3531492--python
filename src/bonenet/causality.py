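"""Single-marker causal orientation of marker -> gene -> module relations.

For a triad (M = marker genotype, A = candidate gene expression, B = module
eigengene) three structural models are compared, each imposing exactly one
testable constraint on the correlation matrix:

* causal      M -> A -> B : cor(M,B) = cor(M,A) * cor(A,B)
* reactive    M -> B -> A : cor(M,A) = cor(M,B) * cor(A,B)
* independent A <- M -> B : cor(A,B) = cor(M,A) * cor(M,B)

Each constraint is equivalent to a vanishing partial correlation, and the
maximum-likelihood chi-square for the corresponding path model has the
closed form chi2 = -(n - 1) * ln(1 - r_partial^2) with 1 degree of freedom
(the ML-fitted covariance matches the sample covariance on the model's
cliques, making the trace term exactly 3). An iterative ML fit of the same
discrepancy function is provided for cross-checking. The LEO.NB score is
log10(p_causal / p_next_best); scores above 1.0 are treated as strong
evidence for the causal orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

MODELS = ("causal", "reactive", "independent")
P_FLOOR = 1e-300


@dataclass
class TriadData:
    """Marker / candidate / eigengene vectors plus their correlations."""

    M: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float).ravel()
        self.A = np.asarray(self.A, dtype=float).ravel()
        self.B = np.asarray(self.B, dtype=float).ravel()
        if not (len(self.M) == len(self.A) == len(self.B)):
            raise ValueError("triad vectors must share a length")
        if min(self.M.var(), self.A.var(), self.B.var()) <= 0:
            raise ValueError("triad variables must have positive variance")

    @property
    def n(self) -> int:
        return len(self.M)

    def correlations(self) -> np.ndarray:
        R = np.corrcoef(np.vstack([self.M, self.A, self.B]))
        if abs(np.linalg.det(R)) < 1e-14:
            raise ValueError("singular triad correlation matrix")
        return R


def _partial_r(rxy: float, rxz: float, ryz: float) -> float:
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("degenerate correlations: partial correlation undefined")
    return (rxy - rxz * ryz) / denom


def sem_model_pvalue(triad: TriadData, model: str, method: str = "closed") -> tuple:
    """Chi-square, df and p for one structural model of the triad.

    ``method='closed'`` uses the analytic partial-correlation form;
    ``method='ml'`` minimizes the ML discrepancy
    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - 3 over the model's two path
    coefficients numerically. Both yield df = 1.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if triad.n < 10:
        raise ValueError("need at least 10 observations")
    R = triad.correlations()
    r_MA, r_MB, r_AB = R[0, 1], R[0, 2], R[1, 2]
    if method == "closed":
        if model == "causal":        # M ⟂ B | A
            pr = _partial_r(r_MB, r_MA, r_AB)
        elif model == "reactive":    # M ⟂ A | B
            pr = _partial_r(r_MA, r_MB, r_AB)
        else:                        # A ⟂ B | M
            pr = _partial_r(r_AB, r_MA, r_MB)
        pr2 = min(pr**2, 1 - 1e-15)
        chi2 = -(triad.n - 1) * np.log1p(-pr2)
    elif method == "ml":
        chi2 = _ml_chi2(R, model, triad.n)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def _implied_correlation(model: str, a: float, b: float) -> np.ndarray:
    """Implied correlation matrix of (M, A, B) under a path model."""
    R = np.eye(3)
    if model == "causal":       # M -a-> A -b-> B
        R[0, 1] = a; R[1, 2] = b; R[0, 2] = a * b
    elif model == "reactive":   # M -a-> B -b-> A
        R[0, 2] = a; R[1, 2] = b; R[0, 1] = a * b
    else:                       # A <-a- M -b-> B
        R[0, 1] = a; R[0, 2] = b; R[1, 2] = a * b
    R[1, 0], R[2, 1], R[2, 0] = R[0, 1], R[1, 2], R[0, 2]
    return R


def _ml_chi2(S: np.ndarray, model: str, n: int) -> float:
    logdet_s = np.log(np.linalg.det(S))

    def discrepancy(theta):
        a, b = np.tanh(theta)  # keep paths inside (-1, 1)
        Sigma = _implied_correlation(model, a, b)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return 1e6
        return logdet + np.trace(S @ np.linalg.inv(Sigma)) - logdet_s - 3.0

    res = optimize.minimize(discrepancy, x0=np.array([0.1, -0.1]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 5000})
    return float((n - 1) * max(res.fun, 0.0))


@dataclass
class CausalScore:
    """Per-model fits and the LEO next-best score for one triad."""

    chi2: dict
    p: dict
    leo_nb: float
    best_model: str
    floored: bool


def leo_nb_single_marker(triad: TriadData) -> CausalScore:
    """LEO.NB.AtoB = log10(p_causal) - log10(max(p_reactive, p_independent)).

    p-values are floored at 1e-300 before the ratio; a bound floor is
    flagged. A numerically zero next-best p yields an infinite score with
    the flag set.
    """
    chi2, p = {}, {}
    for model in MODELS:
        chi2[model], _, p[model] = sem_model_pvalue(triad, model)
    p_next = max(p["reactive"], p["independent"])
    floored = p["causal"] < P_FLOOR or p_next < P_FLOOR
    score = np.log10(max(p["causal"], P_FLOOR)) - np.log10(max(p_next, P_FLOOR))
    if p_next == 0.0 and p["causal"] > 0.0:
        score = np.inf
    best = max(MODELS, key=lambda m: p[m])
    return CausalScore(chi2=chi2, p=p, leo_nb=float(score), best_model=best,
                       floored=bool(floored))


def overlap_fraction(candidate_expr, module_expr, r_threshold: float = 0.25) -> float:
    """Fraction of module genes correlated with the candidate at |r| > threshold.

    The inequality is strict, so a gene at exactly the threshold is excluded.
    """
    module_expr = pd.DataFrame(module_expr)
    if module_expr.shape[0] == 0:
        raise ValueError("empty module")
    x = np.asarray(candidate_expr, dtype=float).ravel()
    X = module_expr.to_numpy(dtype=float)
    xz = x - x.mean()
    Xz = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xz)
    Xn = np.linalg.norm(Xz, axis=1)
    Xn[Xn == 0] = np.inf
    r = (Xz @ xz) / (Xn * xn)
    return float((np.abs(r) > r_threshold).mean())


def rank_candidate_regulators(local_table: pd.DataFrame, expr, labels: pd.Series,
                              eigengene: pd.Series, lead_snp_genotype,
                              module: int, r_threshold: float = 0.25,
                              only_significant: bool = True) -> pd.DataFrame:
    """Candidate-regulator table: eSNP p, overlap %, eigengene r, LEO.NB.

    Candidates are the genes with (by default significant) local eQTL in the
    region table; the marker M for every LEO fit is the lead module-QTL SNP.
    Rows are sorted by genomic position and the maximum-score candidate is
    flagged.
    """
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    table = local_table[local_table["significant"]] if only_significant else local_table
    if len(table) == 0:
        logger.info("no significant local-eQTL candidates in region")
        return pd.DataFrame(columns=["gene", "probe", "chr", "gene_bp", "esnp_p",
                                     "overlap_pct", "me_r", "leo_nb", "top_candidate"])
    labels = labels.reindex(values.index).fillna(0).astype(int)
    module_genes = labels[labels == module].index
    Mvec = np.asarray(lead_snp_genotype, dtype=float).ravel()
    Bvec = eigengene.reindex(values.columns).to_numpy(dtype=float)

    rows = []
    for r in table.itertuples():
        a = values.loc[r.probe].to_numpy(dtype=float)
        ov = overlap_fraction(a, values.loc[module_genes], r_threshold)
        me_r = float(np.corrcoef(a, Bvec)[0, 1])
        try:
            score = leo_nb_single_marker(TriadData(M=Mvec, A=a, B=Bvec)).leo_nb
        except ValueError:
            score = np.nan
        rows.append({"gene": r.gene, "probe": r.probe, "chr": r.chr,
                     "gene_bp": r.gene_bp, "esnp_p": r.p,
                     "overlap_pct": 100.0 * ov, "me_r": me_r, "leo_nb": score})
    out = pd.DataFrame(rows).sort_values("gene_bp").reset_index(drop=True)
    out["top_candidate"] = False
    if out["leo_nb"].notna().any():
        out.loc[out["leo_nb"].idxmax(), "top_candidate"] = True
    return out
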