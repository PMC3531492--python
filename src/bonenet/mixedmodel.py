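"""EMMA-style mixed-model association mapping for inbred panels.

Model: y = X b + u + e with u ~ N(0, sigma_g^2 K) and e ~ N(0, sigma_e^2 I),
where K is the strain kinship (identity-by-state proportion). Variance
components are estimated by REML through a single spectral decomposition and
a 1-D optimization over the variance ratio delta = sigma_e^2 / sigma_g^2;
per-SNP tests are generalized least squares on variance-rotated data with
the null-model variance components reused for every SNP (EMMAX-style
approximation; exact per-SNP re-estimation available via ``per_snp_reml``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

RIDGE_EPS = 1e-6


def kinship_matrix(genotypes) -> pd.DataFrame:
    """Identity-by-state kinship: proportion of SNPs with identical codes."""
    G = genotypes.genotypes.to_numpy(dtype=float)  # snps x strains
    if G.shape[0] < 2:
        raise ValueError("need at least 2 SNPs for kinship")
    if ((G.min(axis=1) == G.max(axis=1))).all():
        logger.warning("all SNPs monomorphic: kinship is uninformative")
    m = G.shape[0]
    K = (G.T @ G + (1 - G).T @ (1 - G)) / m
    strains = genotypes.strains
    K = pd.DataFrame(K, index=strains, columns=strains)
    np.fill_diagonal(K.values, 1.0)
    return K


def _psd_kinship(K: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(K)
    if w.min() < 0:
        K = K + RIDGE_EPS * np.eye(K.shape[0])
        if np.linalg.eigvalsh(K).min() < -1e-10:
            raise ValueError("kinship not positive semi-definite after ridge adjustment")
    return K


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    pseudo_heritability: float
    boundary: bool


@dataclass
class _SpectralNull:
    """Cached spectral pieces for one covariate design and kinship."""

    xis: np.ndarray      # nonzero eigenvalues of S (K + I) S, length n - q
    U: np.ndarray        # corresponding eigenvectors (n x (n - q))
    n: int
    q: int


def _spectral_null(K: np.ndarray, X: np.ndarray) -> _SpectralNull:
    n, q = X.shape
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    M = S @ (K + np.eye(n)) @ S
    w, V = np.linalg.eigh(M)
    idx = np.argsort(w)[::-1][: n - q]
    xis = np.maximum(w[idx] - 1.0, 1e-12)  # eigenvalues of S K S part, clipped
    return _SpectralNull(xis=xis, U=V[:, idx], n=n, q=q)


def _reml_loglik(log_delta: float, xis: np.ndarray, eta2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    nq = xis.size
    denom = xis + delta
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi))
        - nq
        - nq * np.log(np.sum(eta2 / denom))
        - np.sum(np.log(denom))
    )


def reml_variance_components(y, X, K, grid_bounds=(-10.0, 10.0),
                             grid_points: int = 100) -> VarianceComponents:
    """REML variance components by grid search plus bracketed refinement.

    The restricted likelihood is profiled down to the ratio
    delta = sigma_e^2/sigma_g^2 and maximized over log delta on a grid,
    followed by bounded 1-D refinement around every grid local maximum.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("NaNs in response")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, q = X.shape
    if n < q + 2:
        raise ValueError("need at least q + 2 observations")
    K = _psd_kinship(np.asarray(K, dtype=float))
    spec = _spectral_null(K, X)
    eta = spec.U.T @ y
    eta2 = eta**2

    lo, hi = grid_bounds
    grid = np.linspace(lo, hi, grid_points)
    ll = np.array([_reml_loglik(g, spec.xis, eta2) for g in grid])

    candidates = [(ll[0], grid[0]), (ll[-1], grid[-1])]
    for i in range(1, grid_points - 1):
        if ll[i] >= ll[i - 1] and ll[i] >= ll[i + 1]:
            res = optimize.minimize_scalar(
                lambda g: -_reml_loglik(g, spec.xis, eta2),
                bounds=(grid[i - 1], grid[i + 1]), method="bounded",
                options={"xatol": 1e-8},
            )
            candidates.append((-res.fun, res.x))
    best_ll, best_logdelta = max(candidates, key=lambda t: t[0])
    boundary = best_logdelta in (grid[0], grid[-1])

    delta = float(np.exp(best_logdelta))
    nq = spec.xis.size
    sigma_g2 = float(np.sum(eta2 / (spec.xis + delta)) / nq)
    sigma_e2 = float(delta * sigma_g2)
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
        reml_loglik=float(best_ll),
        pseudo_heritability=1.0 / (1.0 + delta),
        boundary=bool(boundary),
    )


def _rotation(K: np.ndarray, delta: float) -> tuple:
    """Whitening transform W such that W y has iid errors under the model."""
    w, U = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    scale = 1.0 / np.sqrt(w + delta)
    return U, scale


def _gls_scan(ty: np.ndarray, tX: np.ndarray, tG: np.ndarray) -> tuple:
    """Per-SNP GLS given rotated response, covariates and genotypes.

    Residualizes the rotated genotypes and response against the rotated
    covariates, then tests each SNP coefficient with a two-sided t-test on
    n - q - 1 degrees of freedom.
    """
    n, q = tX.shape
    Q, _ = np.linalg.qr(tX)
    ey = ty - Q @ (Q.T @ ty)
    eG = tG - Q @ (Q.T @ tG)
    gg = np.einsum("ij,ij->j", eG, eG)
    gy = eG.T @ ey
    yy = float(ey @ ey)
    df = n - q - 1
    zero = gg <= 1e-12
    gg_safe = np.where(zero, 1.0, gg)
    beta = gy / gg_safe
    rss = np.maximum(yy - beta * gy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    beta[zero] = 0.0
    se[zero] = np.nan
    tstat[zero] = 0.0
    p[zero] = 1.0
    return beta, se, tstat, p, zero


def association_scan(y, genotypes, K=None, vc: VarianceComponents = None,
                     X=None, response_id: str = "trait",
                     per_snp_reml: bool = False) -> pd.DataFrame:
    """Genome-wide mixed-model association scan for one response.

    With ``K=None`` (identity kinship) the scan reduces exactly to ordinary
    least squares. Zero-variance SNPs are reported with p = 1 and flagged.
    """
    yv = np.asarray(pd.Series(y).reindex(genotypes.strains)
                    if isinstance(y, pd.Series) else y, dtype=float)
    n = len(genotypes.strains)
    if yv.shape != (n,):
        raise ValueError("response length must match strain count")
    Xv = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    Kv = np.eye(n) if K is None else _psd_kinship(np.asarray(K, dtype=float))
    G = genotypes.genotypes.to_numpy(dtype=float).T  # strains x snps

    if per_snp_reml:
        rows = []
        for j in range(G.shape[1]):
            g = G[:, j]
            if g.var() == 0:
                rows.append((0.0, np.nan, 0.0, 1.0, True))
                continue
            vc_j = reml_variance_components(yv, np.column_stack([Xv, g]), Kv)
            U, scale = _rotation(Kv, vc_j.delta)
            ty = scale * (U.T @ yv)
            tX = scale[:, None] * (U.T @ Xv)
            tg = scale * (U.T @ g)
            b, se, t, p, z = _gls_scan(ty, tX, tg[:, None])
            rows.append((b[0], se[0], t[0], p[0], False))
        beta, se, tstat, p, zero = map(np.array, zip(*rows))
    else:
        if vc is None:
            vc = reml_variance_components(yv, Xv, Kv)
        U, scale = _rotation(Kv, vc.delta)
        ty = scale * (U.T @ yv)
        tX = scale[:, None] * (U.T @ Xv)
        tG = scale[:, None] * (U.T @ G)
        beta, se, tstat, p, zero = _gls_scan(ty, tX, tG)

    out = genotypes.snp_map.copy()
    out.insert(0, "snp", out.index)
    out["response"] = response_id
    out["beta"] = beta
    out["se"] = se
    out["t"] = tstat
    out["p"] = p
    out["zero_variance"] = zero
    return out


def eqtl_scan(expr, genotypes, K, probes=None) -> pd.DataFrame:
    """Full probe x SNP association table (small inputs only).

    For genome-scale runs use :func:`eqtl_bin_minima`, which streams one
    probe at a time and never materializes more than one full scan.
    """
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    probes = list(values.index) if probes is None else list(probes)
    scans = []
    for batch in _stream_probe_scans(values.loc[probes], genotypes, K):
        scans.append(batch)
    return pd.concat(scans, axis=0, ignore_index=True)


def _stream_probe_scans(values: pd.DataFrame, genotypes, K):
    """Yield one probe's association table at a time, sharing spectral work."""
    n = len(genotypes.strains)
    Kv = _psd_kinship(np.asarray(K, dtype=float))
    Xv = np.ones((n, 1))
    spec = _spectral_null(Kv, Xv)
    wK, UK = np.linalg.eigh(Kv)
    wK = np.maximum(wK, 0.0)
    G = genotypes.genotypes.to_numpy(dtype=float).T
    UG = UK.T @ G
    UX = UK.T @ Xv
    Y = values.to_numpy(dtype=float)
    H = (spec.U.T @ Y.T) ** 2  # (n - q) x probes, squared projections

    grid = np.linspace(-10.0, 10.0, 100)
    for i, probe in enumerate(values.index):
        eta2 = H[:, i]
        ll = np.array([_reml_loglik(g, spec.xis, eta2) for g in grid])
        j = int(np.argmax(ll))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda g: -_reml_loglik(g, spec.xis, eta2),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
        )
        delta = float(np.exp(res.x if -res.fun >= ll[j] else grid[j]))
        scale = 1.0 / np.sqrt(wK + delta)
        ty = scale * (UK.T @ Y[i])
        tX = scale[:, None] * UX
        tG = scale[:, None] * UG
        beta, se, tstat, p, zero = _gls_scan(ty, tX, tG)
        out = genotypes.snp_map.copy()
        out.insert(0, "snp", out.index)
        out["response"] = probe
        out["beta"] = beta
        out["se"] = se
        out["t"] = tstat
        out["p"] = p
        out["zero_variance"] = zero
        yield out.reset_index(drop=True)


def eqtl_bin_minima(expr, genotypes, K, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-probe minimum association p-value within each genomic bin.

    Streams probes one at a time (memory contract). ``bins`` is a bin table
    with columns chr/start/end (half-open intervals); returns a probes x bins
    DataFrame of minimum p-values (NaN for SNP-free bins).
    """
    values = expr.values if hasattr(expr, "annotation") else pd.DataFrame(expr)
    snp_bin = assign_snps_to_bins(genotypes.snp_map, bins)
    nbins = len(bins)
    valid = snp_bin >= 0
    occupied = np.zeros(nbins, dtype=bool)
    occupied[snp_bin[valid]] = True
    out = np.full((values.shape[0], nbins), np.nan)
    for i, scan in enumerate(_stream_probe_scans(values, genotypes, K)):
        p = scan["p"].to_numpy()
        mins = np.full(nbins, np.inf)
        np.minimum.at(mins, snp_bin[valid], p[valid])
        mins[~occupied] = np.nan
        out[i] = mins
    return pd.DataFrame(out, index=values.index, columns=bins.index)


def assign_snps_to_bins(snp_map: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Bin index per SNP (-1 when the SNP falls outside every bin)."""
    idx = np.full(len(snp_map), -1, dtype=int)
    for b, (chrom, start, end) in enumerate(zip(bins["chr"], bins["start"], bins["end"])):
        sel = ((snp_map["chr"].astype(str) == str(chrom))
               & (snp_map["bp"] >= start) & (snp_map["bp"] < end))
        idx[sel.to_numpy()] = b
    return idx


def local_eqtl_table(expr, genotypes, K, region: tuple,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Best local eSNP per gene inside a genomic region, with Bonferroni flags.

    Probes whose annotated position lies inside ``region = (chr, start, end)``
    are tested against the SNPs inside the region; per gene, the probe with
    the most significant local eSNP is retained. The Bonferroni threshold is
    ``alpha / n_unique_genes_in_region``.
    """
    chrom, start, end = region
    ann = expr.annotation
    probe_sel = ((ann["chr"].astype(str) == str(chrom))
                 & (ann["bp"] >= start) & (ann["bp"] <= end))
    snp_sel = ((genotypes.snp_map["chr"].astype(str) == str(chrom))
               & (genotypes.snp_map["bp"] >= start)
               & (genotypes.snp_map["bp"] <= end))
    if probe_sel.sum() == 0 or snp_sel.sum() == 0:
        return pd.DataFrame(columns=["gene", "probe", "snp", "chr", "bp",
                                     "p", "n_genes_region", "threshold",
                                     "significant"])
    from .datatypes import GenotypeData

    local_geno = GenotypeData(
        genotypes=genotypes.genotypes.loc[snp_sel],
        snp_map=genotypes.snp_map.loc[snp_sel],
    )
    sub = expr.values.loc[probe_sel[probe_sel].index]
    n_genes = ann.loc[probe_sel, "gene"].nunique()
    threshold = alpha / n_genes

    rows = []
    for scan in _stream_probe_scans(sub, local_geno, K):
        probe = scan["response"].iloc[0]
        best = scan.loc[scan["p"].idxmin()]
        rows.append({"gene": ann.loc[probe, "gene"], "probe": probe,
                     "snp": best["snp"], "chr": best["chr"], "bp": best["bp"],
                     "p": best["p"]})
    table = pd.DataFrame(rows)
    table = table.loc[table.groupby("gene")["p"].idxmin()].reset_index(drop=True)
    table["gene_bp"] = [ann.loc[pr, "bp"] for pr in table["probe"]]
    table = table.sort_values("gene_bp").reset_index(drop=True)
    table["n_genes_region"] = n_genes
    table["threshold"] = threshold
    table["significant"] = table["p"] <= threshold
    return table
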