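"""Synthetic inbred-panel generator with planted co-expression structure.

The generator emulates the data architecture of a mouse diversity-panel bone
study: ~96 fully inbred strains genotyped at biallelic SNPs, a log2
expression matrix carrying latent-factor co-expression modules, one module
whose factor is partly driven by a "driver" gene under a local (cis) eQTL so
that a trans-eQTL hotspot and a module QTL exist, a designated marker-gene
subset inside that module, a cell-type reference panel with the module's
genes elevated in one cell type, and a quantitative trait with a quadratic
(U-shaped) relationship to the module eigengene.

Every function takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CellTypeReference,
    ExpressionMatrix,
    GenomeSpec,
    GenotypeData,
    PlantedTruth,
    TraitTable,
)

# Expected one recombination breakpoint per 30 Mb of chromosome per strain:
# a coarse but serviceable stand-in for the LD block structure of an inbred panel.
DEFAULT_BREAKPOINT_RATE = 1.0 / 30_000_000


def _snp_positions(rng: np.random.Generator, length: int, count: int) -> np.ndarray:
    pos = rng.choice(length, size=count, replace=False) + 1
    pos.sort()
    return pos


def simulate_genotypes(
    n_strains: int,
    n_founders: int,
    genome: GenomeSpec,
    seed: int,
    maf_floor: float = 0.05,
    breakpoint_rate: float = DEFAULT_BREAKPOINT_RATE,
    max_resample: int = 200,
) -> GenotypeData:
    """Simulate homozygous genotypes as founder-haplotype mosaics.

    Each strain's chromosome is a mosaic of ``n_founders`` haplotypes with
    breakpoints drawn as a Poisson process along the bp coordinate, which
    induces local LD and realistic kinship. SNPs whose minor allele frequency
    falls below ``maf_floor`` have their founder alleles redrawn (the mosaic
    is kept fixed); if a SNP cannot reach the floor within ``max_resample``
    redraws the floor is deemed unattainable and a ``ValueError`` is raised.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if not 0.0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must lie in [0, 0.5)")
    if n_founders == 1 and maf_floor > 0:
        raise ValueError("MAF floor unattainable: a single founder yields monomorphic SNPs")

    rng = np.random.default_rng(seed)
    snp_ids, chroms, bps = [], [], []
    founder_idx_cols = []  # per SNP: founder index per strain (strain-major later)

    for (chrom, length), count in zip(genome.chromosomes, genome.snp_count):
        pos = _snp_positions(rng, length, count)
        # founder mosaic per strain for this chromosome
        founder_at = np.empty((n_strains, count), dtype=np.int64)
        for s in range(n_strains):
            n_bp = rng.poisson(breakpoint_rate * length)
            breaks = np.sort(rng.integers(1, length + 1, size=n_bp))
            segs = rng.integers(0, n_founders, size=n_bp + 1)
            founder_at[s] = segs[np.searchsorted(breaks, pos, side="right")]
        founder_idx_cols.append(founder_at)
        snp_ids.extend(f"{chrom}_snp{i + 1}" for i in range(count))
        chroms.extend([chrom] * count)
        bps.extend(pos.tolist())

    founder_at_all = np.concatenate(founder_idx_cols, axis=1)  # strains x snps
    m = founder_at_all.shape[1]
    alleles = rng.integers(0, 2, size=(n_founders, m))  # founder x snp
    G = alleles[founder_at_all, np.arange(m)]  # strains x snps

    if maf_floor >= 0 and n_founders > 1:
        for j in range(m):
            tries = 0
            while True:
                freq = G[:, j].mean()
                if min(freq, 1 - freq) >= maf_floor:
                    break
                tries += 1
                if tries > max_resample:
                    raise ValueError(
                        f"MAF floor {maf_floor} unattainable at SNP index {j}: "
                        f"founder mosaic cannot support it"
                    )
                alleles[:, j] = rng.integers(0, 2, size=n_founders)
                G[:, j] = alleles[founder_at_all[:, j], j]

    strains = [f"strain{s + 1:03d}" for s in range(n_strains)]
    genotypes = pd.DataFrame(G.T.astype(np.int8), index=snp_ids, columns=strains)
    snp_map = pd.DataFrame({"chr": chroms, "bp": bps}, index=snp_ids)
    return GenotypeData(genotypes=genotypes, snp_map=snp_map)


def make_planted_truth(
    genotypes: GenotypeData,
    genome: GenomeSpec,
    seed: int,
    n_genes: int = 2000,
    n_modules: int = 10,
    module_size_range: tuple = (40, 120),
    n_markers: int = 9,
    theta: float = 0.5,
    gamma: float = 3.0,
    lambda_range: tuple = (0.6, 0.9),
    cis_window: int = 1_000_000,
    cis_min_maf: float = 0.3,
    trait_vertex: float = 0.0,
    trait_curvature: float = 1.0,
    trait_noise_sd: float = 1.0,
) -> PlantedTruth:
    """Lay out module assignments, loadings, the cis-driven driver and markers.

    Module 1 is the target module; the driver gene is relocated to within
    ``cis_window`` bp of a randomly chosen common SNP (MAF >= ``cis_min_maf``,
    so the planted local eQTL and downstream trans-hotspot are well powered)
    and the marker genes are drawn from the module's other members.
    """
    rng = np.random.default_rng(seed)
    lo, hi = module_size_range
    sizes = rng.integers(lo, hi + 1, size=n_modules)
    if sizes.sum() > n_genes:
        raise ValueError("module sizes exceed n_genes")
    gene_ids = [f"gene{g + 1:04d}" for g in range(n_genes)]

    module_of = {}
    loadings = {}
    cursor = 0
    for mod, size in enumerate(sizes, start=1):
        for g in gene_ids[cursor:cursor + size]:
            module_of[g] = int(mod)
            loadings[g] = float(rng.uniform(*lambda_range))
        cursor += size

    # gene positions uniform over the genome
    chrom_names = [c for c, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    gchrom = rng.choice(len(chrom_names), size=n_genes, p=lengths / lengths.sum())
    gbp = (rng.random(n_genes) * lengths[gchrom]).astype(np.int64) + 1
    annotation = pd.DataFrame(
        {
            "gene": gene_ids,
            "chr": [chrom_names[c] for c in gchrom],
            "bp": gbp,
        },
        index=gene_ids,
    )

    target_members = [g for g in gene_ids if module_of.get(g) == 1]
    driver = target_members[int(rng.integers(len(target_members)))]
    freqs = genotypes.genotypes.mean(axis=1)
    maf = np.minimum(freqs, 1 - freqs)
    common = maf.index[maf >= cis_min_maf]
    if len(common) == 0:
        common = maf.index[[int(np.argmax(maf.to_numpy()))]]
    cis_snp = common[int(rng.integers(len(common)))]
    snp_row = genotypes.snp_map.loc[cis_snp]
    offset = int(rng.integers(-cis_window // 2, cis_window // 2 + 1))
    chrom_len = dict(genome.chromosomes)[str(snp_row["chr"])]
    annotation.loc[driver, "chr"] = snp_row["chr"]
    annotation.loc[driver, "bp"] = int(np.clip(snp_row["bp"] + offset, 1, chrom_len))

    non_driver = [g for g in target_members if g != driver]
    markers = list(rng.choice(non_driver, size=min(n_markers, len(non_driver)), replace=False))

    return PlantedTruth(
        module_of=module_of,
        loadings=loadings,
        driver_gene=driver,
        driver_cis_snp=str(cis_snp),
        gamma=float(gamma),
        theta=float(theta),
        target_module=1,
        marker_genes=[str(g) for g in markers],
        trait_vertex=float(trait_vertex),
        trait_curvature=float(trait_curvature),
        trait_noise_sd=float(trait_noise_sd),
        seed=int(seed),
        gene_annotation=annotation,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v, dtype=float)
    return (v - v.mean()) / sd


def simulate_expression(
    genotypes: GenotypeData,
    truth: PlantedTruth,
    seed: int,
    noise_sd: float = 1.0,
    target_factor: Optional[np.ndarray] = None,
    gamma: Optional[float] = None,
    theta: Optional[float] = None,
    driver_shift: float = 0.0,
    denom_norm: Optional[float] = None,
    base_mean: float = 8.0,
    base_sd: float = 1.0,
) -> ExpressionMatrix:
    """Simulate log2 expression with planted factor modules and a cis driver.

    Per-gene model (n = strains), on top of a per-gene baseline abundance
    mu_g ~ N(base_mean, base_sd^2) shared by all strains:

    * driver:            x = mu + gamma * g_cis + noise_sd * eps
    * target-module gene: x = mu + lambda_g * F + sqrt(1 - lambda_g^2) * noise_sd * eps,
      where F = (theta * z_driver + (1 - theta) * f_1) / denom with z_driver
      the standardized driver expression, f_1 the module's latent factor and
      denom = sqrt(theta^2 + (1-theta)^2) so F has near-unit variance
    * other-module gene:  same with F = its standardized module factor
    * background gene:    x = mu + noise

    The sqrt(1-lambda^2) noise scaling makes lambda_g the gene-factor
    correlation at unit noise, so within-module correlations are lambda_i *
    lambda_j. ``gamma``/``theta``/``target_factor`` override the recorded
    truth; combined with a reused seed (identical noise stream) this
    supports perturbation re-simulation. ``driver_shift`` lowers the
    standardized driver signal by a constant (a knockdown); ``denom_norm``
    pins the composite normalization to a reference value so perturbed and
    unperturbed runs stay on the same scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    gamma = truth.gamma if gamma is None else float(gamma)
    theta = truth.theta if theta is None else float(theta)
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    strains = genotypes.strains
    n = len(strains)
    gene_ids = list(truth.gene_annotation.index)
    n_genes = len(gene_ids)
    modules = sorted({m for m in truth.module_of.values()})

    base = base_mean + base_sd * rng.standard_normal(n_genes)

    factors = {}
    for mod in modules:
        f = rng.standard_normal(n)
        factors[mod] = f
    if target_factor is not None:
        tf = np.asarray(target_factor, dtype=float)
        if tf.shape != (n,):
            raise ValueError("target_factor must have one value per strain")
        factors[truth.target_module] = tf

    noise = rng.standard_normal((n_genes, n)) * noise_sd

    g_cis = genotypes.genotypes.loc[truth.driver_cis_snp].to_numpy(dtype=float)
    didx = gene_ids.index(truth.driver_gene)
    driver_signal = gamma * g_cis + noise[didx]
    z_driver = _standardize(driver_signal) - driver_shift

    f1 = _standardize(factors[truth.target_module])
    composite = theta * z_driver + (1.0 - theta) * f1
    denom = denom_norm if denom_norm is not None else np.sqrt(
        theta**2 + (1.0 - theta) ** 2)
    composite = composite / denom if denom > 0 else composite

    X = np.empty((n_genes, n), dtype=float)
    for i, g in enumerate(gene_ids):
        if g == truth.driver_gene:
            X[i] = base[i] + driver_signal - driver_shift * driver_signal.std(ddof=1)
            continue
        mod = truth.module_of.get(g, 0)
        if mod == 0:
            X[i] = base[i] + noise[i]
        else:
            lam = truth.loadings[g]
            F = composite if mod == truth.target_module else _standardize(factors[mod])
            X[i] = base[i] + lam * F + np.sqrt(1.0 - lam**2) * noise[i]

    values = pd.DataFrame(X, index=gene_ids, columns=strains)
    return ExpressionMatrix(values=values, annotation=truth.gene_annotation.copy())


def simulate_knockdown(
    genotypes: GenotypeData,
    truth: PlantedTruth,
    seed: int,
    noise_sd: float = 1.0,
    target_factor: Optional[np.ndarray] = None,
    theta_scale: float = 0.5,
    driver_shift: float = 1.5,
    assay_noise_sd: float = 0.1,
    assay_seed: Optional[int] = None,
) -> ExpressionMatrix:
    """Re-simulate expression with the driver effect knocked down.

    Reuses ``seed`` so the noise stream matches the unperturbed simulation
    exactly: the only differences are the halved (by default) driver-module
    coupling, the downward shift of the driver signal, and a small
    independent assay noise so genes untouched by the driver still vary
    between the two conditions.
    """
    denom = np.sqrt(truth.theta**2 + (1.0 - truth.theta) ** 2)
    kd = simulate_expression(
        genotypes, truth, seed=seed, noise_sd=noise_sd,
        target_factor=target_factor, theta=truth.theta * theta_scale,
        driver_shift=driver_shift, denom_norm=denom,
    )
    rng = np.random.default_rng(seed + 1 if assay_seed is None else assay_seed)
    kd.values.iloc[:, :] += assay_noise_sd * rng.standard_normal(kd.values.shape)
    return kd


def simulate_trait(
    n_strains_or_strains,
    vertex: float,
    curvature: float,
    noise_sd: float,
    seed: int,
) -> TraitTable:
    """Sample a trait and build the quadratically-linked module factor.

    The trait t_s is sampled first (standard normal); the eigengene-driving
    factor is curvature*(t_s - vertex)^2 + N(0, noise_sd^2), standardized.
    The module eigengene downstream is therefore a quadratic function of the
    trait by construction (plus noise); with curvature = 0 the factor is
    independent of the trait, giving a null link.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if isinstance(n_strains_or_strains, int):
        strains = [f"strain{s + 1:03d}" for s in range(n_strains_or_strains)]
    else:
        strains = list(n_strains_or_strains)
    n = len(strains)
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    factor = curvature * (t - vertex) ** 2 + rng.standard_normal(n) * noise_sd
    if factor.std(ddof=1) > 0:
        factor = _standardize(factor)
    trait = pd.Series(t, index=strains, name="trait")
    return TraitTable(
        trait=trait,
        factor=factor,
        vertex=float(vertex),
        curvature=float(curvature),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


def simulate_celltype_reference(
    truth: PlantedTruth,
    seed: int,
    n_types: int = 4,
    elevation_log2: float = 2.0,
    replicates: int = 3,
    target_type: str = "osteoblast",
    time_points: Sequence[str] = ("d5", "d14", "d21"),
    time_fractions: Sequence[float] = (0.6, 0.8, 1.0),
    noise_sd: float = 0.25,
    base_mean: float = 8.0,
) -> CellTypeReference:
    """Simulate a labeled cell-type reference panel (genes x samples, log2).

    The target cell type is assayed at several differentiation time points in
    replicate; target-module genes are elevated by ``elevation_log2 * frac``
    at each time point, with the largest fraction equal to 1 so that the
    max-over-time-points contrast rule recovers ``elevation_log2``. All other
    genes (and all genes in the other cell types) are exchangeable noise
    around a shared per-gene baseline.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2 for a defined contrast")
    if n_types < 2:
        raise ValueError("need at least two cell types")
    if len(time_points) != len(time_fractions) or not time_points:
        raise ValueError("time_points and time_fractions must match and be non-empty")

    rng = np.random.default_rng(seed)
    gene_ids = list(truth.gene_annotation.index)
    n_genes = len(gene_ids)
    base = base_mean + rng.standard_normal(n_genes)
    target_mask = np.array(
        [truth.module_of.get(g, 0) == truth.target_module for g in gene_ids]
    )

    other_types = [f"celltype{k + 1}" for k in range(n_types - 1)]
    cols, meta = [], []
    blocks = []
    for tp, frac in zip(time_points, time_fractions):
        for r in range(replicates):
            sid = f"{target_type}_{tp}_r{r + 1}"
            cols.append(sid)
            meta.append((target_type, tp, r + 1))
            x = base + rng.standard_normal(n_genes) * noise_sd
            x = x + np.where(target_mask, elevation_log2 * frac, 0.0)
            blocks.append(x)
    for ct in other_types:
        for r in range(replicates):
            sid = f"{ct}_r{r + 1}"
            cols.append(sid)
            meta.append((ct, "", r + 1))
            blocks.append(base + rng.standard_normal(n_genes) * noise_sd)

    values = pd.DataFrame(np.column_stack(blocks), index=gene_ids, columns=cols)
    samples = pd.DataFrame(meta, index=cols, columns=["cell_type", "time_point", "replicate"])
    return CellTypeReference(values=values, samples=samples)


def simulate_gwas_gene_list(
    truth: PlantedTruth,
    seed: int,
    n_from_target: int = 5,
    n_total: int = 57,
) -> list:
    """An external gene list (e.g. GWAS homologs): a few target-module genes
    plus random non-target genes, for enrichment recovery tests."""
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_annotation.index)
    target = [g for g in genes if truth.module_of.get(g, 0) == truth.target_module]
    rest = [g for g in genes if truth.module_of.get(g, 0) != truth.target_module]
    if n_from_target > len(target) or n_total - n_from_target > len(rest):
        raise ValueError("requested list larger than available gene pools")
    picked = list(rng.choice(target, size=n_from_target, replace=False))
    picked += list(rng.choice(rest, size=n_total - n_from_target, replace=False))
    return [str(g) for g in picked]
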