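"""End-to-end pipeline: simulate -> network -> module scores -> mapping ->
hotspots -> causal candidates -> trait link -> enrichment.

A single ``RunConfig`` seed fans out into per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``, so every stage
is independently reproducible. ``run_full_pipeline`` returns a report of the
headline quantities and (optionally) writes every stage table as TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causality, enrich, hotspots, mixedmodel, modscore, netbuild, synth
from .datatypes import ExpressionMatrix, GenomeSpec, GenotypeData

logger = logging.getLogger(__name__)

STAGES = ("genotypes", "truth", "trait", "expression", "celltype", "network",
          "modscore", "mapping", "causality", "traitlink", "enrich")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


DEFAULT_GENOME = dict(chromosomes=[["chr1", 100_000_000], ["chr2", 100_000_000]],
                      snp_count=500, bin_width=5_000_000)


@dataclass
class RunConfig:
    """All knobs of a simulated study plus analysis thresholds."""

    seed: int = 0
    # simulation
    genome: dict = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_strains: int = 96
    n_founders: int = 8
    n_genes: int = 2000
    n_modules: int = 10
    module_size_range: tuple = (40, 120)
    n_markers: int = 9
    theta: float = 0.5
    gamma: float = 3.0
    lambda_range: tuple = (0.6, 0.9)
    noise_sd: float = 1.0
    maf_floor: float = 0.05
    trait_vertex: float = 0.0
    trait_curvature: float = 1.0
    trait_noise_sd: float = 1.0
    celltype_elevation_log2: float = 2.0
    # analysis
    beta: float = None            # None -> scale-free criterion
    r2_target: float = 0.8
    min_module_size: int = 20
    merge_cut: float = 0.25
    n_perm: int = 10_000
    neglogp_threshold: float = 4.0
    overlap_r_threshold: float = 0.25
    region_halfwidth: int = 5_000_000
    knockdown_theta_scale: float = 0.5
    enrich_list_total: int = 57
    enrich_list_from_target: int = 9

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(**self.genome)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class SimulatedStudy:
    genotypes: GenotypeData
    truth: object
    trait: object
    expression: ExpressionMatrix
    celltype: object


def simulate_study(config: RunConfig) -> SimulatedStudy:
    """Generate one complete synthetic study from a config."""
    genome = config.genome_spec()
    genotypes = synth.simulate_genotypes(
        config.n_strains, config.n_founders, genome,
        seed=stage_seed(config.seed, "genotypes"), maf_floor=config.maf_floor)
    truth = synth.make_planted_truth(
        genotypes, genome, seed=stage_seed(config.seed, "truth"),
        n_genes=config.n_genes, n_modules=config.n_modules,
        module_size_range=tuple(config.module_size_range),
        n_markers=config.n_markers, theta=config.theta, gamma=config.gamma,
        lambda_range=tuple(config.lambda_range),
        trait_vertex=config.trait_vertex, trait_curvature=config.trait_curvature,
        trait_noise_sd=config.trait_noise_sd)
    trait = synth.simulate_trait(
        genotypes.strains, vertex=config.trait_vertex,
        curvature=config.trait_curvature, noise_sd=config.trait_noise_sd,
        seed=stage_seed(config.seed, "trait"))
    expression = synth.simulate_expression(
        genotypes, truth, seed=stage_seed(config.seed, "expression"),
        noise_sd=config.noise_sd, target_factor=trait.factor)
    celltype = synth.simulate_celltype_reference(
        truth, seed=stage_seed(config.seed, "celltype"),
        elevation_log2=config.celltype_elevation_log2)
    return SimulatedStudy(genotypes=genotypes, truth=truth, trait=trait,
                          expression=expression, celltype=celltype)


@dataclass
class PipelineResult:
    config: RunConfig
    study: SimulatedStudy
    partition: object
    soft_threshold: object
    tom: pd.DataFrame
    significance: object
    contrast: pd.DataFrame
    kinship: pd.DataFrame
    gwa: pd.DataFrame
    bins: pd.DataFrame
    bin_minima: pd.DataFrame
    hotspot_table: pd.DataFrame
    local_table: pd.DataFrame
    candidates: pd.DataFrame
    quadratic: object
    knockdown: pd.DataFrame
    enrichment: pd.DataFrame
    report: dict


def run_full_pipeline(config: RunConfig, outdir=None,
                      n_perm: int = None) -> PipelineResult:
    """Execute every stage on a freshly simulated study and aggregate a report."""
    n_perm = config.n_perm if n_perm is None else n_perm
    study = simulate_study(config)
    expr, genotypes, truth = study.expression, study.genotypes, study.truth
    genome = config.genome_spec()

    # --- network ---
    cor = netbuild.correlation_matrix(expr)
    soft = netbuild.pick_soft_threshold(cor, r2_target=config.r2_target)
    beta = config.beta if config.beta is not None else soft.beta
    adj = netbuild.adjacency(cor, beta)
    tom = netbuild.tom_similarity(adj)
    part = netbuild.detect_modules(expr, tom, min_module_size=config.min_module_size,
                                   merge_cut=config.merge_cut)

    # --- marker-anchored module significance + cell-type contrast ---
    markers = truth.marker_genes
    marker_eig = modscore.marker_eigengene(expr, markers)
    gs = modscore.gene_significance(expr, marker_eig)
    sig = modscore.module_significance_test(
        gs, part.labels, n_perm=n_perm, seed=stage_seed(config.seed, "modscore"))
    contrast = modscore.celltype_contrast_test(
        part.labels, study.celltype, target_type="osteoblast",
        n_perm=n_perm, seed=stage_seed(config.seed, "modscore") + 1)
    target_module = int(sig.table["MS"].idxmax())
    target_eig = part.eigengenes.loc[target_module]

    # --- mixed-model mapping ---
    K = mixedmodel.kinship_matrix(genotypes)
    gwa = mixedmodel.association_scan(target_eig, genotypes, K,
                                      response_id=f"module{target_module}_eigengene")
    bins = hotspots.bin_genome(genome)
    minima = mixedmodel.eqtl_bin_minima(expr, genotypes, K, bins)

    # --- hotspots ---
    module_mask = part.labels == target_module
    counts = hotspots.hotspot_counts(minima, module_mask,
                                     neglogp_threshold=config.neglogp_threshold)
    hs = hotspots.hotspot_enrichment(counts)
    top_bin = hs["fisher_p"].idxmin()

    # --- causal candidates around the top hotspot ---
    tb = bins.loc[top_bin]
    center = (int(tb.start) + int(tb.end)) // 2
    region = (tb.chr, max(1, center - config.region_halfwidth),
              center + config.region_halfwidth)
    local = mixedmodel.local_eqtl_table(expr, genotypes, K, region)
    region_gwa = gwa[(gwa["chr"].astype(str) == str(region[0]))
                     & (gwa["bp"] >= region[1]) & (gwa["bp"] <= region[2])]
    lead_snp = (region_gwa["p"].idxmin() if len(region_gwa) else gwa["p"].idxmin())
    lead_geno = genotypes.genotypes.loc[lead_snp].to_numpy(dtype=float)
    candidates = causality.rank_candidate_regulators(
        local, expr, part.labels, target_eig, lead_geno, target_module,
        r_threshold=config.overlap_r_threshold)

    # --- trait link ---
    from . import traitlink as tl

    quad = tl.quadratic_association(
        pd.Series(target_eig.to_numpy(), index=expr.strains), study.trait.trait)
    # reference = the genotype group with the lower driver expression, so the
    # panel and knockdown difference vectors share a sign convention
    driver_expr = expr.values.loc[truth.driver_gene].to_numpy()
    ref_group = 1 if driver_expr[lead_geno == 1].mean() < driver_expr[lead_geno == 0].mean() else 0
    hmdp_diff = pd.Series(
        {g: tl.genotype_stratified_percent_diff(expr.values.loc[g], lead_geno,
                                                reference=ref_group)
         for g in expr.probes}, name="hmdp_diff")
    kd_expr = synth.simulate_knockdown(
        genotypes, truth, seed=stage_seed(config.seed, "expression"),
        noise_sd=config.noise_sd, target_factor=study.trait.factor,
        theta_scale=config.knockdown_theta_scale)
    perturb_diff = pd.Series(
        tl.perturbation_percent_diff(kd_expr.values.mean(axis=1).to_numpy(),
                                     expr.values.mean(axis=1).to_numpy()),
        index=expr.probes, name="perturb_diff")
    kd = tl.knockdown_contrast_correlation(hmdp_diff, perturb_diff, part.labels)

    # --- enrichment ---
    gene_list = synth.simulate_gwas_gene_list(
        truth, seed=stage_seed(config.seed, "enrich"),
        n_from_target=config.enrich_list_from_target,
        n_total=config.enrich_list_total)
    # map planted-truth genes onto detected modules via probe identity
    universe = list(expr.probes)
    enr = enrich.module_list_enrichment_table(
        part.labels, gene_list, universe, n_draws=n_perm,
        seed=stage_seed(config.seed, "enrich"))

    report = {
        "seed": config.seed,
        "beta": float(beta),
        "n_modules": int(len(part.module_sizes)),
        "target_module": target_module,
        "target_module_MS": float(sig.table.loc[target_module, "MS"]),
        "target_module_MS_p": float(sig.table.loc[target_module, "p"]),
        "ms_bonferroni_threshold": sig.bonferroni_threshold,
        "top_hotspot_bin": str(top_bin),
        "top_hotspot_fisher_p": float(hs.loc[top_bin, "fisher_p"]),
        "lead_snp": str(lead_snp),
        "lead_snp_p": float(gwa.loc[lead_snp, "p"]),
        "n_candidates": int(len(candidates)),
        "top_candidate": (str(candidates.loc[candidates["top_candidate"], "gene"].iloc[0])
                          if len(candidates) else None),
        "top_candidate_leo_nb": (float(candidates["leo_nb"].max())
                                 if len(candidates) else None),
        "quadratic_p": quad.p_value,
        "quadratic_r2": quad.r_squared,
        "enrichment_min_sampling_p": float(enr["sampling_p"].min()),
        "driver_gene": truth.driver_gene,
        "driver_cis_snp": truth.driver_cis_snp,
    }

    result = PipelineResult(
        config=config, study=study, partition=part, soft_threshold=soft,
        tom=tom, significance=sig, contrast=contrast, kinship=K, gwa=gwa,
        bins=bins, bin_minima=minima, hotspot_table=hs, local_table=local,
        candidates=candidates, quadratic=quad, knockdown=kd, enrichment=enr,
        report=report)
    if outdir is not None:
        write_run(result, outdir)
    return result


def _network_and_target(config: RunConfig, study: SimulatedStudy, n_perm: int):
    """Shared front half of a trial: network, MS test, target module."""
    expr = study.expression
    cor = netbuild.correlation_matrix(expr)
    soft = netbuild.pick_soft_threshold(cor, r2_target=config.r2_target)
    beta = config.beta if config.beta is not None else soft.beta
    adj = netbuild.adjacency(cor, beta)
    tom = netbuild.tom_similarity(adj)
    part = netbuild.detect_modules(expr, tom, min_module_size=config.min_module_size,
                                   merge_cut=config.merge_cut)
    marker_eig = modscore.marker_eigengene(expr, study.truth.marker_genes)
    gs = modscore.gene_significance(expr, marker_eig)
    sig = modscore.module_significance_test(
        gs, part.labels, n_perm=n_perm, seed=stage_seed(config.seed, "modscore"))
    target_module = int(sig.table["MS"].idxmax())
    return part, sig, target_module


def run_recovery_trial(config: RunConfig, n_perm: int = 1000) -> dict:
    """One planted-truth recovery trial: which pipeline stages found the truth.

    Runs the core stages (network, marker-anchored MS, eigengene GWA, hotspot
    enrichment, local-eQTL candidates with LEO.NB, quadratic trait fit) on a
    fresh simulated study and reports per-stage recovery indicators against
    the recorded ground truth.
    """
    study = simulate_study(config)
    expr, genotypes, truth = study.expression, study.genotypes, study.truth
    genome = config.genome_spec()
    part, sig, target_module = _network_and_target(config, study, n_perm)

    planted = truth.module_labels(expr.probes)
    # contingency-based agreement between planted and recovered partitions
    flagged = set(sig.table.index[sig.table["significant"]])
    target_members = set(part.labels[part.labels == target_module].index)
    planted_members = {g for g, m in truth.module_of.items()
                       if m == truth.target_module}
    target_is_planted = (len(target_members & planted_members)
                         > 0.5 * len(planted_members))

    K = mixedmodel.kinship_matrix(genotypes)
    target_eig = part.eigengenes.loc[target_module]
    gwa = mixedmodel.association_scan(target_eig, genotypes, K)
    bins = hotspots.bin_genome(genome)
    minima = mixedmodel.eqtl_bin_minima(expr, genotypes, K, bins)
    counts = hotspots.hotspot_counts(minima, part.labels == target_module,
                                     neglogp_threshold=config.neglogp_threshold)
    hs = hotspots.hotspot_enrichment(counts)
    top_bin = hs["fisher_p"].idxmin()
    cis = genotypes.snp_map.loc[truth.driver_cis_snp]
    tb = bins.loc[top_bin]
    driver_bin_is_top = (str(tb.chr) == str(cis.chr)
                         and tb.start <= cis.bp < tb.end)

    center = (int(tb.start) + int(tb.end)) // 2
    region = (tb.chr, max(1, center - config.region_halfwidth),
              center + config.region_halfwidth)
    local = mixedmodel.local_eqtl_table(expr, genotypes, K, region)
    region_gwa = gwa[(gwa["chr"].astype(str) == str(region[0]))
                     & (gwa["bp"] >= region[1]) & (gwa["bp"] <= region[2])]
    lead_snp = region_gwa["p"].idxmin() if len(region_gwa) else gwa["p"].idxmin()
    lead_geno = genotypes.genotypes.loc[lead_snp].to_numpy(dtype=float)
    candidates = causality.rank_candidate_regulators(
        local, expr, part.labels, target_eig, lead_geno, target_module,
        r_threshold=config.overlap_r_threshold)
    driver_is_top = (len(candidates) > 0
                     and candidates.loc[candidates["top_candidate"], "gene"].iloc[0]
                     == truth.driver_gene)

    from . import traitlink as tl

    quad = tl.quadratic_association(
        pd.Series(target_eig.to_numpy(), index=expr.strains), study.trait.trait)

    from sklearn.metrics import adjusted_rand_score  # test-time metric

    ari = float(adjusted_rand_score(planted.to_numpy(),
                                    part.labels.reindex(expr.probes).to_numpy()))
    return {
        "ari": ari,
        "ms_flags": sorted(flagged),
        "ms_flags_only_target": flagged == {target_module},
        "target_is_planted": bool(target_is_planted),
        "driver_bin_is_top_hotspot": bool(driver_bin_is_top),
        "driver_is_top_candidate": bool(driver_is_top),
        "n_candidates": int(len(candidates)),
        "driver_leo_nb": (float(candidates["leo_nb"].max())
                          if len(candidates) else np.nan),
        "quadratic_p": quad.p_value,
    }


def run_null_quadratic_trial(config: RunConfig, n_perm: int = 200) -> float:
    """Quadratic-fit p-value for a study simulated with curvature = 0."""
    cfg = dataclasses.replace(config, trait_curvature=0.0)
    study = simulate_study(cfg)
    part, sig, target_module = _network_and_target(cfg, study, n_perm)
    from . import traitlink as tl

    quad = tl.quadratic_association(
        pd.Series(part.eigengenes.loc[target_module].to_numpy(),
                  index=study.expression.strains),
        study.trait.trait)
    return quad.p_value


def export_network_edges(tom: pd.DataFrame, labels: pd.Series, module: int,
                         min_tom: float, path) -> int:
    """Write the within-module weighted edge list (gene_a, gene_b, omega >= cut)."""
    genes = list(labels[labels == module].index)
    if not genes:
        raise ValueError(f"module {module} does not exist")
    sub = tom.loc[genes, genes].to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if sub[i, j] >= min_tom:
                rows.append((genes[i], genes[j], sub[i, j]))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom"])
    if df.empty:
        logger.warning("edge threshold %g excludes every edge", min_tom)
    df.to_csv(path, sep="\t", index=False)
    return len(df)


# ---------------------------------------------------------------- I/O helpers

def write_expression_tsv(expr: ExpressionMatrix, values_path, annotation_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="probe_id")
    expr.annotation.to_csv(annotation_path, sep="\t", index_label="probe_id")


def read_expression_tsv(values_path, annotation_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    ann = pd.read_csv(annotation_path, sep="\t", index_col="probe_id")
    return ExpressionMatrix(values=values, annotation=ann)


def write_genotypes_tsv(genotypes: GenotypeData, genotype_path, map_path) -> None:
    genotypes.genotypes.to_csv(genotype_path, sep="\t", index_label="snp_id")
    genotypes.snp_map.to_csv(map_path, sep="\t", index_label="snp_id")


def read_genotypes_tsv(genotype_path, map_path) -> GenotypeData:
    g = pd.read_csv(genotype_path, sep="\t", index_col="snp_id")
    m = pd.read_csv(map_path, sep="\t", index_col="snp_id")
    return GenotypeData(genotypes=g.astype(np.int8), snp_map=m)


def write_vcf(genotypes: GenotypeData, path) -> None:
    """Minimal VCFv4.2 export: homozygous GT fields only (0/0 and 1/1)."""
    strains = genotypes.strains
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in genotypes.snp_map.groupby("chr", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp.bp.max())}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(strains) + "\n")
        G = genotypes.genotypes
        for snp, row in genotypes.snp_map.iterrows():
            gts = "\t".join("1/1" if v else "0/0" for v in G.loc[snp])
            fh.write(f"{row.chr}\t{int(row.bp)}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_run(result: PipelineResult, outdir) -> None:
    """Write every stage artifact of a pipeline run as TSV/JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    st = result.study
    write_expression_tsv(st.expression, out / "expression.tsv", out / "probes.tsv")
    write_genotypes_tsv(st.genotypes, out / "genotypes.tsv", out / "snp_map.tsv")
    st.trait.trait.to_frame().to_csv(out / "trait.tsv", sep="\t", index_label="strain")
    st.truth.to_json(out / "truth.json")
    assign = pd.DataFrame({"module": result.partition.labels})
    assign = assign.join(result.partition.kme.add_prefix("kme_module"))
    assign.to_csv(out / "module_assignment.tsv", sep="\t", index_label="probe_id")
    result.partition.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    result.significance.table.to_csv(out / "module_significance.tsv", sep="\t")
    result.contrast.to_csv(out / "celltype_contrast.tsv", sep="\t")
    result.gwa.to_csv(out / "eigengene_gwa.tsv", sep="\t", index=False)
    result.hotspot_table.to_csv(out / "hotspots.tsv", sep="\t")
    result.local_table.to_csv(out / "local_eqtl.tsv", sep="\t", index=False)
    result.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    result.knockdown.to_csv(out / "knockdown_concordance.tsv", sep="\t")
    result.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1)
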