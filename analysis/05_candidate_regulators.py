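#!/usr/bin/env python
"""Prioritize candidate regulators inside the top hotspot region: local
eQTL table, module-overlap fractions, eigengene correlations and LEO.NB
causal scores against the lead module-QTL SNP. Writes results/candidates/."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (CANDIDATES, MAPPING, SCORES, load_config,  # noqa: E402
                    load_modules, load_study)

from bonenet import causality, hotspots, mixedmodel  # noqa: E402


def main() -> None:
    cfg = load_config()
    expr, geno, *_ = load_study()
    labels, eigengenes = load_modules()
    sig = pd.read_csv(SCORES / "module_significance.tsv", sep="\t",
                      index_col="module")
    target = int(sig["MS"].idxmax())
    hs = pd.read_csv(MAPPING / "hotspots.tsv", sep="\t", index_col="bin")
    gwa = pd.read_csv(MAPPING / "eigengene_gwa.tsv", sep="\t")

    bins = hotspots.bin_genome(cfg.genome_spec())
    tb = bins.loc[hs["fisher_p"].idxmin()]
    center = (int(tb.start) + int(tb.end)) // 2
    region = (tb.chr, max(1, center - cfg.region_halfwidth),
              center + cfg.region_halfwidth)
    K = mixedmodel.kinship_matrix(geno)
    local = mixedmodel.local_eqtl_table(expr, geno, K, region)

    in_region = gwa[(gwa["chr"].astype(str) == str(region[0]))
                    & (gwa["bp"] >= region[1]) & (gwa["bp"] <= region[2])]
    lead = in_region.loc[in_region["p"].idxmin(), "snp"] if len(in_region) \
        else gwa.loc[gwa["p"].idxmin(), "snp"]
    lead_geno = geno.genotypes.loc[lead].to_numpy(dtype=float)
    table = causality.rank_candidate_regulators(
        local, expr, labels, eigengenes.loc[target], lead_geno, target,
        r_threshold=cfg.overlap_r_threshold)

    CANDIDATES.mkdir(parents=True, exist_ok=True)
    local.to_csv(CANDIDATES / "local_eqtl.tsv", sep="\t", index=False)
    table.to_csv(CANDIDATES / "candidates.tsv", sep="\t", index=False)

    print(f"region {region[0]}:{region[1]}-{region[2]} holds "
          f"{local['n_genes_region'].iloc[0] if len(local) else 0} genes, "
          f"{int(local['significant'].sum()) if len(local) else 0} with "
          f"significant local eQTL "
          f"(threshold {local['threshold'].iloc[0]:.3g})" if len(local)
          else "region holds no testable genes")
    if len(table):
        top = table[table["top_candidate"]].iloc[0]
        print(f"top candidate {top['gene']}: eSNP p={top['esnp_p']:.3g}, "
              f"overlap {top['overlap_pct']:.1f}%, ME r={top['me_r']:.2f}, "
              f"LEO.NB={top['leo_nb']:.2f} (lead SNP {lead})")
    print(f"outputs in {CANDIDATES}")


if __name__ == "__main__":
    main()
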