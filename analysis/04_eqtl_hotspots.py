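#!/usr/bin/env python
"""Map genetic drivers of the top-scoring module: mixed-model GWA of its
eigengene, genome-wide eQTL bin minima for all probes, and Fisher
trans-hotspot enrichment. Writes results/mapping/."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import MAPPING, SCORES, load_config, load_modules, load_study  # noqa: E402

from bonenet import hotspots, mixedmodel  # noqa: E402


def main() -> None:
    cfg = load_config()
    expr, geno, *_ = load_study()
    labels, eigengenes = load_modules()
    sig = pd.read_csv(SCORES / "module_significance.tsv", sep="\t",
                      index_col="module")
    target = int(sig["MS"].idxmax())

    K = mixedmodel.kinship_matrix(geno)
    gwa = mixedmodel.association_scan(
        eigengenes.loc[target], geno, K,
        response_id=f"module{target}_eigengene")
    bins = hotspots.bin_genome(cfg.genome_spec())
    minima = mixedmodel.eqtl_bin_minima(expr, geno, K, bins)
    counts = hotspots.hotspot_counts(minima, labels == target,
                                     neglogp_threshold=cfg.neglogp_threshold)
    hs = hotspots.hotspot_enrichment(counts)

    MAPPING.mkdir(parents=True, exist_ok=True)
    gwa.to_csv(MAPPING / "eigengene_gwa.tsv", sep="\t", index=False)
    minima.to_csv(MAPPING / "eqtl_bin_minima.tsv", sep="\t",
                  index_label="probe_id")
    hs.to_csv(MAPPING / "hotspots.tsv", sep="\t")

    lead = gwa.loc[gwa["p"].idxmin()]
    top_bin = hs["fisher_p"].idxmin()
    print(f"module {target} eigengene GWA lead SNP {lead['snp']} "
          f"({lead['chr']}:{int(lead['bp'])}) p={lead['p']:.3g}")
    print(f"top trans-eQTL hotspot {top_bin}: "
          f"{hs.loc[top_bin, 'module_hits']} module hits vs "
          f"{hs.loc[top_bin, 'other_hits']} background, Fisher "
          f"p={hs.loc[top_bin, 'fisher_p']:.3g} "
          f"(threshold {hs['threshold'].iloc[0]:.3g}); "
          f"{int(hs['significant'].sum())} significant bins")
    print(f"outputs in {MAPPING}")


if __name__ == "__main__":
    main()
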