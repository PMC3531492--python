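#!/usr/bin/env python
"""Simulate the study panel: genotypes, expression with planted modules,
a cis-driven driver gene, markers, a cell-type reference and a U-shaped
trait. Writes everything (plus ground truth) under results/data/."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA  # noqa: E402

from bonenet import workflow  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = workflow.RunConfig(seed=args.seed)
    study = workflow.simulate_study(cfg)

    DATA.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(DATA / "config.yaml")
    workflow.write_expression_tsv(study.expression, DATA / "expression.tsv",
                                  DATA / "probes.tsv")
    workflow.write_genotypes_tsv(study.genotypes, DATA / "genotypes.tsv",
                                 DATA / "snp_map.tsv")
    workflow.write_vcf(study.genotypes, DATA / "genotypes.vcf")
    import pandas as pd
    pd.DataFrame({"trait": study.trait.trait,
                  "factor": study.trait.factor}).to_csv(
        DATA / "trait.tsv", sep="\t", index_label="strain")
    study.truth.to_json(DATA / "truth.json")
    study.celltype.values.to_csv(DATA / "celltype_values.tsv", sep="\t")
    study.celltype.samples.to_csv(DATA / "celltype_samples.tsv", sep="\t")

    truth = study.truth
    n_module_genes = sum(1 for m in truth.module_of.values() if m > 0)
    print(f"simulated {len(study.genotypes.strains)} strains, "
          f"{study.expression.values.shape[0]} probes "
          f"({n_module_genes} in {cfg.n_modules} planted modules), "
          f"{study.genotypes.n_snps} SNPs")
    print(f"planted driver {truth.driver_gene} under cis SNP "
          f"{truth.driver_cis_snp} (gamma={truth.gamma}, theta={truth.theta})")
    print(f"trait linked to the module factor with curvature "
          f"{truth.trait_curvature}; outputs in {DATA}")


if __name__ == "__main__":
    main()
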