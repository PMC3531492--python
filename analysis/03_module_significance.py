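#!/usr/bin/env python
"""Score modules against the osteoblast/osteocyte marker-set eigengene
(GS/MS with a resampling null) and against the cell-type reference panel
(max-over-time-points contrast). Writes results/scores/."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCORES, load_config, load_modules, load_study  # noqa: E402

from bonenet import modscore  # noqa: E402
from bonenet.workflow import stage_seed  # noqa: E402


def main() -> None:
    cfg = load_config()
    expr, _, _, truth, reference = load_study()
    labels, _ = load_modules()

    marker_eig = modscore.marker_eigengene(expr, truth.marker_genes)
    gs = modscore.gene_significance(expr, marker_eig)
    sig = modscore.module_significance_test(
        gs, labels, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "modscore"))
    contrast = modscore.celltype_contrast_test(
        labels, reference, target_type="osteoblast", n_perm=cfg.n_perm,
        seed=stage_seed(cfg.seed, "modscore") + 1)

    SCORES.mkdir(parents=True, exist_ok=True)
    gs.to_frame().to_csv(SCORES / "gene_significance.tsv", sep="\t",
                         index_label="probe_id")
    sig.table.to_csv(SCORES / "module_significance.tsv", sep="\t")
    contrast.to_csv(SCORES / "celltype_contrast.tsv", sep="\t")

    top = sig.table["MS"].idxmax()
    flagged = list(sig.table.index[sig.table["significant"]])
    print(f"marker-anchored MS over {len(sig.table)} modules "
          f"(Bonferroni threshold {sig.bonferroni_threshold:.4g})")
    print(f"top module {top}: MS={sig.table.loc[top, 'MS']:.3f}, "
          f"permutation p={sig.table.loc[top, 'p']:.4g}"
          f"{sig.table.loc[top, 'p_annotation'] or ''}; flagged: {flagged}")
    c = contrast.loc[top]
    print(f"module {top} osteoblast contrast {c['mean_log2_diff']:+.2f} log2 "
          f"(p={c['p']:.4g}); outputs in {SCORES}")


if __name__ == "__main__":
    main()
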