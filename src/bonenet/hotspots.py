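"""Trans-eQTL hotspot detection over fixed-width genomic bins.

The genome is tiled into half-open bins (default 5 Mb). For every network
probe the minimum association p-value within each bin is taken (computed by
:func:`bonenet.mixedmodel.eqtl_bin_minima`); probes with -log10 p >= 4 count
as a hit, and each bin's 2x2 table (module hits / module misses vs other
hits / other misses) gets a one-sided Fisher's exact enrichment p-value with
a Bonferroni flag at 0.05 / n_bins. A probe can count in several bins.
SNP-free bins carry no minima and are reported with p = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_NEGLOGP = 4.0


def bin_genome(genome, width_bp: int = None) -> pd.DataFrame:
    """Tile each chromosome into half-open bins of the given width (bp).

    The last bin of a chromosome is truncated at the chromosome end; starts
    are 1-based, intervals are [start, end).
    """
    width = genome.bin_width if width_bp is None else int(width_bp)
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, length in genome.chromosomes:
        n_bins = int(np.ceil(length / width))
        for b in range(n_bins):
            start = b * width + 1
            end = min((b + 1) * width + 1, length + 1)
            rows.append({"chr": chrom, "start": start, "end": end})
    bins = pd.DataFrame(rows)
    bins.index = [f"{r.chr}:{(r.start - 1) // 1_000_000}-{(r.end - 1) / 1e6:g}Mb"
                  for r in bins.itertuples()]
    bins.index.name = "bin"
    return bins


def hotspot_counts(bin_minima: pd.DataFrame, module_mask: pd.Series,
                   neglogp_threshold: float = DEFAULT_NEGLOGP) -> pd.DataFrame:
    """Count strong-eQTL probes per bin, split module vs non-module.

    ``bin_minima`` is probes x bins of minimum p-values; ``module_mask`` is a
    boolean per probe. A probe is a hit in a bin when -log10(min p) exceeds
    or equals the threshold.
    """
    mask = module_mask.reindex(bin_minima.index).fillna(False).astype(bool)
    if mask.sum() == 0:
        raise ValueError("module mask covers zero probes")
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(bin_minima.to_numpy(dtype=float))
    hit = np.nan_to_num(neglogp, nan=-np.inf) >= neglogp_threshold
    m = mask.to_numpy()
    out = pd.DataFrame(index=bin_minima.columns)
    out["module_hits"] = hit[m].sum(axis=0)
    out["other_hits"] = hit[~m].sum(axis=0)
    out["module_total"] = int(m.sum())
    out["other_total"] = int((~m).sum())
    return out


def hotspot_enrichment(counts: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher enrichment p per bin, Bonferroni-flagged.

    The 2x2 table per bin is (module hit, module miss; other hit, other
    miss); degenerate tables (a zero margin) get p = 1.
    """
    n_bins = len(counts)
    threshold = 0.05 / n_bins
    ps = []
    for r in counts.itertuples():
        table = [[r.module_hits, r.module_total - r.module_hits],
                 [r.other_hits, r.other_total - r.other_hits]]
        if r.module_hits + r.other_hits == 0:
            ps.append(1.0)
            continue
        ps.append(float(stats.fisher_exact(table, alternative="greater")[1]))
    out = counts.copy()
    out["fisher_p"] = ps
    out["threshold"] = threshold
    out["significant"] = out["fisher_p"] < threshold
    return out
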