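"""Gene-list enrichment: Fisher's exact overlap and sampling-based nulls.

Two routes for asking whether a module is over-represented in an external
gene list (e.g. mouse homologs of human GWAS hits): the exact one-sided
Fisher test on the 2x2 overlap table, and a resampling Monte-Carlo
scheme that repeatedly draws random gene sets from the network universe and
counts draws whose overlap reaches the observed one. Both follow the same
hypergeometric law; sampling draws the smaller of the two sets for speed
(the overlap distribution is symmetric in which set is drawn).

The choice of universe (all network-input genes vs module-assigned genes)
changes the answer, so it is always an explicit argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    module_size: int
    list_size: int
    universe_size: int
    observed_overlap: int
    p_value: float
    method: str
    n_draws: int = 0
    seed: int = None
    overlap_genes: tuple = ()


def fisher_list_enrichment(module_genes, gene_list, universe) -> EnrichmentResult:
    """One-sided Fisher's exact test for module/list over-representation."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes)
    gene_list = set(gene_list)
    if not module_genes <= universe or not gene_list <= universe:
        raise ValueError("module and list must be subsets of the universe")
    overlap = module_genes & gene_list
    a = len(overlap)
    b = len(module_genes) - a
    c = len(gene_list) - a
    d = len(universe) - a - b - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    return EnrichmentResult(
        module_size=len(module_genes), list_size=len(gene_list),
        universe_size=len(universe), observed_overlap=a, p_value=p,
        method="fisher", overlap_genes=tuple(sorted(overlap)),
    )


def _floyd_sample(rng: np.random.Generator, n: int, k: int) -> set:
    """Uniform k-subset of range(n) without replacement (Floyd's algorithm)."""
    chosen = set()
    for j in range(n - k, n):
        t = int(rng.integers(0, j + 1))
        chosen.add(t if t not in chosen else j)
    return chosen


def sampling_enrichment(module_size: int, universe_size: int, list_size: int,
                        observed_overlap: int, n_draws: int = 10_000,
                        seed: int = 0) -> EnrichmentResult:
    """Monte-Carlo enrichment p by drawing random gene sets from the universe.

    p = fraction of draws whose overlap with the fixed set reaches the
    observed overlap (>=). The smaller of the two sets is drawn; by
    hypergeometric symmetry this matches drawing the larger one.
    """
    small, big = sorted((module_size, list_size))
    if observed_overlap > small:
        raise ValueError("observed overlap exceeds the smaller set")
    if max(module_size, list_size) > universe_size:
        raise ValueError("set sizes exceed the universe")
    if n_draws < 100:
        logger.warning("n_draws=%d is very small for a Monte-Carlo p", n_draws)
    if observed_overlap == 0:
        return EnrichmentResult(module_size=module_size, list_size=list_size,
                                universe_size=universe_size, observed_overlap=0,
                                p_value=1.0, method="sampling",
                                n_draws=n_draws, seed=seed)
    rng = np.random.default_rng(seed)
    # fixed set occupies indices [0, big); draw the small set each round
    count = 0
    for _ in range(n_draws):
        draw = _floyd_sample(rng, universe_size, small)
        overlap = sum(1 for x in draw if x < big)
        if overlap >= observed_overlap:
            count += 1
    return EnrichmentResult(
        module_size=module_size, list_size=list_size,
        universe_size=universe_size, observed_overlap=observed_overlap,
        p_value=count / n_draws, method="sampling", n_draws=n_draws, seed=seed,
    )


def module_list_enrichment_table(labels, gene_list, universe, n_draws: int = 10_000,
                                 seed: int = 0):
    """Fisher and sampling enrichment for every module, Bonferroni-flagged."""
    import pandas as pd

    labels = labels[labels > 0]
    mods = sorted(set(labels))
    threshold = 0.05 / len(mods)
    gene_list = set(gene_list) & set(universe)
    rows = []
    for i, mod in enumerate(mods):
        members = set(labels[labels == mod].index)
        fisher = fisher_list_enrichment(members, gene_list, universe)
        samp = sampling_enrichment(len(members), len(set(universe)), len(gene_list),
                                   fisher.observed_overlap, n_draws=n_draws,
                                   seed=seed + i)
        rows.append({"module": mod, "size": len(members),
                     "overlap": fisher.observed_overlap,
                     "fisher_p": fisher.p_value, "sampling_p": samp.p_value,
                     "significant": samp.p_value < threshold,
                     "overlap_genes": ";".join(fisher.overlap_genes)})
    out = pd.DataFrame(rows).set_index("module")
    out["threshold"] = threshold
    return out
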