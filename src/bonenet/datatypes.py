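"""Shared containers for the bone systems-genetics pipeline.

Conventions: expression matrices are probes x strains (log2 scale), genotype
matrices are SNPs x strains with homozygous codes {0, 1} (inbred panel), and
all genomic coordinates are 1-based base pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomeSpec:
    """A miniature genome: chromosome sizes, SNP counts and the hotspot bin width.

    Parameters
    ----------
    chromosomes : sequence of (name, length_bp)
    snp_count : SNPs per chromosome (single int applied to every chromosome,
        or one int per chromosome).
    bin_width : width of the genomic bins used for trans-eQTL hotspot counting,
        in bp. Default 5 Mb, the standard hotspot bin size for mouse panels.
    """

    chromosomes: tuple
    snp_count: tuple
    bin_width: int = 5_000_000

    def __init__(self, chromosomes: Sequence, snp_count, bin_width: int = 5_000_000):
        chroms = tuple((str(name), int(length)) for name, length in chromosomes)
        if not chroms:
            raise ValueError("genome must have at least one chromosome")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if np.isscalar(snp_count):
            counts = tuple(int(snp_count) for _ in chroms)
        else:
            counts = tuple(int(c) for c in snp_count)
        if len(counts) != len(chroms):
            raise ValueError("snp_count must be scalar or one entry per chromosome")
        if any(c <= 0 for c in counts):
            raise ValueError("snp_count entries must be positive")
        for (name, length), c in zip(chroms, counts):
            if c > length:
                raise ValueError(f"chromosome {name!r}: cannot place {c} SNPs on {length} bp")
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "snp_count", counts)
        object.__setattr__(self, "bin_width", int(bin_width))

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class GenotypeData:
    """SNPs x strains genotype matrix for a fully inbred panel.

    ``genotypes`` is indexed by snp_id with strain columns and values in {0,1};
    ``snp_map`` is indexed by snp_id with columns ``chr`` and ``bp``.
    """

    genotypes: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.snp_map.index):
            raise ValueError("genotypes and snp_map must share the same SNP index")

    @property
    def strains(self) -> list:
        return list(self.genotypes.columns)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class ExpressionMatrix:
    """Probes x strains log2 expression with probe annotation.

    ``annotation`` is indexed by probe_id with columns ``gene``, ``chr``, ``bp``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.annotation.index):
            raise ValueError("expression values and annotation must share the probe index")

    @property
    def strains(self) -> list:
        return list(self.values.columns)

    @property
    def probes(self) -> list:
        return list(self.values.index)


@dataclass
class CellTypeReference:
    """Labeled cell-type reference panel (genes x samples).

    ``samples`` is indexed by sample id with columns ``cell_type``,
    ``time_point`` (empty string when not applicable) and ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("reference columns must match the sample table index")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study, recorded so recovery is testable.

    module_of maps gene -> planted module label (0 = background); loadings map
    module genes to their factor loading lambda in (0, 1] (the gene-factor
    correlation at unit noise). The driver gene sits inside ``target_module``
    under a local eQTL at ``driver_cis_snp`` with allelic effect ``gamma``
    (expression units per allele); ``theta`` in [0,1] is the share of the
    target-module factor carried by the standardized driver expression.
    """

    module_of: dict
    loadings: dict
    driver_gene: str
    driver_cis_snp: str
    gamma: float
    theta: float
    target_module: int
    marker_genes: list
    trait_vertex: float
    trait_curvature: float
    trait_noise_sd: float
    seed: int
    gene_annotation: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.module_of.get(self.driver_gene, 0) != self.target_module:
            raise ValueError("driver gene must belong to the target module")
        member_set = {g for g, m in self.module_of.items() if m == self.target_module}
        if not set(self.marker_genes) <= member_set:
            raise ValueError("marker genes must be a subset of the target module")
        for g, lam in self.loadings.items():
            if not 0.0 < lam <= 1.0:
                raise ValueError(f"loading for {g} outside (0, 1]: {lam}")

    def module_labels(self, probes: Sequence[str]) -> pd.Series:
        return pd.Series([self.module_of.get(p, 0) for p in probes], index=list(probes))

    def to_json(self, path) -> None:
        d = asdict(self)
        d.pop("gene_annotation")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(gene_annotation=None, **d)


@dataclass
class TraitTable:
    """Per-strain quantitative trait plus the module-driving latent factor.

    ``factor`` is the target-module latent factor after the quadratic trait
    augmentation; downstream expression simulation uses it so the planted
    eigengene-trait link is known exactly.
    """

    trait: pd.Series
    factor: np.ndarray
    vertex: float
    curvature: float
    noise_sd: float
    seed: int
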