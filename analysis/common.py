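"""Shared plumbing for the numbered analysis drivers: paths and loaders."""

from pathlib import Path

import pandas as pd

from bonenet import workflow
from bonenet.datatypes import CellTypeReference, PlantedTruth

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
NETWORK = RESULTS / "network"
SCORES = RESULTS / "scores"
MAPPING = RESULTS / "mapping"
CANDIDATES = RESULTS / "candidates"
TRAIT = RESULTS / "trait"
ENRICH = RESULTS / "enrich"


def load_config() -> workflow.RunConfig:
    return workflow.RunConfig.from_yaml(DATA / "config.yaml")


def load_study():
    """Reload every simulated input written by 01_simulate.py."""
    expr = workflow.read_expression_tsv(DATA / "expression.tsv",
                                        DATA / "probes.tsv")
    geno = workflow.read_genotypes_tsv(DATA / "genotypes.tsv",
                                       DATA / "snp_map.tsv")
    trait = pd.read_csv(DATA / "trait.tsv", sep="\t", index_col="strain")
    truth = PlantedTruth.from_json(DATA / "truth.json")
    truth.gene_annotation = expr.annotation
    ref_values = pd.read_csv(DATA / "celltype_values.tsv", sep="\t",
                             index_col=0)
    ref_samples = pd.read_csv(DATA / "celltype_samples.tsv", sep="\t",
                              index_col=0).fillna({"time_point": ""})
    ref_samples["time_point"] = ref_samples["time_point"].astype(str)
    reference = CellTypeReference(values=ref_values, samples=ref_samples)
    return expr, geno, trait, truth, reference


def load_modules():
    assign = pd.read_csv(NETWORK / "module_assignment.tsv", sep="\t",
                         index_col="probe_id")
    labels = assign["module"].astype(int)
    eigengenes = pd.read_csv(NETWORK / "eigengenes.tsv", sep="\t",
                             index_col="module")
    return labels, eigengenes
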