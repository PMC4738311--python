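from __future__ import annotations

import random

import pytest

from orthoppi.cli import run_stage
from orthoppi.config import PipelineConfig
from orthoppi.evidence import IPExperiment, ProteinEvidence
from orthoppi.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """One full default-configuration pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=out)
    summary = run_stage("all", config)
    return config, summary


@pytest.fixture(scope="session")
def small_simulation():
    """A reduced study design for alignment-heavy tests."""
    return SimulationConfig(
        seed=7,
        n_conserved_preys=4,
        n_species_specific_preys=6,
        n_sticky=4,
        n_contaminants=4,
    )


def random_experiments(rng: random.Random, n_per_species=4, n_controls=1):
    """Small random roster with controls, for oracle-equivalence tests."""
    experiments = []
    for sp in ("fly", "human"):
        for i in range(n_per_species):
            experiments.append(
                IPExperiment(
                    experiment_id=f"{sp}_e{i}",
                    species=sp,
                    bait=rng.choice(["baitA", "baitB"]),
                    condition=rng.choice(["basal", "insulin_10", "insulin_30"]),
                    replicate=rng.randint(1, 3),
                )
            )
        for i in range(n_controls):
            experiments.append(
                IPExperiment(
                    experiment_id=f"{sp}_ctrl{i}",
                    species=sp,
                    bait="control",
                    condition="basal",
                    replicate=1,
                    is_control=True,
                )
            )
    return experiments


DESCRIPTION_POOL = [
    "Keratin, type II cytoskeletal 1",
    "Dermcidin",
    "Alpha-S1-casein",
    "Trypsin precursor",
    "Serum albumin",
    "60S ribosomal protein L7",
    "Heat shock protein 83",
    "Actin-5C",
    "Tubulin alpha chain",
    "Activator of 90 kDa heat shock protein ATPase homolog 1",
    "Tyrosine-protein phosphatase non-receptor type 11",
    "Insulin receptor substrate 1",
    "Uncharacterized protein",
    "Splicing factor 1",
    "",
]


def random_evidence(rng: random.Random, experiments, n_accessions=12, density=0.6):
    """Random evidence records over a shared accession pool."""
    accessions = [f"ACC{i:02d}" for i in range(n_accessions)]
    descriptions = {a: rng.choice(DESCRIPTION_POOL) for a in accessions}
    records = []
    for exp in experiments:
        for acc in accessions:
            if rng.random() > density:
                continue
            counts = rng.randint(0, 12)
            peptides = 0 if counts == 0 else rng.randint(1, min(counts, 5))
            records.append(
                ProteinEvidence(
                    experiment_id=exp.experiment_id,
                    accession=acc,
                    unique_peptides=peptides,
                    spectral_counts=counts,
                    description=descriptions[acc],
                )
            )
    return records
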