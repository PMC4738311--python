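"""Synthetic two-species IP-MS study generator with planted ground truth.

Emulates the data a cross-species bait-prey conservation analysis consumes:
two proteome FASTA files, an experiment roster, and per-run spectral-count
evidence tables, together with a :class:`TruthSet` recording exactly which
ortholog pairs and conserved interactors were planted.

The default design mirrors a two-species study: two fly TAP-tagged PI3K
baits (regulatory and catalytic subunit) assayed at basal and 10/30-minute
insulin stimulation with three biological replicates each plus an empty-TAP
control, and sixteen human antibody-IP condition units (cell line x
treatment) with two replicates each plus an IgG control.  Planted content:

* conserved preys — present in both species' IPs; their species-B sequences
  are per-site mutated copies of the species-A sequences at a configured
  identity, so reciprocal-best-hit search can rediscover the pairing.  The
  first two conserved preys are the named analogues of the study's headline
  patterns: one regulatory-bait-preferring and insulin-responsive (the
  SHP2/Csw pattern), one catalytic-bait-preferring and insulin-responsive
  (the IRS1/Chico pattern).
* species-specific preys — real binders with no ortholog counterpart.
* sticky preys — ribosomal/heat-shock/actin/tubulin-named background
  present in every IP including controls.
* contaminants — keratin/casein/trypsin/albumin/dermcidin-named records in
  every run of both species.

Counts are Poisson (or negative-binomial) around the configured means;
unique peptide numbers are drawn as ``min(counts, 1 + Binomial(counts, p))``
so identifications with healthy counts realistically carry >= 2 unique
peptides.  Everything is deterministic under ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evidence import IPExperiment, ProteinEvidence
from .interlog import InterlogRecord
from .orthology import OrthologPair

AA = "ACDEFGHIKLMNPQRSTVWY"

FLY_BAIT_REG = "FREG001"  # fly regulatory-subunit bait (p85 analogue)
FLY_BAIT_CAT = "FCAT001"  # fly catalytic-subunit bait (p110 analogue)
HUMAN_BAIT_P85 = "HREG001"  # human regulatory-subunit antibody bait
HUMAN_P110 = "HCAT001"  # human catalytic subunit, seen as prey of the p85 IPs

FLY_CONDITIONS = ("basal", "insulin_10", "insulin_30")

DEFAULT_HUMAN_CONDITIONS = (
    "serum_H1703",
    "drug:imatinib_H1703",
    "starved_H929",
    "serum_H929",
    "serum_A549",
    "starved_A549",
    "serum_8226",
    "starved_8226",
    "drug:bortezomib_8226",
    "serum_HCC827",
    "drug:gefitinib_HCC827",
    "drug:gefitinib_hgf_HCC827",
    "serum_H1993",
    "drug:pha665752_H1993",
    "serum_EBC1",
    "serum_K562",
)

STICKY_DESCRIPTIONS = (
    "60S ribosomal protein L{i}",
    "40S ribosomal protein S{i}",
    "Heat shock protein 70 cognate {i}",
    "Actin-related protein {i}",
    "Tubulin beta-{i} chain",
)

CONTAMINANT_DESCRIPTIONS = (
    "Keratin, type II cytoskeletal {i}",
    "Dermcidin isoform {i}",
    "Alpha-S{i}-casein",
    "Trypsin precursor variant {i}",
    "Serum albumin fragment {i}",
)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generator."""

    seed: int = 1
    n_conserved_preys: int = 12
    n_species_specific_preys: int = 30  # total, split evenly between species
    n_sticky: int = 20  # total, split evenly between species
    n_contaminants: int = 15  # entities observed in every run of both species
    ortholog_identity: float = 0.85
    min_length: int = 150
    max_length: int = 600
    baseline_abundance: float = 30.0
    bait_abundance: float = 80.0
    background_rate: float = 5.0
    preference_factor: float = 8.0  # enrichment of a prey on its preferred bait
    stimulation_fold: float = 3.0  # insulin response of the two named analogues
    stimulation_effects: dict[str, float] = field(default_factory=dict)
    count_model: str = "poisson"  # or "negative_binomial"
    dispersion: float = 2.0  # NB size parameter (smaller = more overdispersed)
    peptide_prob: float = 0.25  # per-spectrum chance of a new unique peptide
    fly_replicates: int = 3
    human_replicates: int = 2
    human_conditions: tuple[str, ...] = DEFAULT_HUMAN_CONDITIONS
    curated_fraction: float = 0.5  # share of planted pairs listed as curated

    def __post_init__(self) -> None:
        if not (0 < self.ortholog_identity <= 1):
            raise ValueError("ortholog_identity must be in (0, 1]")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if not self.stimulation_effects:
            # the two named analogues respond to insulin; other preys do not
            self.stimulation_effects = {
                self.regulatory_preferring_prey: self.stimulation_fold,
                self.catalytic_preferring_prey: self.stimulation_fold,
            }

    @property
    def regulatory_preferring_prey(self) -> str:
        """Fly accession of the planted SHP2/Csw-like prey."""
        return "FCON01"

    @property
    def catalytic_preferring_prey(self) -> str:
        """Fly accession of the planted IRS1/Chico-like prey."""
        return "FCON02"


@dataclass
class TruthSet:
    """Planted ground truth for scoring pipeline recovery."""

    ortholog_pairs: list[tuple[str, str]]
    conserved_pairs: set[tuple[str, str]]
    curated_pairs: list[tuple[str, str]]
    bait_preference: dict[str, str]  # fly prey accession -> {regulatory, catalytic}
    stimulation_folds: dict[str, float]  # fly prey accession -> insulin fold
    fly_descriptions: dict[str, str]
    human_descriptions: dict[str, str]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, sequence: str, identity: float) -> str:
    """Per-site substitution to a random different residue at rate 1-identity."""
    out = []
    for residue in sequence:
        if rng.random() < identity:
            out.append(residue)
        else:
            choices = AA.replace(residue, "")
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _split(total: int) -> tuple[int, int]:
    return (total - total // 2, total // 2)


def _planted_accessions(config: SimulationConfig) -> dict[str, list[str]]:
    n_fly_spec, n_human_spec = _split(config.n_species_specific_preys)
    n_fly_sticky, n_human_sticky = _split(config.n_sticky)
    return {
        "conserved_fly": [f"FCON{i:02d}" for i in range(1, config.n_conserved_preys + 1)],
        "conserved_human": [f"HCON{i:02d}" for i in range(1, config.n_conserved_preys + 1)],
        "specific_fly": [f"FSPE{i:02d}" for i in range(1, n_fly_spec + 1)],
        "specific_human": [f"HSPE{i:02d}" for i in range(1, n_human_spec + 1)],
        "sticky_fly": [f"FSTK{i:02d}" for i in range(1, n_fly_sticky + 1)],
        "sticky_human": [f"HSTK{i:02d}" for i in range(1, n_human_sticky + 1)],
        "contaminant_fly": [f"FCTM{i:02d}" for i in range(1, config.n_contaminants + 1)],
        "contaminant_human": [f"HCTM{i:02d}" for i in range(1, config.n_contaminants + 1)],
    }


def generate_proteomes(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Generate fly and human proteomes plus the planted truth.

    Fly sequences are random amino-acid strings; each planted ortholog's
    human counterpart is a per-site mutated copy at
    ``config.ortholog_identity``; all other human sequences are independent
    random decoys.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    acc = _planted_accessions(config)

    def lengths(n: int) -> list[int]:
        return list(rng.integers(config.min_length, config.max_length + 1, size=n))

    fly: dict[str, str] = {}
    human: dict[str, str] = {}
    fly_desc: dict[str, str] = {}
    human_desc: dict[str, str] = {}

    # baits: fly pair + human orthologs (regulatory = antibody bait, catalytic
    # = heterodimer partner detected as prey of the regulatory IPs)
    for fly_acc, human_acc, desc in (
        (FLY_BAIT_REG, HUMAN_BAIT_P85, "Phosphoinositide 3-kinase regulatory subunit (bait)"),
        (FLY_BAIT_CAT, HUMAN_P110, "Phosphoinositide 3-kinase catalytic subunit"),
    ):
        seq = _random_protein(rng, int(rng.integers(config.min_length, config.max_length + 1)))
        fly[fly_acc] = seq
        human[human_acc] = _mutate(rng, seq, config.ortholog_identity)
        fly_desc[fly_acc] = desc
        human_desc[human_acc] = desc

    conserved_names = {
        config.regulatory_preferring_prey: "Tyrosine phosphatase, regulatory-subunit-associated",
        config.catalytic_preferring_prey: "Insulin receptor substrate homolog",
    }
    for i, (facc, hacc) in enumerate(zip(acc["conserved_fly"], acc["conserved_human"])):
        seq = _random_protein(rng, int(rng.integers(config.min_length, config.max_length + 1)))
        fly[facc] = seq
        human[hacc] = _mutate(rng, seq, config.ortholog_identity)
        name = conserved_names.get(facc, f"Conserved interactor {i + 1:02d}")
        fly_desc[facc] = name
        human_desc[hacc] = name

    for group, desc_fmt, target, descs in (
        ("specific_fly", "Fly-specific interactor {i:02d}", fly, fly_desc),
        ("specific_human", "Human-specific interactor {i:02d}", human, human_desc),
    ):
        for i, accession in enumerate(acc[group], start=1):
            target[accession] = _random_protein(
                rng, int(rng.integers(config.min_length, config.max_length + 1))
            )
            descs[accession] = desc_fmt.format(i=i)

    for group, target, descs in (
        ("sticky_fly", fly, fly_desc),
        ("sticky_human", human, human_desc),
    ):
        for i, accession in enumerate(acc[group], start=1):
            target[accession] = _random_protein(
                rng, int(rng.integers(config.min_length, config.max_length + 1))
            )
            descs[accession] = STICKY_DESCRIPTIONS[(i - 1) % len(STICKY_DESCRIPTIONS)].format(i=i)

    for i, (facc, hacc) in enumerate(
        zip(acc["contaminant_fly"], acc["contaminant_human"]), start=1
    ):
        desc = CONTAMINANT_DESCRIPTIONS[(i - 1) % len(CONTAMINANT_DESCRIPTIONS)].format(i=i)
        fly[facc] = _random_protein(rng, int(rng.integers(config.min_length, config.max_length + 1)))
        human[hacc] = _random_protein(rng, int(rng.integers(config.min_length, config.max_length + 1)))
        fly_desc[facc] = desc
        human_desc[hacc] = desc

    ortholog_pairs = [
        (FLY_BAIT_REG, HUMAN_BAIT_P85),
        (FLY_BAIT_CAT, HUMAN_P110),
    ] + list(zip(acc["conserved_fly"], acc["conserved_human"]))
    conserved_pairs = set(ortholog_pairs)  # every planted pair is detectable
    n_curated = round(config.curated_fraction * len(ortholog_pairs))
    curated_pairs = sorted(ortholog_pairs)[:n_curated]

    preference = {facc: "none" for facc in acc["conserved_fly"]}
    preference[config.regulatory_preferring_prey] = "regulatory"
    preference[config.catalytic_preferring_prey] = "catalytic"

    truth = TruthSet(
        ortholog_pairs=ortholog_pairs,
        conserved_pairs=conserved_pairs,
        curated_pairs=curated_pairs,
        bait_preference=preference,
        stimulation_folds=dict(config.stimulation_effects),
        fly_descriptions=fly_desc,
        human_descriptions=human_desc,
    )
    return fly, human, truth


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for accession in sequences:
            handle.write(f">{accession}\n")
            seq = sequences[accession]
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def build_design(config: SimulationConfig) -> list[IPExperiment]:
    """The experiment roster implied by the configuration."""
    experiments = []
    for bait in (FLY_BAIT_REG, FLY_BAIT_CAT):
        for condition in FLY_CONDITIONS:
            for rep in range(1, config.fly_replicates + 1):
                experiments.append(
                    IPExperiment(
                        experiment_id=f"fly_{bait}_{condition}_r{rep}",
                        species="fly",
                        bait=bait,
                        condition=condition,
                        replicate=rep,
                    )
                )
    for rep in range(1, config.fly_replicates + 1):
        experiments.append(
            IPExperiment(
                experiment_id=f"fly_emptyTAP_r{rep}",
                species="fly",
                bait="control",
                condition="basal",
                replicate=rep,
                is_control=True,
            )
        )
    for condition in config.human_conditions:
        for rep in range(1, config.human_replicates + 1):
            experiments.append(
                IPExperiment(
                    experiment_id=f"human_{HUMAN_BAIT_P85}_{condition}_r{rep}",
                    species="human",
                    bait=HUMAN_BAIT_P85,
                    condition=condition,
                    replicate=rep,
                )
            )
    for rep in range(1, config.human_replicates + 1):
        experiments.append(
            IPExperiment(
                experiment_id=f"human_IgG_r{rep}",
                species="human",
                bait="control",
                condition="serum_H929",
                replicate=rep,
                is_control=True,
            )
        )
    return experiments


def _draw_counts(rng: np.random.Generator, config: SimulationConfig, mean: float) -> int:
    if mean <= 0:
        return 0
    if config.count_model == "poisson":
        return int(rng.poisson(mean))
    r = config.dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def _draw_peptides(rng: np.random.Generator, config: SimulationConfig, counts: int) -> int:
    if counts == 0:
        return 0
    return int(min(counts, 1 + rng.binomial(counts, config.peptide_prob)))


def _prey_means_fly(
    config: SimulationConfig, bait: str, condition: str, acc: dict[str, list[str]]
) -> dict[str, float]:
    means: dict[str, float] = {bait: config.bait_abundance}
    # heterodimer partner co-purifies
    partner = FLY_BAIT_CAT if bait == FLY_BAIT_REG else FLY_BAIT_REG
    means[partner] = config.baseline_abundance
    insulin = condition.startswith("insulin")
    for i, facc in enumerate(acc["conserved_fly"]):
        mean = config.baseline_abundance
        pref = "none"
        if facc == config.regulatory_preferring_prey:
            pref = "regulatory"
        elif facc == config.catalytic_preferring_prey:
            pref = "catalytic"
        if pref == "regulatory" and bait == FLY_BAIT_CAT:
            mean /= config.preference_factor
        elif pref == "catalytic" and bait == FLY_BAIT_REG:
            mean /= config.preference_factor
        if insulin:
            mean *= config.stimulation_effects.get(facc, 1.0)
        means[facc] = mean
    # species-specific preys alternate between the two baits
    for i, facc in enumerate(acc["specific_fly"]):
        if (i % 2 == 0) == (bait == FLY_BAIT_REG):
            means[facc] = config.baseline_abundance
    for facc in acc["sticky_fly"]:
        means[facc] = config.background_rate
    for facc in acc["contaminant_fly"]:
        means[facc] = config.background_rate
    return means


def _prey_means_human(
    config: SimulationConfig, acc: dict[str, list[str]]
) -> dict[str, float]:
    means: dict[str, float] = {
        HUMAN_BAIT_P85: config.bait_abundance,
        HUMAN_P110: config.baseline_abundance,
    }
    for hacc in acc["conserved_human"]:
        means[hacc] = config.baseline_abundance
    for hacc in acc["specific_human"]:
        means[hacc] = config.baseline_abundance
    for hacc in acc["sticky_human"]:
        means[hacc] = config.background_rate
    for hacc in acc["contaminant_human"]:
        means[hacc] = config.background_rate
    return means


def simulate_ipms(
    config: SimulationConfig, truth: TruthSet
) -> tuple[list[IPExperiment], list[ProteinEvidence]]:
    """Draw per-run spectral-count evidence for the whole study design."""
    rng = np.random.default_rng([config.seed, 1])
    acc = _planted_accessions(config)
    experiments = build_design(config)
    descriptions = {**truth.fly_descriptions, **truth.human_descriptions}

    evidence: list[ProteinEvidence] = []
    for exp in experiments:
        if exp.is_control:
            groups = ("sticky_fly", "contaminant_fly") if exp.species == "fly" else (
                "sticky_human",
                "contaminant_human",
            )
            means = {a: config.background_rate for g in groups for a in acc[g]}
        elif exp.species == "fly":
            means = _prey_means_fly(config, exp.bait, exp.condition, acc)
        else:
            means = _prey_means_human(config, acc)
        for accession, mean in means.items():
            counts = _draw_counts(rng, config, mean)
            if counts == 0:
                continue
            evidence.append(
                ProteinEvidence(
                    experiment_id=exp.experiment_id,
                    accession=accession,
                    unique_peptides=_draw_peptides(rng, config, counts),
                    spectral_counts=counts,
                    description=descriptions.get(accession, ""),
                )
            )
    return experiments, evidence


def write_truth(truth: TruthSet, path: str | Path) -> None:
    """Serialize the planted truth as a TSV of ortholog pairs with attributes."""
    rows = []
    for facc, hacc in sorted(truth.ortholog_pairs):
        rows.append(
            (
                facc,
                hacc,
                (facc, hacc) in truth.conserved_pairs,
                (facc, hacc) in set(truth.curated_pairs),
                truth.bait_preference.get(facc, "none"),
                truth.stimulation_folds.get(facc, 1.0),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "fly_accession",
            "human_accession",
            "conserved",
            "curated",
            "bait_preference",
            "stimulation_fold",
        ],
    ).to_csv(path, sep="\t", index=False)


def curated_pair_frame(truth: TruthSet) -> pd.DataFrame:
    return pd.DataFrame(truth.curated_pairs, columns=["fly_accession", "human_accession"])


def score_recovery(
    recovered: Sequence[InterlogRecord] | Sequence[tuple[str, str]],
    truth: TruthSet,
) -> tuple[float, float]:
    """Precision and recall of a recovered conserved-pair set vs the truth.

    Accepts interlog records or bare (fly, human) tuples.  An empty truth
    set gives recall 1.0; an empty recovered set gives precision 1.0
    (nothing asserted, nothing wrong).
    """
    pairs = {
        r.key if isinstance(r, InterlogRecord) else tuple(r) for r in recovered
    }
    true_pairs = set(truth.conserved_pairs)
    tp = len(pairs & true_pairs)
    precision = tp / len(pairs) if pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall
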