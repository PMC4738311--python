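"""IP-MS identification evidence: data model, TSV I/O and the filtering cascade.

An affinity-purification / immunoprecipitation mass-spectrometry (IP-MS)
experiment pulls down a tagged or antibody-targeted *bait* protein together
with its co-purifying *preys*.  Database search of the resulting spectra
yields, per run, a table of identified proteins with their spectral counts
(number of peptide-spectrum matches, a label-free abundance proxy) and the
number of unique peptides supporting each identification.

This module holds the downstream filtering cascade applied to such tables
before any cross-species comparison:

1. ``remove_contaminants`` — drop ubiquitous sample-handling contaminants
   (keratins, dermcidin, caseins, trypsin, serum albumin) by accession
   blocklist and case-insensitive description matching.
2. ``subtract_controls`` — drop, per species, every accession observed in a
   negative-control IP (empty-TAP or IgG pull-down).
3. ``apply_identification_policy`` — accept a protein only with at least
   ``min_counts_per_experiment`` spectral counts (and, for human data,
   ``min_unique_peptides`` unique peptides) in at least the required number
   of experiment-condition units per species.
4. ``remove_sticky`` — drop promiscuous prey categories (ribosomal proteins,
   heat-shock proteins, actin, tubulin) that co-purify in most pull-downs
   without belonging to the core complex.

Steps 1 and 2 are pure set subtractions and commute; step 3 depends on both
having run first (a contaminant present at high counts would otherwise be
accepted); step 4 acts on the accepted accession sets.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("fly", "human")

EXPERIMENT_COLUMNS = [
    "experiment_id",
    "species",
    "bait",
    "condition",
    "replicate",
    "is_control",
]
EVIDENCE_COLUMNS = [
    "experiment_id",
    "accession",
    "unique_peptides",
    "spectral_counts",
    "description",
]

DEFAULT_CONTAMINANT_PATTERNS = (
    "keratin",
    "dermcidin",
    "dermicidin",
    "casein",
    "trypsin",
    "serum albumin",
)
DEFAULT_STICKY_PATTERNS = (
    "ribosomal protein",
    "heat shock",
    "heat-shock",
    "actin",
    "tubulin",
)
# Descriptions that contain a sticky category word but denote a distinct
# protein and are kept (e.g. AHSA1, an activator OF Hsp90, not a chaperone).
DEFAULT_STICKY_EXEMPTIONS = ("heat shock protein atpase",)


class EvidenceFormatError(ValueError):
    """Raised for malformed evidence/experiment tables (missing columns...)."""


class EvidenceValidationError(ValueError):
    """Raised for well-formed tables whose values violate an invariant."""


@dataclass(frozen=True)
class IPExperiment:
    """Metadata for one immunoprecipitation run.

    ``replicate`` distinguishes biological replicates of the same
    (species, bait, condition) unit; the identification policy counts
    units, not replicate runs.
    """

    experiment_id: str
    species: str
    bait: str
    condition: str
    replicate: int = 1
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise EvidenceValidationError(
                f"experiment {self.experiment_id!r}: species must be one of "
                f"{SPECIES}, got {self.species!r}"
            )
        if self.replicate < 1:
            raise EvidenceValidationError(
                f"experiment {self.experiment_id!r}: replicate must be >= 1"
            )
        if self.is_control and self.bait != "control":
            raise EvidenceValidationError(
                f"experiment {self.experiment_id!r}: control IPs must have "
                f'bait="control", got {self.bait!r}'
            )

    @property
    def unit(self) -> tuple[str, str, str]:
        """The experiment-condition unit this run replicates."""
        return (self.species, self.bait, self.condition)


@dataclass(frozen=True)
class ProteinEvidence:
    """One protein's identification evidence within one run."""

    experiment_id: str
    accession: str
    unique_peptides: int
    spectral_counts: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.unique_peptides < 0 or self.spectral_counts < 0:
            raise EvidenceValidationError(
                f"{self.experiment_id}/{self.accession}: negative counts"
            )
        if self.unique_peptides > 0 and self.spectral_counts < self.unique_peptides:
            raise EvidenceValidationError(
                f"{self.experiment_id}/{self.accession}: spectral_counts "
                f"({self.spectral_counts}) < unique_peptides "
                f"({self.unique_peptides})"
            )


@dataclass
class FilterPolicy:
    """Thresholds and pattern lists for the full evidence cascade."""

    min_counts_per_experiment: int = 3
    min_unique_peptides: int = 2
    min_supporting_experiments_human: int = 2
    min_supporting_experiments_fly: int = 1
    contaminant_accessions: set[str] = field(default_factory=set)
    contaminant_name_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_CONTAMINANT_PATTERNS)
    )
    sticky_name_patterns: list[str] = field(
        default_factory=lambda: list(DEFAULT_STICKY_PATTERNS)
    )
    sticky_exemptions: list[str] = field(
        default_factory=lambda: list(DEFAULT_STICKY_EXEMPTIONS)
    )

    def __post_init__(self) -> None:
        for name in (
            "min_counts_per_experiment",
            "min_unique_peptides",
            "min_supporting_experiments_human",
            "min_supporting_experiments_fly",
        ):
            if getattr(self, name) < 0:
                raise EvidenceValidationError(f"FilterPolicy.{name} must be >= 0")

    def min_supporting_experiments(self, species: str) -> int:
        if species == "human":
            return self.min_supporting_experiments_human
        return self.min_supporting_experiments_fly

    def with_updates(self, **kwargs) -> "FilterPolicy":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# I/O


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise EvidenceFormatError(f"cannot parse boolean value {value!r}")


def read_experiments(path: str | Path) -> list[IPExperiment]:
    """Read the experiment roster from a tab-separated table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceFormatError(
            f"{path}: experiment table missing column(s) {missing}"
        )
    experiments = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.experiment_id in seen:
            raise EvidenceValidationError(
                f"{path}: duplicate experiment_id {row.experiment_id!r}"
            )
        seen.add(row.experiment_id)
        experiments.append(
            IPExperiment(
                experiment_id=row.experiment_id,
                species=row.species,
                bait=row.bait,
                condition=row.condition,
                replicate=int(row.replicate),
                is_control=_parse_bool(row.is_control),
            )
        )
    return experiments


def read_evidence(
    path: str | Path, experiment_table: str | Path
) -> tuple[list[IPExperiment], list[ProteinEvidence]]:
    """Read experiment and evidence tables, validating cross-references.

    Rows referencing an experiment_id absent from the roster are rejected
    with a validation error; negative counts are reported with their
    1-based data row number.
    """
    experiments = read_experiments(experiment_table)
    known = {e.experiment_id for e in experiments}

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceFormatError(f"{path}: evidence table missing column(s) {missing}")

    evidence: list[ProteinEvidence] = []
    seen_keys: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            peptides = int(row.unique_peptides)
            counts = int(row.spectral_counts)
        except ValueError as exc:
            raise EvidenceValidationError(f"{path}: row {i}: {exc}") from exc
        if peptides < 0 or counts < 0:
            raise EvidenceValidationError(
                f"{path}: row {i}: negative count ({row.experiment_id}/"
                f"{row.accession})"
            )
        if row.experiment_id not in known:
            raise EvidenceValidationError(
                f"{path}: row {i}: unknown experiment_id {row.experiment_id!r}"
            )
        key = (row.experiment_id, row.accession)
        if key in seen_keys:
            raise EvidenceValidationError(f"{path}: row {i}: duplicate record {key}")
        seen_keys.add(key)
        try:
            evidence.append(
                ProteinEvidence(
                    experiment_id=row.experiment_id,
                    accession=row.accession,
                    unique_peptides=peptides,
                    spectral_counts=counts,
                    description=row.description,
                )
            )
        except EvidenceValidationError as exc:
            raise EvidenceValidationError(f"{path}: row {i}: {exc}") from exc
    return experiments, evidence


def write_experiments(experiments: Sequence[IPExperiment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.experiment_id, e.species, e.bait, e.condition, e.replicate, e.is_control)
            for e in experiments
        ],
        columns=EXPERIMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_evidence(evidence: Sequence[ProteinEvidence], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.experiment_id, r.accession, r.unique_peptides, r.spectral_counts, r.description)
            for r in evidence
        ],
        columns=EVIDENCE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering cascade


def _matches_any(description: str, patterns: Iterable[str]) -> bool:
    text = description.lower()
    return any(p.lower() in text for p in patterns)


def remove_contaminants(
    evidence: Sequence[ProteinEvidence], policy: FilterPolicy
) -> list[ProteinEvidence]:
    """Drop records for common sample-handling contaminants.

    A record is removed if its accession is blocklisted or its description
    contains (case-insensitively) any contaminant name pattern.
    """
    kept = []
    for record in evidence:
        if record.accession in policy.contaminant_accessions:
            logger.debug("contaminant (accession): %s", record.accession)
            continue
        if _matches_any(record.description, policy.contaminant_name_patterns):
            logger.debug(
                "contaminant (pattern): %s %r", record.accession, record.description
            )
            continue
        kept.append(record)
    return kept


def subtract_controls(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    mode: str = "accession",
    sticky_patterns: Sequence[str] | None = None,
) -> list[ProteinEvidence]:
    """Remove everything observed in a negative-control IP, per species.

    Any accession with at least one spectral count in any control run of
    species S is removed from all of S's non-control evidence; the control
    runs' own records are removed as well.  ``mode="accession"`` (default)
    subtracts exact accessions; ``mode="category"`` additionally removes
    records whose description matches a category pattern seen in a control
    (``sticky_patterns`` supplies the category vocabulary).
    """
    if mode not in ("accession", "category"):
        raise ValueError(f"unknown control subtraction mode {mode!r}")
    species_of = {e.experiment_id: e.species for e in experiments}
    control_ids = {e.experiment_id for e in experiments if e.is_control}

    observed: dict[str, set[str]] = defaultdict(set)  # species -> accessions
    control_descriptions: dict[str, list[str]] = defaultdict(list)
    for record in evidence:
        if record.experiment_id in control_ids and record.spectral_counts >= 1:
            sp = species_of[record.experiment_id]
            observed[sp].add(record.accession)
            control_descriptions[sp].append(record.description)

    patterns = list(sticky_patterns or [])
    kept = []
    for record in evidence:
        if record.experiment_id in control_ids:
            continue
        sp = species_of.get(record.experiment_id)
        if sp is not None and record.accession in observed[sp]:
            logger.debug("control subtraction: %s (%s)", record.accession, sp)
            continue
        if mode == "category" and sp is not None:
            control_hit_categories = [
                p
                for p in patterns
                if any(p.lower() in d.lower() for d in control_descriptions[sp])
            ]
            if _matches_any(record.description, control_hit_categories):
                logger.debug(
                    "control subtraction (category): %s (%s)", record.accession, sp
                )
                continue
        kept.append(record)
    return kept


def supporting_units(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: FilterPolicy,
) -> dict[str, dict[str, set[tuple[str, str, str]]]]:
    """Map species -> accession -> experiment-condition units with support.

    A unit (species, bait, condition) supports an accession when at least
    one of its replicate runs individually meets the per-run thresholds:
    spectral_counts >= min_counts_per_experiment and (for human data)
    unique_peptides >= min_unique_peptides.
    """
    by_id = {e.experiment_id: e for e in experiments}
    support: dict[str, dict[str, set]] = {sp: defaultdict(set) for sp in SPECIES}
    for record in evidence:
        exp = by_id.get(record.experiment_id)
        if exp is None or exp.is_control:
            continue
        if record.spectral_counts < policy.min_counts_per_experiment:
            continue
        if exp.species == "human" and record.unique_peptides < policy.min_unique_peptides:
            continue
        support[exp.species][record.accession].add(exp.unit)
    return support


def apply_identification_policy(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: FilterPolicy,
) -> dict[str, set[str]]:
    """Accept accessions with enough supporting experiment-condition units.

    Human accessions need >= ``min_supporting_experiments_human`` units each
    meeting both the spectral-count and unique-peptide thresholds; fly
    accessions need >= ``min_supporting_experiments_fly`` units meeting the
    spectral-count threshold.  Returns ``{"fly": set, "human": set}``.
    """
    for sp in SPECIES:
        if not any(e.species == sp and not e.is_control for e in experiments):
            logger.warning("no non-control %s experiments; %s set will be empty", sp, sp)
    support = supporting_units(evidence, experiments, policy)
    accepted: dict[str, set[str]] = {}
    for sp in SPECIES:
        needed = policy.min_supporting_experiments(sp)
        accepted[sp] = {
            acc for acc, units in support[sp].items() if len(units) >= needed
        }
    return accepted


def remove_sticky(
    accepted: set[str],
    evidence: Sequence[ProteinEvidence],
    policy: FilterPolicy,
) -> set[str]:
    """Drop promiscuous prey categories from an accepted accession set.

    An accession is removed when any of its descriptions matches a sticky
    pattern, unless it also matches an exemption phrase (proteins merely
    named after a sticky category, e.g. Hsp90 co-chaperone activators).
    """
    descriptions: dict[str, list[str]] = defaultdict(list)
    for record in evidence:
        descriptions[record.accession].append(record.description)

    kept = set()
    for accession in accepted:
        descs = descriptions.get(accession, [])
        exempt = any(_matches_any(d, policy.sticky_exemptions) for d in descs)
        sticky = any(_matches_any(d, policy.sticky_name_patterns) for d in descs)
        if sticky and not exempt:
            logger.debug("sticky removal: %s", accession)
            continue
        kept.add(accession)
    return kept


def run_cascade(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: FilterPolicy,
    control_mode: str = "accession",
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Run the full cascade; return accepted sets and checkpoint counts.

    Checkpoints record the number of distinct non-control accessions after
    each stage, mirroring the candidate counts a pipeline audit reports.
    """
    def n_accessions(records: Sequence[ProteinEvidence]) -> int:
        controls = {e.experiment_id for e in experiments if e.is_control}
        return len(
            {r.accession for r in records if r.experiment_id not in controls}
        )

    checkpoints = {"input_accessions": n_accessions(evidence)}
    step1 = remove_contaminants(evidence, policy)
    checkpoints["post_contaminant"] = n_accessions(step1)
    step2 = subtract_controls(
        step1, experiments, mode=control_mode, sticky_patterns=policy.sticky_name_patterns
    )
    checkpoints["post_control"] = n_accessions(step2)
    accepted = apply_identification_policy(step2, experiments, policy)
    checkpoints["accepted_fly"] = len(accepted["fly"])
    checkpoints["accepted_human"] = len(accepted["human"])
    final = {
        sp: remove_sticky(accepted[sp], step2, policy) for sp in SPECIES
    }
    checkpoints["post_sticky_fly"] = len(final["fly"])
    checkpoints["post_sticky_human"] = len(final["human"])
    return final, checkpoints
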