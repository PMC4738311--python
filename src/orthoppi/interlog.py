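"""Conserved-interactor (interlog) analysis.

An *interlog* is a conserved interaction: a bait-prey association observed
in one species whose ortholog pair is also observed interacting in the
other.  Here the overlap is taken downstream of the full evidence cascade:
an ortholog pair (fly a, human b) becomes an interlog record when a is in
the accepted fly interactor set and b is in the accepted human set, each
having met the per-experiment identification thresholds in the required
number of experiments.

The package also ships a reference table of 49 fly/human conserved PI3K
interactor pairs (``load_reference_conserved_pairs``) used as a desk-scale
fixture for the table format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evidence import FilterPolicy, IPExperiment, ProteinEvidence
from .orthology import OrthologPair

CONSERVED_COLUMNS = [
    "fly_accession",
    "human_accession",
    "source",
    "n_fly_experiments",
    "n_human_experiments",
    "fly_experiments",
    "human_experiments",
]


@dataclass(frozen=True)
class InterlogRecord:
    """One conserved interactor: an ortholog pair plus per-species support."""

    fly_accession: str
    human_accession: str
    supporting_fly_experiments: tuple[str, ...]
    supporting_human_experiments: tuple[str, ...]
    source: str = "curated"

    def __post_init__(self) -> None:
        if not self.supporting_fly_experiments or not self.supporting_human_experiments:
            raise ValueError(
                f"interlog ({self.fly_accession}, {self.human_accession}): "
                "support lists must be non-empty"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.fly_accession, self.human_accession)


def _supporting_runs(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: FilterPolicy,
) -> dict[tuple[str, str], list[str]]:
    """(species, accession) -> sorted run ids meeting the per-run thresholds."""
    by_id = {e.experiment_id: e for e in experiments}
    runs: dict[tuple[str, str], set[str]] = {}
    for record in evidence:
        exp = by_id.get(record.experiment_id)
        if exp is None or exp.is_control:
            continue
        if record.spectral_counts < policy.min_counts_per_experiment:
            continue
        if exp.species == "human" and record.unique_peptides < policy.min_unique_peptides:
            continue
        runs.setdefault((exp.species, record.accession), set()).add(exp.experiment_id)
    return {key: sorted(ids) for key, ids in runs.items()}


def compute_interlogs(
    accepted_fly: set[str],
    accepted_human: set[str],
    pairs: Sequence[OrthologPair],
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: FilterPolicy | None = None,
) -> list[InterlogRecord]:
    """Intersect the species-wise accepted sets through the ortholog map.

    Emits one record per ortholog pair whose fly accession is accepted in
    fly data and whose human accession is accepted in human data; many-to-
    many pairs each produce their own record.  Records are sorted by human
    then fly accession.
    """
    policy = policy or FilterPolicy()
    support = _supporting_runs(evidence, experiments, policy)
    records = []
    for pair in pairs:
        if pair.fly_accession not in accepted_fly:
            continue
        if pair.human_accession not in accepted_human:
            continue
        fly_runs = support.get(("fly", pair.fly_accession), [])
        human_runs = support.get(("human", pair.human_accession), [])
        if not fly_runs or not human_runs:
            # accepted sets may have been built from a different evidence
            # snapshot; a pair without per-run support here is dropped
            continue
        records.append(
            InterlogRecord(
                fly_accession=pair.fly_accession,
                human_accession=pair.human_accession,
                supporting_fly_experiments=tuple(fly_runs),
                supporting_human_experiments=tuple(human_runs),
                source=pair.source,
            )
        )
    return sorted(records, key=lambda r: (r.human_accession, r.fly_accession))


def collapse_by_human(records: Sequence[InterlogRecord]) -> dict[str, list[InterlogRecord]]:
    """Optional view grouping many-to-many records by human accession."""
    grouped: dict[str, list[InterlogRecord]] = {}
    for record in records:
        grouped.setdefault(record.human_accession, []).append(record)
    return grouped


def write_conserved_table(records: Sequence[InterlogRecord], path: str | Path) -> None:
    """Serialize interlog records as a deterministic TSV."""
    rows = [
        (
            r.fly_accession,
            r.human_accession,
            r.source,
            len(r.supporting_fly_experiments),
            len(r.supporting_human_experiments),
            ";".join(r.supporting_fly_experiments),
            ";".join(r.supporting_human_experiments),
        )
        for r in sorted(records, key=lambda r: (r.human_accession, r.fly_accession))
    ]
    pd.DataFrame(rows, columns=CONSERVED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_conserved_table(path: str | Path) -> list[InterlogRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            InterlogRecord(
                fly_accession=row.fly_accession,
                human_accession=row.human_accession,
                source=row.source,
                supporting_fly_experiments=tuple(row.fly_experiments.split(";")),
                supporting_human_experiments=tuple(row.human_experiments.split(";")),
            )
        )
    return records


def load_reference_conserved_pairs() -> pd.DataFrame:
    """Load the packaged 49-pair conserved PI3K interactor reference table.

    Columns: fly_accession, fly_mw_kda, protein_name, human_accession,
    human_mw_kda.  One row per fly/human ortholog pair, including the
    regulatory-subunit bait itself.
    """
    ref = resources.files("orthoppi.data").joinpath("pi3k_conserved_pairs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)
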