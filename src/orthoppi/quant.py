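"""Spectral-count quantification and bait-prey network export.

Spectral counts are averaged over the biological replicates of each
(species, bait, condition) unit, treating a protein absent from a replicate
as 0 counts.  On the averaged table three read-outs are computed:

* ``fold_change`` — stimulation response of a prey within one bait's IPs:
  (mean_stimulated + c) / (mean_basal + c) with pseudocount c (default 1.0)
  so a prey absent at baseline still has a finite, interpretable fold.
* ``subunit_preference`` — which of two baits a prey favours:
  log2((mean_regulatory + c) / (mean_catalytic + c)); positive means
  preference for the regulatory subunit, negative for the catalytic one.
* ``build_network`` — directed bait->prey edges for every unit whose mean
  count reaches the threshold (default 3.0), coloured by condition
  (black/green/orange for 0/10/30 min of insulin stimulation) for export to
  network-visualization software (SIF, GraphML or TSV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .evidence import IPExperiment, ProteinEvidence

logger = logging.getLogger(__name__)

DEFAULT_CONDITION_COLORS = {
    "basal": "black",
    "insulin_10": "green",
    "insulin_30": "orange",
}

EDGE_COLUMNS = ["bait", "prey", "species", "condition", "mean_counts", "color"]


@dataclass
class QuantPolicy:
    """Averaging and edge-threshold parameters."""

    pseudocount: float = 1.0
    min_average_counts: float = 3.0
    log_base: float = 2.0
    condition_colors: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_COLORS)
    )
    normalize_totals: bool = False  # optional between-run total-count scaling

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_average_counts < 0:
            raise ValueError("min_average_counts must be >= 0")

    def with_updates(self, **kwargs) -> "QuantPolicy":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NetworkEdge:
    """Directed bait->prey association for one condition."""

    bait: str
    prey: str
    species: str
    condition: str
    mean_counts: float
    color: str


def average_counts(
    evidence: Sequence[ProteinEvidence],
    experiments: Sequence[IPExperiment],
    policy: QuantPolicy | None = None,
) -> pd.DataFrame:
    """Replicate-averaged counts keyed by (species, bait, condition, prey).

    The mean runs over all replicate runs of a unit; a prey with no record
    in some replicate contributes 0 there.  Control IPs are excluded.
    With ``normalize_totals`` each run's counts are first scaled so that all
    runs of a species share the same total (off by default: raw averages).
    Returns a DataFrame with columns species, bait, condition, prey,
    mean_counts.
    """
    policy = policy or QuantPolicy()
    by_id = {e.experiment_id: e for e in experiments if not e.is_control}
    unit_runs: dict[tuple[str, str, str], set[str]] = {}
    for exp in by_id.values():
        unit_runs.setdefault(exp.unit, set()).add(exp.experiment_id)

    scale: dict[str, float] = {}
    if policy.normalize_totals:
        totals: dict[str, int] = {}
        species_totals: dict[str, list[int]] = {}
        for record in evidence:
            if record.experiment_id in by_id:
                totals[record.experiment_id] = (
                    totals.get(record.experiment_id, 0) + record.spectral_counts
                )
        for run_id, total in totals.items():
            species_totals.setdefault(by_id[run_id].species, []).append(total)
        for run_id, total in totals.items():
            sp_mean = sum(species_totals[by_id[run_id].species]) / len(
                species_totals[by_id[run_id].species]
            )
            scale[run_id] = sp_mean / total if total else 1.0

    sums: dict[tuple[str, str, str, str], float] = {}
    for record in evidence:
        exp = by_id.get(record.experiment_id)
        if exp is None:
            continue
        key = exp.unit + (record.accession,)
        value = record.spectral_counts * scale.get(record.experiment_id, 1.0)
        sums[key] = sums.get(key, 0.0) + value

    rows = [
        (sp, bait, cond, prey, total / len(unit_runs[(sp, bait, cond)]))
        for (sp, bait, cond, prey), total in sums.items()
    ]
    df = pd.DataFrame(
        rows, columns=["species", "bait", "condition", "prey", "mean_counts"]
    )
    return df.sort_values(
        ["species", "bait", "condition", "prey"], ignore_index=True
    )


def _lookup_mean(
    avg: pd.DataFrame, bait: str, prey: str, condition: str
) -> float | None:
    mask = (
        (avg["bait"] == bait) & (avg["prey"] == prey) & (avg["condition"] == condition)
    )
    hits = avg.loc[mask, "mean_counts"]
    if hits.empty:
        return None
    return float(hits.iloc[0])


def fold_change(
    avg: pd.DataFrame,
    bait: str,
    prey: str,
    stimulated_condition: str,
    basal_condition: str,
    policy: QuantPolicy | None = None,
) -> float | None:
    """Pseudocounted stimulation fold change for one bait-prey pair.

    Returns None (missing) when the prey is absent from both conditions —
    an unobserved pair is not the same thing as an unchanged one.
    """
    policy = policy or QuantPolicy()
    stim = _lookup_mean(avg, bait, prey, stimulated_condition)
    basal = _lookup_mean(avg, bait, prey, basal_condition)
    if stim is None and basal is None:
        return None
    stim = stim or 0.0
    basal = basal or 0.0
    return (stim + policy.pseudocount) / (basal + policy.pseudocount)


def subunit_preference(
    avg: pd.DataFrame,
    prey: str,
    regulatory_bait: str,
    catalytic_bait: str,
    policy: QuantPolicy | None = None,
    condition: str | None = None,
) -> float | None:
    """log2 preference of a prey for the regulatory over the catalytic bait.

    Means are taken over all conditions of each bait unless ``condition``
    pins one.  Positive values indicate regulatory-subunit preference.
    Returns None when the prey was seen with neither bait.
    """
    policy = policy or QuantPolicy()
    sub = avg[avg["prey"] == prey]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    reg = sub.loc[sub["bait"] == regulatory_bait, "mean_counts"]
    cat = sub.loc[sub["bait"] == catalytic_bait, "mean_counts"]
    if reg.empty and cat.empty:
        return None
    mean_reg = float(reg.mean()) if not reg.empty else 0.0
    mean_cat = float(cat.mean()) if not cat.empty else 0.0
    ratio = (mean_reg + policy.pseudocount) / (mean_cat + policy.pseudocount)
    return math.log(ratio, policy.log_base)


def build_network(
    avg: pd.DataFrame, policy: QuantPolicy | None = None
) -> list[NetworkEdge]:
    """One directed edge per (bait, condition, prey) meeting the mean threshold."""
    policy = policy or QuantPolicy()
    edges = []
    for row in avg.itertuples(index=False):
        if row.mean_counts < policy.min_average_counts:
            continue
        color = policy.condition_colors.get(row.condition)
        if color is None:
            logger.debug("condition %r has no color mapping", row.condition)
            color = "unmapped"
        edges.append(
            NetworkEdge(
                bait=row.bait,
                prey=row.prey,
                species=row.species,
                condition=row.condition,
                mean_counts=float(row.mean_counts),
                color=color,
            )
        )
    return sorted(edges, key=lambda e: (e.species, e.bait, e.condition, e.prey))


def export_network(
    edges: Sequence[NetworkEdge], path: str | Path, format: str = "tsv"
) -> None:
    """Write edges as SIF, GraphML or TSV (deterministic ordering).

    SIF carries only the topology ("bait interacts prey"); GraphML and TSV
    carry mean_counts, species, condition and color as edge attributes.
    GraphML uses one multigraph edge per condition.
    """
    ordered = sorted(edges, key=lambda e: (e.species, e.bait, e.condition, e.prey))
    path = Path(path)
    if format == "sif":
        lines = [f"{e.bait}\tinteracts\t{e.prey}" for e in ordered]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "tsv":
        pd.DataFrame(
            [
                (e.bait, e.prey, e.species, e.condition, e.mean_counts, e.color)
                for e in ordered
            ],
            columns=EDGE_COLUMNS,
        ).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        graph = nx.MultiDiGraph()
        for e in ordered:
            graph.add_edge(
                e.bait,
                e.prey,
                key=e.condition,
                mean_counts=e.mean_counts,
                species=e.species,
                condition=e.condition,
                color=e.color,
            )
        nx.write_graphml(graph, path)
    else:
        raise ValueError(
            f"unknown format {format!r}; supported: sif, graphml, tsv"
        )


def read_network_tsv(path: str | Path) -> list[NetworkEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"mean_counts": float}, keep_default_na=False)
    return [
        NetworkEdge(
            bait=row.bait,
            prey=row.prey,
            species=row.species,
            condition=row.condition,
            mean_counts=float(row.mean_counts),
            color=row.color,
        )
        for row in df.itertuples(index=False)
    ]
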