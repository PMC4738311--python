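"""Fly<->human ortholog mapping: curated tables merged with reciprocal best-k hits.

The ortholog map is built from two sources, curated taking precedence:

* curated pair tables (two-column TSV of fly and human accessions, as
  distributed by orthology databases), and
* reciprocal best-three-hits (RB3H) from all-vs-all protein sequence search
  at an E-value cutoff of 1e-60: fly protein a and human protein b are
  paired when b is within a's top-3 hits AND a is within b's top-3 hits.

Using the top *three* hits rather than strict best-best keeps close paralogs
and splice variants — e.g. a single fly regulatory subunit whose best human
match is the short p55γ isoform and whose second-best is p85α; both pairs
are retained and downstream interlog logic accepts either.

Hits can come from an external search engine via 12-column tabular files
(``read_blast_tabular``) or from the built-in all-vs-all Smith-Waterman
aligner (``align_proteomes``: BLOSUM62, affine gaps 11/1, E-values from the
Karlin-Altschul extreme-value approximation with the standard gapped
parameters lambda=0.267, K=0.041).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")

BLAST_TABULAR_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


class OrthologyFormatError(ValueError):
    pass


class ProteomeValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise search hit; rank is 1-based within the query."""

    query: str
    subject: str
    bitscore: float
    evalue: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.query}->{self.subject}")


@dataclass(frozen=True)
class OrthologPair:
    """A fly<->human accession pairing with provenance.

    ``source`` is "curated" (database table) or "rbh" (reciprocal best-k);
    rbh pairs carry the rank of each partner in the other's hit list and the
    smaller of the two E-values.
    """

    fly_accession: str
    human_accession: str
    source: str
    best_rank_fly_to_human: int | None = None
    best_rank_human_to_fly: int | None = None
    min_evalue: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.fly_accession, self.human_accession)


@dataclass
class OrthologyPolicy:
    """Reciprocal best-k parameters (k=3, E<1e-60 by default)."""

    evalue_cutoff: float = 1e-60
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")

    def with_updates(self, **kwargs) -> "OrthologyPolicy":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Scoring


def _hit_sort_key(hit: AlignmentHit) -> tuple:
    # ascending E-value, then descending bitscore, then subject accession
    return (hit.evalue, -hit.bitscore, hit.subject)


def rank_hits(
    hits: Sequence[AlignmentHit], policy: OrthologyPolicy
) -> list[AlignmentHit]:
    """Cutoff-filter and rank hits 1..n within each query.

    Ordering: ascending E-value, ties broken by descending bitscore, then
    lexicographic subject accession (so ranking is deterministic).
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        if hit.evalue >= policy.evalue_cutoff:
            continue
        by_query.setdefault(hit.query, []).append(hit)
    ranked: list[AlignmentHit] = []
    for query in sorted(by_query):
        ordered = sorted(by_query[query], key=_hit_sort_key)
        ranked.extend(
            replace(hit, rank=i) for i, hit in enumerate(ordered, start=1)
        )
    return ranked


def _karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E-value for a raw Smith-Waterman score against a database.

    E = K * m * n * exp(-lambda * S) with m the query length and n the total
    database residue count; clamped to avoid underflow surprises.
    """
    log_e = math.log(KA_K) + math.log(m) + math.log(n) - KA_LAMBDA * score
    if log_e < -745:  # exp underflows to 0.0 below this
        return 0.0
    return math.exp(log_e)


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def read_fasta_proteome(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {accession: sequence}, validating residues."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ProteomeValidationError(
                f"{path}: record {record.id!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ProteomeValidationError(f"{path}: empty proteome")
    return sequences


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def align_proteomes(
    proteome_a: str | Path | dict[str, str],
    proteome_b: str | Path | dict[str, str],
    policy: OrthologyPolicy,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """All-vs-all local alignment between two proteomes, both directions.

    Returns ``(hits_ab, hits_ba)``: ranked, cutoff-filtered hit lists with
    proteome A's sequences as queries against B, and vice versa.  Intended
    for desk-scale proteomes (hundreds of sequences); precomputed tabular
    hit files can be supplied instead via :func:`read_blast_tabular`.
    """
    seqs_a = proteome_a if isinstance(proteome_a, dict) else read_fasta_proteome(proteome_a)
    seqs_b = proteome_b if isinstance(proteome_b, dict) else read_fasta_proteome(proteome_b)
    aligner = _make_aligner()
    total_a = sum(len(s) for s in seqs_a.values())
    total_b = sum(len(s) for s in seqs_b.values())

    # SW score is symmetric for a symmetric substitution matrix, so each
    # unordered pair is aligned once; the two directions differ only in the
    # (m, n) lengths entering the E-value.
    hits_ab: list[AlignmentHit] = []
    hits_ba: list[AlignmentHit] = []
    for acc_a, seq_a in seqs_a.items():
        for acc_b, seq_b in seqs_b.items():
            score = aligner.score(seq_a, seq_b)
            e_ab = _karlin_altschul_evalue(score, len(seq_a), total_b)
            e_ba = _karlin_altschul_evalue(score, len(seq_b), total_a)
            bits = bit_score(score)
            if e_ab < policy.evalue_cutoff:
                hits_ab.append(AlignmentHit(acc_a, acc_b, bits, e_ab))
            if e_ba < policy.evalue_cutoff:
                hits_ba.append(AlignmentHit(acc_b, acc_a, bits, e_ba))
    return rank_hits(hits_ab, policy), rank_hits(hits_ba, policy)


def read_blast_tabular(
    path: str | Path, policy: OrthologyPolicy | None = None
) -> list[AlignmentHit]:
    """Parse a 12-column tabular hit file and rank the hits.

    Columns: query, subject, pident, length, mismatches, gapopens, qstart,
    qend, sstart, send, evalue, bitscore (the common tab-separated output
    dialect of protein search engines).
    """
    policy = policy or OrthologyPolicy()
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise OrthologyFormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise OrthologyFormatError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            hits.append(AlignmentHit(fields[0], fields[1], bits, evalue))
    return rank_hits(hits, policy)


# ---------------------------------------------------------------------------
# Reciprocal best-k and merging


def reciprocal_best_k(
    hits_ab: Sequence[AlignmentHit],
    hits_ba: Sequence[AlignmentHit],
    policy: OrthologyPolicy,
) -> list[OrthologPair]:
    """Reciprocal best-k pairs from two ranked hit lists.

    ``hits_ab`` queries are taken as fly accessions and ``hits_ba`` queries
    as human accessions; (a, b) is emitted when each is within the other's
    top-k hits.  Output is sorted by (fly, human) accession.
    """
    top_ab: dict[str, dict[str, AlignmentHit]] = {}
    for hit in hits_ab:
        if hit.rank <= policy.top_k:
            top_ab.setdefault(hit.query, {})[hit.subject] = hit
    top_ba: dict[str, dict[str, AlignmentHit]] = {}
    for hit in hits_ba:
        if hit.rank <= policy.top_k:
            top_ba.setdefault(hit.query, {})[hit.subject] = hit

    pairs = []
    for a, subjects in top_ab.items():
        for b, hit_ab in subjects.items():
            hit_ba = top_ba.get(b, {}).get(a)
            if hit_ba is None:
                continue
            pairs.append(
                OrthologPair(
                    fly_accession=a,
                    human_accession=b,
                    source="rbh",
                    best_rank_fly_to_human=hit_ab.rank,
                    best_rank_human_to_fly=hit_ba.rank,
                    min_evalue=min(hit_ab.evalue, hit_ba.evalue),
                )
            )
    return sorted(pairs, key=lambda p: p.key)


def merge_orthology(
    curated: Sequence[OrthologPair], rbh: Sequence[OrthologPair]
) -> list[OrthologPair]:
    """Merge curated and sequence-search pairs; curated provenance wins.

    All curated pairs are retained.  RBH pairs are added only for fly
    accessions absent from every curated pair (sequence search fills the
    gaps the databases leave, it does not overrule them).
    """
    merged: dict[tuple[str, str], OrthologPair] = {}
    curated_fly = set()
    for pair in curated:
        if pair.source != "curated":
            pair = replace(pair, source="curated")
        merged[pair.key] = pair
        curated_fly.add(pair.fly_accession)
    for pair in rbh:
        if pair.fly_accession in curated_fly:
            if pair.key in merged:
                logger.debug("pair %s has both provenances; keeping curated", pair.key)
            continue
        merged.setdefault(pair.key, pair)
    return sorted(merged.values(), key=lambda p: p.key)


# ---------------------------------------------------------------------------
# Pair table I/O


def read_curated_pairs(path: str | Path) -> list[OrthologPair]:
    """Read a two-column (fly, human) accession pair table (TSV, header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise OrthologyFormatError(f"{path}: need two columns (fly, human)")
    fly_col, human_col = df.columns[:2]
    pairs = [
        OrthologPair(fly_accession=f, human_accession=h, source="curated")
        for f, h in zip(df[fly_col], df[human_col])
    ]
    return sorted(set(pairs), key=lambda p: p.key)


def write_pairs(pairs: Sequence[OrthologPair], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (
                p.fly_accession,
                p.human_accession,
                p.source,
                p.best_rank_fly_to_human if p.best_rank_fly_to_human is not None else "",
                p.best_rank_human_to_fly if p.best_rank_human_to_fly is not None else "",
                f"{p.min_evalue:.3g}" if p.min_evalue is not None else "",
            )
            for p in sorted(pairs, key=lambda p: p.key)
        ],
        columns=[
            "fly_accession",
            "human_accession",
            "source",
            "rank_fly_to_human",
            "rank_human_to_fly",
            "min_evalue",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[OrthologPair]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            OrthologPair(
                fly_accession=row.fly_accession,
                human_accession=row.human_accession,
                source=row.source,
                best_rank_fly_to_human=int(row.rank_fly_to_human)
                if row.rank_fly_to_human
                else None,
                best_rank_human_to_fly=int(row.rank_human_to_fly)
                if row.rank_human_to_fly
                else None,
                min_evalue=float(row.min_evalue) if row.min_evalue else None,
            )
        )
    return pairs
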