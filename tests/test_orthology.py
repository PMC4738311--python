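"""Sequence search, hit ranking, reciprocal best-k and orthology merging."""

from __future__ import annotations

import random

import pytest

import oracles
from orthoppi.orthology import (
    AlignmentHit,
    OrthologPair,
    OrthologyFormatError,
    OrthologyPolicy,
    ProteomeValidationError,
    align_proteomes,
    merge_orthology,
    rank_hits,
    read_blast_tabular,
    read_fasta_proteome,
    reciprocal_best_k,
)
from orthoppi.simulate import SimulationConfig, generate_proteomes


def random_hits(rng: random.Random, n_queries=6, n_subjects=8, cutoff=1e-60):
    hits = []
    for qi in range(n_queries):
        for si in range(n_subjects):
            if rng.random() < 0.5:
                continue
            exponent = rng.choice([-90, -80, -70, -65, -50, -10])
            hits.append(
                AlignmentHit(
                    query=f"Q{qi}",
                    subject=f"S{si}",
                    bitscore=rng.choice([100.0, 200.0, 300.0]),
                    evalue=10.0**exponent,
                )
            )
    return hits


class TestRankHits:
    def test_orders_by_evalue(self):
        policy = OrthologyPolicy()
        hits = [
            AlignmentHit("q", "a", 100, 1e-70),
            AlignmentHit("q", "b", 100, 1e-90),
        ]
        ranked = {h.subject: h.rank for h in rank_hits(hits, policy)}
        assert ranked == {"b": 1, "a": 2}

    def test_tie_breaks_lexicographically(self):
        policy = OrthologyPolicy()
        hits = [
            AlignmentHit("q", "zzz", 100, 1e-70),
            AlignmentHit("q", "aaa", 100, 1e-70),
        ]
        ranked = {h.subject: h.rank for h in rank_hits(hits, policy)}
        assert ranked == {"aaa": 1, "zzz": 2}

    def test_cutoff_drops_weak_hits(self):
        policy = OrthologyPolicy()
        hits = [AlignmentHit("q", "a", 100, 1e-60), AlignmentHit("q", "b", 100, 1e-61)]
        ranked = rank_hits(hits, policy)
        assert [h.subject for h in ranked] == ["b"]  # 1e-60 is not < cutoff

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_comparator_sort_oracle(self, seed):
        rng = random.Random(seed)
        policy = OrthologyPolicy()
        hits = random_hits(rng)
        ranked = rank_hits(hits, policy)
        expected = oracles.comparator_sort(hits, policy.evalue_cutoff)
        got = {}
        for h in ranked:
            got.setdefault(h.query, []).append((h.rank, h.subject))
        assert {q: [s for _, s in sorted(v)] for q, v in got.items()} == expected


class TestBlastTabular:
    LINE = "q1\ts1\t98.5\t200\t3\t0\t1\t200\t1\t200\t1e-80\t350.0"

    def test_single_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.LINE + "\n")
        hits = read_blast_tabular(path)
        assert len(hits) == 1
        assert hits[0].evalue == pytest.approx(1e-80)
        assert hits[0].bitscore == pytest.approx(350.0)
        assert hits[0].rank == 1

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.LINE + "\nq1\ts2\tbroken\n")
        with pytest.raises(OrthologyFormatError, match="line 2"):
            read_blast_tabular(path)

    def test_line_order_irrelevant(self, tmp_path):
        rng = random.Random(1)
        rows = []
        for q in ("q1", "q2"):
            for i, s in enumerate(("s1", "s2", "s3")):
                rows.append(
                    f"{q}\t{s}\t90\t100\t1\t0\t1\t100\t1\t100\t1e-{70 + 10 * i}\t{100 + i}"
                )
        sorted_path = tmp_path / "sorted.tsv"
        sorted_path.write_text("\n".join(rows) + "\n")
        rng.shuffle(rows)
        shuffled_path = tmp_path / "shuffled.tsv"
        shuffled_path.write_text("\n".join(rows) + "\n")
        assert read_blast_tabular(sorted_path) == read_blast_tabular(shuffled_path)


class TestReciprocalBestK:
    def test_one_fly_gene_two_human_candidates(self):
        # a regulatory-subunit gene whose best human hit is the short splice
        # variant and second-best the full-length paralog: both pairs survive
        policy = OrthologyPolicy()
        hits_ab = rank_hits(
            [
                AlignmentHit("Pi3k21B", "P55G", 400, 1e-120),
                AlignmentHit("Pi3k21B", "P85A", 380, 1e-110),
            ],
            policy,
        )
        hits_ba = rank_hits(
            [
                AlignmentHit("P55G", "Pi3k21B", 400, 1e-120),
                AlignmentHit("P85A", "Pi3k21B", 380, 1e-110),
            ],
            policy,
        )
        pairs = reciprocal_best_k(hits_ab, hits_ba, policy)
        assert {(p.fly_accession, p.human_accession) for p in pairs} == {
            ("Pi3k21B", "P55G"),
            ("Pi3k21B", "P85A"),
        }

    def test_reciprocity_required(self):
        policy = OrthologyPolicy()
        hits_ab = rank_hits([AlignmentHit("a", "b", 400, 1e-120)], policy)
        hits_ba = rank_hits(
            [AlignmentHit("b", f"x{i}", 400, 10 ** -(130 + i)) for i in range(3)],
            policy,
        )
        assert reciprocal_best_k(hits_ab, hits_ba, policy) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = random.Random(seed)
        policy = OrthologyPolicy()
        hits_ab = rank_hits(random_hits(rng), policy)
        hits_ba = rank_hits(
            [
                AlignmentHit(h.subject, h.query, h.bitscore, h.evalue)
                for h in random_hits(rng)
            ],
            policy,
        )
        pairs = reciprocal_best_k(hits_ab, hits_ba, policy)
        assert {p.key for p in pairs} == oracles.rbh_double_loop(
            hits_ab, hits_ba, policy.top_k
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_under_species_swap(self, seed):
        rng = random.Random(seed)
        policy = OrthologyPolicy()
        hits_ab = rank_hits(random_hits(rng), policy)
        hits_ba = rank_hits(
            [
                AlignmentHit(h.subject, h.query, h.bitscore, h.evalue)
                for h in random_hits(rng)
            ],
            policy,
        )
        forward = {p.key for p in reciprocal_best_k(hits_ab, hits_ba, policy)}
        swapped = {p.key for p in reciprocal_best_k(hits_ba, hits_ab, policy)}
        assert forward == {(b, a) for (a, b) in swapped}

    @pytest.mark.parametrize("seed", range(5))
    def test_top1_pairs_subset_of_top3(self, seed):
        rng = random.Random(seed)
        policy3 = OrthologyPolicy(top_k=3)
        policy1 = OrthologyPolicy(top_k=1)
        hits_ab = rank_hits(random_hits(rng), policy3)
        hits_ba = rank_hits(
            [
                AlignmentHit(h.subject, h.query, h.bitscore, h.evalue)
                for h in random_hits(rng)
            ],
            policy3,
        )
        top1 = {p.key for p in reciprocal_best_k(hits_ab, hits_ba, policy1)}
        top3 = {p.key for p in reciprocal_best_k(hits_ab, hits_ba, policy3)}
        assert top1 <= top3

    def test_pair_evalues_below_cutoff(self):
        rng = random.Random(11)
        policy = OrthologyPolicy()
        hits_ab = rank_hits(random_hits(rng), policy)
        hits_ba = rank_hits(
            [
                AlignmentHit(h.subject, h.query, h.bitscore, h.evalue)
                for h in random_hits(rng)
            ],
            policy,
        )
        for pair in reciprocal_best_k(hits_ab, hits_ba, policy):
            assert pair.min_evalue < policy.evalue_cutoff
            assert pair.best_rank_fly_to_human <= policy.top_k
            assert pair.best_rank_human_to_fly <= policy.top_k


class TestMerge:
    def test_curated_precedence_blocks_rbh_for_same_fly_gene(self):
        curated = [OrthologPair("cswFB", "PTN11", "curated")]
        rbh = [
            OrthologPair("cswFB", "PTPN6", "rbh", 1, 1, 1e-90),
            OrthologPair("chicoFB", "IRS1", "rbh", 1, 1, 1e-80),
        ]
        merged = merge_orthology(curated, rbh)
        assert {(p.key, p.source) for p in merged} == {
            (("cswFB", "PTN11"), "curated"),
            (("chicoFB", "IRS1"), "rbh"),
        }

    def test_empty_curated_passes_rbh_through(self):
        rbh = [OrthologPair("a", "b", "rbh", 1, 1, 1e-90)]
        assert [p.key for p in merge_orthology([], rbh)] == [("a", "b")]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_two_pass_oracle(self, seed):
        rng = random.Random(seed)
        flies = [f"f{i}" for i in range(6)]
        humans = [f"h{i}" for i in range(6)]
        curated = [
            OrthologPair(rng.choice(flies), rng.choice(humans), "curated")
            for _ in range(rng.randint(0, 5))
        ]
        rbh = [
            OrthologPair(rng.choice(flies), rng.choice(humans), "rbh", 1, 1, 1e-70)
            for _ in range(rng.randint(0, 8))
        ]
        merged = merge_orthology(curated, rbh)
        assert {p.key: p.source for p in merged} == oracles.merge_two_pass(curated, rbh)


class TestAligner:
    def test_identical_proteomes_self_best_hit(self, small_simulation):
        fly, _, _ = generate_proteomes(small_simulation)
        subset = dict(list(fly.items())[:6])
        policy = OrthologyPolicy()
        hits_ab, hits_ba = align_proteomes(subset, subset, policy)
        rank1 = {h.query: h.subject for h in hits_ab if h.rank == 1}
        assert rank1 == {acc: acc for acc in subset}
        pairs = reciprocal_best_k(hits_ab, hits_ba, policy)
        assert {p.key for p in pairs} >= {(acc, acc) for acc in subset}

    def test_substitution_scores_below_self_alignment(self):
        policy = OrthologyPolicy(evalue_cutoff=1.0)
        seq = "MKTLVILAVLGLSTAW" * 10
        mutated = "A" + seq[1:]
        hits_ab, _ = align_proteomes(
            {"wt": seq}, {"wt_copy": seq, "mut": mutated}, policy
        )
        scores = {h.subject: h.bitscore for h in hits_ab}
        assert scores["mut"] < scores["wt_copy"]

    def test_small_proteomes_match_exhaustive_ranking(self, small_simulation):
        # independent path: score every (query, subject) pair, sort with an
        # explicit comparator, compare with the package's ranked output
        fly, human, _ = generate_proteomes(small_simulation)
        fly_sub = dict(list(fly.items())[:8])
        human_sub = dict(list(human.items())[:8])
        policy = OrthologyPolicy(evalue_cutoff=1e-3)
        hits_ab, _ = align_proteomes(fly_sub, human_sub, policy)
        expected = oracles.comparator_sort(hits_ab, policy.evalue_cutoff)
        got = {}
        for h in sorted(hits_ab, key=lambda h: h.rank):
            got.setdefault(h.query, []).append(h.subject)
        assert got == expected

    def test_empty_proteome_rejected(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ProteomeValidationError):
            read_fasta_proteome(empty)

    def test_non_amino_acid_characters_name_the_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">rec1\nMKTL123\n")
        with pytest.raises(ProteomeValidationError, match="rec1"):
            read_fasta_proteome(path)


class TestPlantedRecovery:
    def test_planted_orthologs_recovered_exactly(self, small_simulation):
        fly, human, truth = generate_proteomes(small_simulation)
        policy = OrthologyPolicy()
        hits_ab, hits_ba = align_proteomes(fly, human, policy)
        pairs = reciprocal_best_k(hits_ab, hits_ba, policy)
        assert {p.key for p in pairs} == set(truth.ortholog_pairs)

    def test_degrading_identity_lowers_recall_monotonically(self, small_simulation):
        recalls = []
        for identity in (0.85, 0.45, 0.25):
            config = SimulationConfig(
                seed=small_simulation.seed,
                n_conserved_preys=small_simulation.n_conserved_preys,
                n_species_specific_preys=small_simulation.n_species_specific_preys,
                n_sticky=small_simulation.n_sticky,
                n_contaminants=small_simulation.n_contaminants,
                ortholog_identity=identity,
            )
            fly, human, truth = generate_proteomes(config)
            policy = OrthologyPolicy()
            hits_ab, hits_ba = align_proteomes(fly, human, policy)
            recovered = {p.key for p in reciprocal_best_k(hits_ab, hits_ba, policy)}
            planted = set(truth.ortholog_pairs)
            recalls.append(len(recovered & planted) / len(planted))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[2] < 1.0
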