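"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — linear scans, double loops and
explicit set arithmetic — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from collections import defaultdict


def contaminant_scan(records, blocklist, patterns):
    """Keep records not blocklisted and not matching any pattern."""
    kept = []
    for r in records:
        if r.accession in blocklist:
            continue
        if any(p.lower() in r.description.lower() for p in patterns):
            continue
        kept.append(r)
    return kept


def control_set_difference(records, experiments):
    """Per-species subtraction of control-observed accessions."""
    species = {e.experiment_id: e.species for e in experiments}
    controls = {e.experiment_id for e in experiments if e.is_control}
    banned = set()
    for r in records:
        if r.experiment_id in controls and r.spectral_counts >= 1:
            banned.add((species[r.experiment_id], r.accession))
    return [
        r
        for r in records
        if r.experiment_id not in controls
        and (species.get(r.experiment_id), r.accession) not in banned
    ]


def identification_enumeration(records, experiments, policy):
    """Per-accession exhaustive count of supporting (bait, condition) units."""
    exp = {e.experiment_id: e for e in experiments}
    accepted = {"fly": set(), "human": set()}
    accessions = defaultdict(set)
    for r in records:
        e = exp.get(r.experiment_id)
        if e is not None and not e.is_control:
            accessions[e.species].add(r.accession)
    for sp in ("fly", "human"):
        needed = (
            policy.min_supporting_experiments_human
            if sp == "human"
            else policy.min_supporting_experiments_fly
        )
        for acc in accessions[sp]:
            units = set()
            for r in records:
                e = exp.get(r.experiment_id)
                if e is None or e.is_control or e.species != sp or r.accession != acc:
                    continue
                ok = r.spectral_counts >= policy.min_counts_per_experiment
                if sp == "human":
                    ok = ok and r.unique_peptides >= policy.min_unique_peptides
                if ok:
                    units.add((e.bait, e.condition))
            if len(units) >= needed:
                accepted[sp].add(acc)
    return accepted


def sticky_scan(accepted, records, patterns, exemptions):
    descs = defaultdict(list)
    for r in records:
        descs[r.accession].append(r.description.lower())
    kept = set()
    for acc in accepted:
        texts = descs.get(acc, [])
        exempt = any(x.lower() in t for x in exemptions for t in texts)
        sticky = any(p.lower() in t for p in patterns for t in texts)
        if sticky and not exempt:
            continue
        kept.add(acc)
    return kept


def rbh_double_loop(hits_ab, hits_ba, top_k):
    """All (a, b) with b in a's top-k and a in b's top-k (ranked inputs)."""
    pairs = set()
    for ha in hits_ab:
        if ha.rank > top_k:
            continue
        for hb in hits_ba:
            if hb.rank > top_k:
                continue
            if ha.query == hb.subject and ha.subject == hb.query:
                pairs.add((ha.query, ha.subject))
    return pairs


def comparator_sort(hits, cutoff):
    """Rank hits per query with an explicit comparator; returns {query: [subjects]}."""
    per_query = defaultdict(list)
    for h in hits:
        if h.evalue < cutoff:
            per_query[h.query].append(h)
    out = {}
    for q, hs in per_query.items():
        hs = sorted(hs, key=lambda h: (h.evalue, -h.bitscore, h.subject))
        out[q] = [h.subject for h in hs]
    return out


def merge_two_pass(curated, rbh):
    """Set union with curated precedence per fly accession."""
    result = {(p.fly_accession, p.human_accession): "curated" for p in curated}
    curated_fly = {p.fly_accession for p in curated}
    for p in rbh:
        key = (p.fly_accession, p.human_accession)
        if p.fly_accession not in curated_fly and key not in result:
            result[key] = "rbh"
    return result


def interlog_brute_force(accepted_fly, accepted_human, pairs):
    """Every ortholog pair accepted on both sides."""
    return {
        (p.fly_accession, p.human_accession)
        for p in pairs
        if p.fly_accession in accepted_fly and p.human_accession in accepted_human
    }


def averaging_loop(records, experiments):
    """Naive per-(unit, prey) mean with absent replicates counted as zero."""
    by_id = {e.experiment_id: e for e in experiments if not e.is_control}
    runs_per_unit = defaultdict(set)
    for e in by_id.values():
        runs_per_unit[(e.species, e.bait, e.condition)].add(e.experiment_id)
    totals = defaultdict(float)
    for r in records:
        e = by_id.get(r.experiment_id)
        if e is None:
            continue
        totals[(e.species, e.bait, e.condition, r.accession)] += r.spectral_counts
    return {
        key: total / len(runs_per_unit[key[:3]]) for key, total in totals.items()
    }


def confusion_scores(recovered, truth):
    tp = len(set(recovered) & set(truth))
    precision = tp / len(set(recovered)) if recovered else 1.0
    recall = tp / len(set(truth)) if truth else 1.0
    return precision, recall
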