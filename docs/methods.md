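# Methods

## The analysis model

`orthoppi` treats a cross-species bait-prey study as four sequential
transformations of per-run protein identification tables.

**Evidence cascade.** The cascade assumes spectral counts are a usable
label-free abundance proxy and that identification quality is captured by
unique-peptide counts. Its order is fixed: contaminants → control
subtraction → identification policy → sticky-category removal. The first
two steps are pure set subtractions and commute (this is tested); the
identification policy must follow them, because a contaminant or
control-observed protein with high counts would otherwise be accepted;
sticky removal acts on the accepted accession sets. The identification
policy counts *experiment-condition units* — distinct (species, bait,
condition) combinations — not replicate runs, so three replicates of one IP
cannot masquerade as three independent experiments. Within a unit, an
accession is supported when at least one replicate individually meets the
per-run thresholds; pooling counts across runs is deliberately avoided,
for the same reason pooling across experiments is: summing sub-threshold
scraps would accept single-spectrum artifacts.

Thresholds (defaults): ≥ 3 spectral counts per run, ≥ 2 unique peptides
(human only — TAP elutions are antibody-free and were historically filtered
on counts alone), ≥ 2 supporting human units, ≥ 1 fly unit. Fly evidence
still respects the spectral-count floor per run.

**Name-based filters.** Contaminant and sticky matching is case-insensitive
substring search on the protein description, plus an exact accession
blocklist. Category-word matching has a known failure mode: proteins
*named after* a category (e.g. an activator of the Hsp90 chaperone whose
description contains "heat shock protein") would be removed although they
are genuine interactors. A small exemption-phrase list (default:
"heat shock protein atpase") is checked before the sticky patterns. Both
lists are policy fields, not constants.

**Control subtraction modes.** The default mode removes exact accessions
observed in any control IP of the same species. A "category" mode
additionally removes records whose description matches a sticky-category
pattern that appeared in a control, for datasets where control and sample
runs were searched against different database versions and accessions do
not line up. Exact-accession is the default because it is the conservative,
auditable reading.

**Orthology.** Curated pair tables are consumed as two-column TSVs and take
precedence; reciprocal best-three-hits (RB3H) sequence search fills in fly
genes absent from every curated pair. RB3H rather than strict best-best
keeps close paralogs and splice variants (a regulatory subunit whose best
cross-species match is a short splice isoform and whose second-best is the
full-length paralog yields both pairs; downstream logic accepts any pair).
Hit ranking is ascending E-value, then descending bitscore, then
lexicographic subject accession — the last tie-break exists only to make
ranking deterministic.

The built-in aligner is local Smith-Waterman (BLOSUM62, gap open 11,
extend 1) via Biopython's `PairwiseAligner`, with E-values from the
Karlin-Altschul extreme-value form `E = K·m·n·exp(−λS)` using the standard
gapped parameters λ = 0.267, K = 0.041, m the query length and n the total
database residue count. This reproduces the behaviour of a conventional
protein search engine closely enough at desk scale (hundreds of
sequences); for real proteomes, precomputed hits in the common 12-column
tabular dialect bypass the aligner entirely.

**Interlogs.** The overlap runs on the *already filtered* accepted sets, so
"supported in at least one experiment of each species" is in practice the
full identification policy (≥ 2 human units). Many-to-many ortholog pairs
each produce their own conserved-interactor record; a collapse-by-human-
gene view is available (`collapse_by_human`) but not the default, since
one row per pair matches how conserved tables are conventionally reported.

**Quantification.** Counts are arithmetically averaged over the replicate
runs of each unit, with a prey absent from a replicate contributing zero —
absence is evidence of low abundance, not missing data, in spectral
counting. Fold change and bait preference both use a pseudocount
(default 1.0) so that preys undetected at baseline have finite values;
raising the pseudocount shrinks fold changes toward 1 and preferences
toward 0 (tested). No between-run normalization is applied by default
(`normalize_totals` turns on optional total-count scaling); spectral-count
averages are reported raw. No significance test is attached to fold
changes: with two or three replicates per condition a count-based test adds
false confidence, so the pipeline reports ranked values and leaves
labelling to the caller. Edges below a mean of 3.0 counts are not exported.

## The synthetic-data generator

The generator emulates the structure such a study actually has: two fly
TAP baits (regulatory and catalytic PI3K subunits) × {basal, insulin_10,
insulin_30} × 3 biological replicates plus an empty-TAP control, and 16
human antibody-IP condition units (cell line × serum/starved/drug) × 2
replicates plus an IgG control. Planted content per the default
configuration: 12 conserved preys (fly/human sequence pairs), 30
species-specific preys (split evenly), 20 sticky background proteins
(split evenly, named after the sticky categories), and 15 contaminant
entities named after the contaminant list and present in every run of both
species, controls included. The two bait ortholog pairs are part of the
planted conserved truth (the human catalytic subunit appears as a prey of
the human regulatory-subunit IPs, as a heterodimer partner would), so the
default truth set has 14 pairs.

Two named conserved preys carry the study's headline patterns: one
regulatory-bait-preferring (8× enrichment) and insulin-responsive (3×),
one catalytic-preferring and insulin-responsive — the SHP2/Csw-like and
IRS1/Chico-like analogues. All other conserved preys bind both fly baits
evenly and ignore stimulation.

Counts are Poisson by default around
`baseline × condition-fold × preference-factor` (baseline 30, background 5
for sticky/contaminant records); a negative-binomial option
(`count_model="negative_binomial"`, size parameter `dispersion`) is
provided because real spectral counts are overdispersed, but Poisson is the
default so that test oracles stay simple. Unique peptides are
`min(counts, 1 + Binomial(counts, 0.25))`, which makes the two-peptide rule
realistically satisfiable at healthy counts and realistically failable at
1-2 counts. Everything derives from `numpy.random.default_rng` seeded from
the single `seed` field; identical seeds give byte-identical FASTA and
TSV outputs.

Ortholog sequences are per-site mutated copies at `ortholog_identity`
(default 0.85), lengths uniform on 150-600 residues. The default identity
was chosen from the E-value arithmetic: at the shortest length (150) an
85%-identity pair has expected raw score ≈ 0.85·150·5.8 − 0.15·150 ≈ 717
(5.8 the mean BLOSUM62 diagonal, −1 the mean off-diagonal), giving
λS ≈ 191 against a detection threshold of ≈ 150 for E < 1e-60 at this
database size — about five standard deviations of headroom, so planted
pairs are essentially never lost to score noise. Identities below ~0.6
progressively fall out of the detectable range at short lengths, which the
identity-degradation test exploits.

What the generator does **not** emulate: peptide-level structure (shared
peptides, protein inference), run-to-run depth variation, batch effects,
abundance-dependent detection bias, paralog families within a species, and
real sticky proteins' cross-species conservation (synthetic sticky preys
are species-private random sequences). Passing the planted-recovery tests
therefore shows the pipeline's set logic and thresholds are correct, not
that the thresholds are optimal for any real instrument or search-engine
configuration.

## Problem sizes and numerics

Default desk-scale runs use ~54 proteins per species (≈ 2,900 pairwise
alignments, a few seconds); oracle-equivalence tests use 200 randomized
instances of ~10-60 records each; monotonicity uses 50 randomized
configurations. E-values are computed in log space and clamped to 0 below
exp(−745) to avoid underflow; the RB3H cutoff is strict (`E < cutoff`, so a
hit at exactly 1e-60 is excluded). Records with zero spectral counts are
accepted on input and treated as absence. Row order of all tables is
meaningless; every writer sorts deterministically.

## Known limitations

* The internal aligner's E-values use fixed gapped Karlin-Altschul
  parameters rather than composition-adjusted ones; absolute E-values can
  differ from a production search engine by orders of magnitude near the
  cutoff. Supply engine hit tables for publication-grade orthology.
* Accessions are opaque tokens: no splice-variant collapsing or gene-level
  aggregation is attempted beyond the optional collapse-by-human view.
* The two-unique-peptide rule is applied to human evidence only, mirroring
  the antibody-IP acceptance practice it encodes; extending it to fly
  evidence requires a small change to the cascade rather than a policy
  switch.
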