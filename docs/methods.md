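# Methods notes

This note records the models behind each stage of `est454`, the parameters
that matter, the numerical conventions, and the design decisions that were
genuinely open — in enough detail that a maintainer can predict the output of
every stage without reading the code.

## Study design model

Libraries are organised by a `StageDesign`: organ groups with ordered stages.
The default design has four flower-bud stages ordered by accumulated chill
units (0, 397, 789, 1333 — one chill unit is an hour at 0–7 °C), four fruit
ripening stages (green < white < pink < blue), and a single leaf library.
Stage ordinates must strictly increase within a group; only groups with at
least two stages carry expression trends.  Library identifiers are
`<group>_<stage>` everywhere.  All coordinates in every artifact are 0-based,
half-open.

## Read QC

Adapter masking is exact-substring and end-anchored: the longest read prefix
equal to an adapter suffix, and the longest read suffix equal to an adapter
prefix, of at least `min_adapter_match` (10) nt are removed.  This is
deliberate: at the 0–1% substitution rates the simulator produces, exact
end matching is essentially as sensitive as alignment-based trimming, and it
is trivially idempotent for non-self-overlapping adapters.  Its known
limitation is adapters with sequencing errors in the matched bases.  No
adapter sequences are built in; they are configuration.  The length filter
keeps reads of ≥ `min_length` (50) nt.  A mean-quality filter exists but is
disabled by default — platform quality filtering happens upstream of this
toolkit, and simulated reads carry no meaningful qualities.

## Greedy assembly

Candidate overlaps are found by indexing the leading `min_overlap − k + 1`
k-mers (k = 16) of both strands of every unit ("prefix seeds") plus all
k-mers of every unit; a seed shared between a unit's interior and another
unit's prefix fixes a diagonal, and the implied end-overlap is scored as its
number of matching bases.  An overlap is admissible when its length is
≥ `min_overlap` (30 nt) and its identity ≥ `min_identity` (0.95); containments
are admissible overlaps.  Merging is greedy best-score-first; ties prefer the
longer overlap, then the lexicographically smaller pair of unit names.  Reads
are processed in sorted-id order, so the result is invariant to input file
order.  Consensus is per-column majority vote over all member bases, ties
resolved in favour of the first-merged base; no quality weighting (inputs are
synthetic or legacy FASTA).  Units with ≥ 2 members are contigs; unmerged
reads remain singletons, unaltered.  Read conservation — every input read in
exactly one contig or singleton — is structural and tested.

Reference validation conditions: error-free libraries at 5× coverage over 50
transcripts of 700–900 nt assemble with zero chimeric contigs (every contig's
members share one source transcript and its consensus is an exact substring
of it).  k-mer buckets longer than 1,000 entries are skipped during candidate
search; this only matters for pathological repeat content, which the
simulator excludes by construction.

## Homology search and E-values

Scoring is BLASTN-like: match +1, mismatch −2, affine gaps with open −5 and
extend −2 under the convention that a gap of length L costs
`open + (L−1)·extend`.  The engine indexes subject 11-mers, seeds both query
strands, groups seeds into diagonal bands (width 8), prescreens each band
with an ungapped X-drop extension (X = 12; bands whose best ungapped score
stays within 3 of the bare seed score are dropped as chance matches), and
refines survivors with an exact gapped local alignment restricted to a
subject window padded 24 nt beyond the seeded diagonals.  Significance uses
the ungapped Karlin–Altschul formula `E = K·m·n·e^{−λS}` with K = 0.621,
λ = 1.33, m the query length and n twice the summed subject length (both
strands), applied to the gapped score — the standard approximation; its error
is conservative at the 1e-5 cutoff used throughout.  Only the best hit per
(query, subject) pair is reported, so downstream read counting cannot
double-count.

`sw_align_oracle` is the exact full-dynamic-programming local alignment
(Biopython's PairwiseAligner under the same scoring).  Because the refinement
step solves the same problem on a subject window, the heuristic score can
never exceed the oracle's, and equals it whenever an exact shared k-mer lies
on the optimal path and the window covers that path — both properties are
tested on random and planted instances.

## Digital expression

Reads of every library are assigned to contigs by best homology hit at
E ≤ 1e-5 (read counting uses sparser seeding — every 4th query k-mer, two
seeds per band — which is ample when reads are near-identical to their source
contig).  Frequencies are percent of the library's total assembled reads, not
of reads-in-contigs.  The trend classifier compares consecutive stages:
step *up* if `(f_{i+1}+p)/(f_i+p) ≥ τ`, *down* if `≤ 1/τ`, else *flat*, with
τ = 1.5.  The damping offset `p` is an absolute frequency, 0.01% (one read
per 10,000), *not* a count added to the numerator and denominator: keeping it
in frequency space makes calls exactly invariant under rescaling a library's
counts and total, which a count-space pseudocount would break.  Collapsing
the non-flat step signs gives the pattern: none → `flat`; all positive →
`up`; all negative → `down`; one sign change → `up_down`/`down_up`; two or
more → `complex`.

A note on symmetry: reversing the stage order swaps `up` and `down` and fixes
`flat`, `complex`, **and both biphasic patterns** — a profile that rises then
falls still rises first when read from the other end ([1, 4, 2] reversed is
[2, 4, 1]).  The property tests assert this (correct) symmetry.

`top_abundant` returns the `top_n` (30) contigs by read count, descending,
ties broken by contig id, zero-count contigs excluded.

Reference validation conditions: at effect size 2, 1% substitution error, and
5,000 reads per library across the four bud stages (contigs built from a
900-read pooled subsample), ≥ 90% of top-abundant contigs receive their
planted pattern.  The residual misses are biphasic patterns whose weak arm
lands inside the τ band under multinomial counting noise.

## qPCR (ΔΔCT)

CT values above the 40-cycle cap are truncated on load.  Replicates are
summarised by arithmetic mean CT with no outlier rejection.  The per-stage
reference level is the arithmetic mean of the reference genes' mean CTs —
equivalent to a geometric mean of their linear quantities; this standard
construction stands in for vendor "global normalization", whose algorithm is
unpublished.  ΔCT subtracts the reference level; folds are
`2^{−(ΔCT_stage − ΔCT_baseline)}` with baselines bud stage `0` and fruit
stage `green`, so the baseline fold is exactly 1 and normalization is
invariant under per-sample additive CT shifts.  Fold profiles are classified
with the same step rule, with zero damping offset (folds live on a scale
of 1).  Concordance between predicted and observed patterns is exact label
equality — the strictest reading of "similar to predicted" — and is reported
as (matches, total, rounded percent).  Reference genes are explicit input:
studies of this kind variously normalise against metallothionein,
high-mobility-group protein, a hypothetical protein, or S-adenosyl-
homocysteine hydrolase, so no default is baked in.

## EST-SSR mining

A locus is a maximal perfect tandem repeat of a primitive motif of length
2–5, reported once under its primitive motif with `end − start =
motif_length × repeat_count`; a trailing partial unit never changes the
count or coordinates, runs are never extendable by a full unit on either
side, and mononucleotide runs are never reported.  Thresholds: ≥ 5 repeats
for dinucleotide, ≥ 4 for trinucleotide, ≥ 3 for tetra- and pentanucleotide
motifs; sequences shorter than 120 nt are excluded from mining.  Canonical
classes are the lexicographic minimum over all rotations of the motif and of
its reverse complement, which reproduces the familiar groupings (AG/GA/TC/CT;
AAG/GAA/AGA/CTT/TTC/TCT; AT/TA is self-complementary).  Composition summaries
report each category's share of all SSRs and of mined sequences, and each
class's share within its category, rounded to one decimal.

Primer-candidate filtering evaluates GC content over the **whole** sequence
(the alternative — GC of the primer-design region only — is a defensible
reading; the whole-sequence rule is the one implemented and stated in output)
and requires ≥ 20 nt of flank on both sides of the locus.  Compound or
interrupted repeats are reported as separate maximal runs, never merged.
Marker screens summarise amplification rate (product in ≥ 1 accession) and
polymorphism rate (records called polymorphic) as integer percentages.

## Synthetic data generator

What it emulates: several stage-ordered libraries multinomially sampled from
one shared transcript pool; 454-like read lengths (truncated normal, mean
287 nt, sd 50, minimum 50, capped at the transcript length); uniform read
start positions; i.i.d. substitution errors (1% default); an optional 5'
adapter; planted microsatellites on backgrounds rejection-sampled until the
miner finds exactly the planted loci (junction bases are resampled so a
planted run cannot extend, keeping recorded coordinates exact); and
triplicate CT tables in which a gene's mean CT falls by log2(effect size)
per planted up-step relative to flat reference genes, with Gaussian replicate
noise (0.25 cycles by default) and the 40-cycle cap.

Expression trends are multiplicative: transcript t in stage s has weight
`base_t · effect^{e(s)}`, where the cumulative exponents e(s) step by ±1 per
stage (turning at the midpoint for biphasic patterns) and are shifted so each
pattern's maximum is 0 — abundance rises toward, or falls from, a peak and
never above the transcript's base weight.  This peak normalization matters:
with exponents growing above baseline and equal pattern mass, the per-library
normalizing total itself varies enough across stages to push genuinely flat
transcripts over the τ band.  With peak normalization and the default
assignment — half the pool flat, the four trending patterns cycling over the
other half, phase-shifted between organ groups — the expected frequency
profile of every transcript follows its planted label by construction.  Base
weights are log-normal (σ = 0.6), giving a realistic abundance spread.

Determinism: all sampling derives from `config.seed`; read sampling uses a
child stream keyed by (seed, library index), so identical configs give
identical output regardless of the order in which libraries are drawn.

What it does **not** emulate, and what passing tests therefore do not show:
454 homopolymer indel errors (the dominant real 454 error mode — the
assembler and aligner are only validated against substitutions), flowgram or
quality-value structure, non-uniform positional coverage (3'/5' bias of real
cDNA libraries), paralogy and shared domains between transcripts (the pool is
i.i.d. random sequence, so homology search enjoys an unrealistically clean
negative space), chimeric cDNAs, and library-size imbalance.  Real-data
contig counts and SSR totals are not reproducible from simulation and are not
targets; the published tallies in `est454.datasets` are carried as inputs for
worked-example arithmetic only.

## Degenerate inputs and conventions

Empty FASTA files parse to empty read sets; empty tables write header-only
TSVs; an empty read set assembles to an empty result with a zero-filled
summary row.  Trend classification requires ≥ 2 stages and raises otherwise;
frequency tables reject zero library totals; `global_normalize` names the
missing reference gene and stage in its error.  Unigene-set comparison counts
a unigene as shared when it has a cross-set hit at the E-value cutoff; since
the two directions can disagree (one long contig can absorb several short
unigenes from the other set), the headline `shared` is the larger of the two
per-side counts, and both per-side counts are returned.  Non-ACGT characters
never match anything: they break SSR runs and are mismatches in alignment.
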