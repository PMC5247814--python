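# Methods

## Motif model

A direct-repeat (DR) element is modelled as two hexameric half-sites and
a spacer. Each half-site is six ordered allowed-nucleotide sets, parsed
from a 15-letter IUPAC string; the spacer is either *variable* — any
bases over a length range, written `N{a,b}` with 0 ≤ a ≤ b ≤ 9 — or
*fixed* — a per-position IUPAC constraint such as `NNNRV`. The DR class
of a match is `DR<n>` where *n* is the realized spacer length, so one
variable-spacer pattern enumerates DR0 through DR9 in a single scan.

Two patterns ship built in:

* `canonical-RARE` = `RGKTCA + N{0,9} + RGKTCA`, the classical
  vertebrate consensus and the default scan pattern;
* `amphioxus-validated-DR5` = `RGKTSA + NNNRV + RGKWCA`, the degenerate
  signature summarising in-vitro validated amphioxus DR5 elements. It is
  a *derived* summary of validated hits, so it is available by name but
  deliberately not the default scan input.

Matching is exact set-membership per position. Two consequences worth
stating: there is no score and hence no threshold to tune, and the hit
set is exactly enumerable, which is what allows the brute-force oracle
equivalence tests. A genomic `N` (unknown base) satisfies only a fully
degenerate pattern position; this conservative policy avoids phantom
elements inside assembly gaps. Matching is case-insensitive by default;
a `masked_policy="skip"` switch rejects any window containing a
soft-masked (lowercase) residue.

## Scanner

For each pattern and strand the scanner computes per-offset half-site
membership vectors (a vectorized table lookup over the encoded sequence)
and combines them for every spacer length, so every (offset, spacer,
strand) combination is reported — overlapping, nested and
shared-half-site matches included. The rationale for exhaustive
enumeration is that filtering is a downstream decision; collapsing
overlaps at scan time would discard information the conservation stage
may need.

Minus-strand elements are found by matching the reverse-complemented
pattern on the plus strand; coordinates are always plus-strand, 0-based
half-open, and the reported half-site/spacer strings are read 5′→3′ on
the matching strand, so `half1+spacer+half2` reconstructs the genomic
substring (or its reverse complement) exactly — an invariant asserted
for every hit in every test run. Duplicate (start, end, strand, pattern)
matches are removed; a perfect palindrome (identical read-out on both
strands at one locus) is reported once, on the plus strand.

The survey window runs from `up` bp upstream of the rank-1 gene's start
codon to `down` bp downstream of the last gene's stop codon (defaults
20 000/20 000), clipped to the sequence. The spacer upper bound is
clamped at 15 to bound scan cost.

## Cluster annotation

Gene models carry `start_codon_pos` (first ATG base) and
`stop_codon_end` (one past the stop codon, walking in gene direction)
plus a `cluster_rank`. For a minus-strand gene the body is
`[stop_codon_end + 1, start_codon_pos + 1)` on the assembly; this
convention makes annotation of a reverse-complemented cluster the exact
mirror of the original, which is tested as a full-pipeline symmetry.

Compartments partition the sequence into the upstream flank, gene
bodies, intergenic intervals and the downstream flank, identified across
species by gene *rank*, not coordinates. A hit overlapping any part of a
gene body is intragenic (largest overlap wins, then lower rank);
otherwise the interval containing the hit's midpoint wins. Distance to a
start codon counts the bases strictly between the hit's proximal edge
and the first ATG base, exclusive of both — a hit ending exactly at the
codon is at distance 0. The edge convention is not universal in the
literature, so it is documented here and in output metadata rather than
assumed obvious.

## Conservation filter

Elements of two species are the "same" element when all enabled
criteria hold: equal DR class; sequence agreement at one of three
stringencies (`exact-element`: half-sites and spacer letter-identical;
`half-sites-and-spacer-length`: spacer sequence free;
`class-only`); same compartment by rank; same orientation relative to
the cluster axis; and normalized intra-compartment positions within
`position_tolerance` (default 0.25 of compartment length).
`exact-element` is the default because the cross-species element printed
for all three amphioxus species is letter-identical; the looser levels
support sensitivity analyses. "Relative position within the cluster" is
stated only qualitatively in the motivating study; the
compartment + orientation + normalized-position operationalization and
its default tolerance are this package's choices and are recorded in the
run manifest.

Grouping is greedy and deterministic: the lexicographically smallest
species anchors; its elements are visited in cluster order (compartment,
normalized position, coordinate); for every other species the unused
candidate with the smallest positional discrepancy is taken; a group is
emitted only if *every* pair passes (transitive consistency, not a
spanning chain) and, under `require_all_species`, only with exactly one
member per species. The result is invariant under permutation of input
species — tested over all orderings. An optimal assignment would require
solving a matching problem; at realistic element densities the greedy
assembly is exact on the benchmark and trivially auditable.

## Consensus and information content

Conserved (or validated) elements of one DR class are fixed-structure
and therefore pre-aligned, so motif discovery is unnecessary: the
consensus is per-position nucleotide counting. Position *j* includes
nucleotide *x* iff count(x,j)/n > θ; θ = 0 (default) is the union
consensus, which provably matches every input site (closure). Sites of
different spacer lengths are summarised separately, per class. If θ
exceeds every frequency at some position, the set falls back to the
maximal-count nucleotides — never empty, and still anti-monotone in θ.
Information content per column is 2 + Σ p log₂ p bits from optionally
pseudocount-smoothed frequencies; the default pseudocount is 0 so that
small-sample profiles are reported as they are.

## Synthetic benchmark generator

The generator emulates a three-species comparison of a three-gene tandem
cluster. Defaults, chosen to mirror the motivating study conditions:
cluster spans 85 000 / 56 000 / 79 000 bp (first start codon to last stop
codon), 20 kb flanks on both sides (so the default survey window covers
the whole synthetic sequence), three plus-strand gene bodies each 15% of
the span, background GC 0.40 (AT-rich, as in cephalochordate genomes),
16 conserved elements with class tally 13 DR5 / 1 DR2 / 2 DR3 distributed
over all compartments in mixed orientations, and 5 single-species decoys
per species. Conserved element sequences are sampled from the canonical
pattern with uniform spacers; each is rejection-sampled until its bare
string contains exactly one canonical match (no internal or palindromic
self-matches) and is unique, which is what makes truth-table precision
and recall well defined. Planted intervals keep a ≥30 bp separation so
no scan window can bridge two planted elements without crossing
background.

With `clean_background` (default on) every accidental background match
is destroyed by resampling its background bases until the oracle-visible
hit set equals the planted truth, giving a benchmark where recall and
precision against truth are exactly measurable. With cleaning off, the
expected accidental-hit count under the i.i.d. background model
(per-offset match probability summed over spacers and strands, ≈2 per
125 kb sequence at GC 0.40) is reported alongside the output so
precision expectations are explicit.

All randomness flows from one integer seed through a single generator
stream; outputs are byte-identical per seed. The background is i.i.d. —
no repeats, no isochores, no k-mer structure — and planted conservation
is letter-exact with no evolutionary divergence (no substitutions or
indels between species). Passing the benchmark therefore demonstrates
correctness of enumeration, annotation arithmetic, grouping and
consensus logic; it does not demonstrate robustness to diverged
elements, repetitive DNA or assembly artefacts in real genomes.

## Pipeline and determinism

Stages are scan → annotate → conserve → consensus; each writes its table
(TSV with a commented header carrying tool version and config hash; BED6
for hits) so stages are independently re-runnable. Analysis stages are
seed-free; reruns with identical inputs and config are byte-identical,
and the YAML manifest records everything needed to re-execute a run. A
stage failure aborts with the stage named and leaves a `FAILED` marker
next to any partial outputs.

## Problem sizes used in the checks

The automated checks run the scanner–oracle comparison on 200 random
5 kb sequences at GC 0.3/0.4/0.5, strand symmetry on 100 random 1 kb
sequences, consensus closure/monotonicity on 1 000 random site sets, and
the full pipeline on the default ~125/96/119 kb three-species benchmark —
sizes at which the brute-force oracles remain exact and fast.

## Known limitations

* No mismatch-tolerant or PWM-threshold matching; elements diverged from
  the degeneracy sets are invisible by design.
* Ortholog ranks are user input; no synteny inference.
* The conservation tolerance and orientation requirement are defaults,
  not estimated quantities; sensitivity to them should be explored with
  the looser stringency settings.
* The generator does not simulate sequence evolution; conservation in
  the benchmark is exact by construction.
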