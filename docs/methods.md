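# Methods

## Coordinate conventions

All in-memory coordinates are 1-based and inclusive, matching both GFF3 and
AGP; any half-open arithmetic is internal to an operation and never
serialized. Readers reject invariant violations (a child feature outside
its gene span, an AGP tiling with overlaps or holes, a BLAST hit whose
alignment exceeds the stated sequence length) with the offending line
number rather than repairing them, and writers guarantee byte-stable round
trips (fixed attribute order `ID, Name, Parent`, then alphabetical; rows
sorted by object and coordinate). One deliberate dialect extension: AGP has
no column for placement confidence, so component rows may carry an optional
10th column with `uncertain_order` or `unanchored`; it is omitted for
certain placements, and the reader accepts 9 or 10 columns.

## Mate-pair filtering and junction calling

An alignment is usable as linking evidence iff its leftmost base lies
within `max_end_distance` (default 5000 bp, inclusive at the boundary) of
the nearer scaffold extremity, MAPQ ≥ 20, and XM ≤ 2, XO ≤ 1, XG ≤ 4. The
thresholds are the standard stringent bowtie2 post-filters for ~2 kb-insert
mate-pair libraries; "lower than 20 … discarded" is read as *keep iff
MAPQ ≥ 20*. The reason code names the first failed criterion in the order
end-distance, MAPQ, XM, XO, XG. End distance is measured from the leftmost
base; for reads spanning the window boundary this is the defined, if
arbitrary, choice — the filter is monotone in every threshold either way.
On a scaffold shorter than two windows a read can sit in both; the nearer
end wins, head on ties.

A cross-scaffold pair becomes a link labeled with the extremity (head/tail)
each read sits near, normalized so the lexicographically smaller scaffold
is first. Junction calling tallies links per scaffold pair by end-pair
geometry and emits the majority geometry when its count reaches
`min_support` (default 2 — the minimal reading of "multiple pairs",
configurable) **and** strictly exceeds all other geometries combined.
Discordant links are reported as `conflict` and set a review flag: this
replaces interactive inspection of multiply-connected scaffolds with a
deterministic rule plus an explicit worklist; flagged junctions still count
as evidence unless `--strict` is given.

## Chromosome anchoring

Per (scaffold, map) anchor: the linkage group is a majority vote over that
scaffold's markers in that map (an exact tie drops the anchor with a
warning), the position is the median cM of the majority group, and the
orientation signal is the sign of the slope of cM against scaffold
coordinate (`single` when there is one marker or one distinct cM value).
A scaffold's chromosome is the majority linkage group over its anchors,
ties broken by marker support then label.

Retention implements the multiple-evidence rule as a fixed point: start
from scaffolds anchored by ≥ 2 maps, then repeatedly admit scaffolds with
≥ 1 map and a junction to an already-retained neighbor assigned to the same
chromosome, until stable. Junctions to scaffolds on other chromosomes never
count.

Ordering: each map ranks its scaffolds by median cM; ranks are normalized
to [0, 1] (a lone scaffold gets 0.5) and the consensus position is the mean
over the maps that contain the scaffold. Ties break by scaffold length
descending, then name — deterministic and robust to maps of different
lengths, since no algorithm is prescribed for combining maps. Adjacent
scaffolds whose order is contradicted by any single map are both flagged
`uncertain_order` unless a junction fixes the adjacency. Junctions form a
confirmation graph only; cycles are reported and the map order stands.

Orientation: the chromosome runs in the direction of increasing cM (taken
from the maps as simulated/ordered; a per-chromosome flip is a caller-side
reversal of the ordered list). A scaffold with an increasing gradient is
`+`, decreasing is `-`; multiple maps vote, an exact vote tie leaves the
scaffold open. Junction geometry orients scaffolds without a usable
gradient: for an adjacent pair with A upstream, A is `+` iff the junction
names A's tail, B is `+` iff it names B's head. A junction conflicting with
a gradient loses, and the conflict is logged. Everything else stays `?`.

Telomere scanning counts the maximal tandem run of the motif (default
TTTAGGG, the plant consensus; window 10 kb; ≥ 10 copies — all configurable)
on both strands of a terminal window. Convention: on the chromosome forward
strand the 5' end carries the motif's reverse complement and the 3' end the
motif itself; a hit at the outward end of an unoriented terminal scaffold
sets its orientation (source `telomere`), while map/junction-derived
orientations are only confirmed or contradicted in the report, never
overwritten.

AGP building inserts 100 bp gap rows of type U (unknown size), linkage
`yes`, evidence `paired-ends;map` between components — the AGP-standard
unknown-gap convention, since no gap size is knowable from maps. `chr00`
concatenates all non-retained scaffolds by descending length with the same
gap rows.

## Liftover

For a `+` placement, scaffold coordinate = `component_beg + (coord −
object_beg)`; for `-`, `component_end − (coord − object_beg)`; composition
through the new AGP inverts this. A gene is lifted atomically: both gene
endpoints and every child endpoint must map onto one scaffold with one
placement; any failure (gap coordinate, endpoints on two scaffolds, child
escaping the lifted gene span, scaffold absent from the target) reports the
whole gene (`failed_gap_span` / `failed_unplaced`) rather than emitting a
partial model. When the placement orientations differ the strand flips,
start/end swap to keep start ≤ end, and children re-sort by new
coordinates; landing in `chr00` gets its own status. Lifting is exactly
length-preserving and an involution (old→new→old is the identity for every
lifted feature), both enforced by tests against a per-base enumeration
oracle. Features abutting gap edges are failed explicitly — no nudging.

## Reconciliation

Grouping connects gene models whose genomic spans overlap by ≥ 1 bp on the
same seqid and strand, taking the transitive closure via a coordinate sweep
(exon-level overlap is deliberately not the default: the comparison is of
gene positions). Group categories by per-source signature: `single` (one
model), `pair`/`triple` (one model from two/three sources), `multi` (any
source contributes ≥ 2).

HO/QO: drop hits with e-value ≥ 1e-20 (strict), keep the best hit per
subject (lowest e-value, then highest bitscore — multiple HSPs per subject
would double-count evidence), sort by (e-value, −bitscore, subject id),
truncate to the 30 best. HO counts hits with subject coverage strictly
> 0.9, QO the same for query coverage. The qualitative labels use
"high = count > half of n_hits" (configurable); zero retained hits is
`dubious`.

Selection: curated models beat everything. Singletons are kept without
analysis. For one-model-per-source groups, "highest HO and QO" is
operationalized as max min(HO, QO) — the parenthetical "(> 90%)" in that
rule is read as the coverage threshold, not a score floor (a `--min-score`
option annotates decisions below a floor for anyone preferring the other
reading). Members with identical predicted proteins (identical CDS
intervals on the shared assembly) are first collapsed keeping the longer
combined UTR. A tie on min(HO, QO) with different tuples falls back to
max(HO + QO), then source priority (default cribi > vcost > refseq); an
exact tuple tie goes straight to priority. Multi groups pre-reduce nested
same-source models (keep the largest — observed nesting is always full
containment), then enumerate maximal non-overlapping configurations
(maximal independent sets of the overlap graph) and keep the configuration
maximizing Σ min(HO, QO); ties prefer more members (the shorter,
possibly-incomplete split over the possibly-chimeric merge) and are flagged
`manual_review`; residual ties fall to memberwise source priority.
Enumeration beyond 10,000 configurations falls back to a flagged greedy
pass. Flagging is a feature: most real groups need eyes, and the report
says exactly which and why.

The merge concatenates kept members, revalidates them, reports (never
repairs) any same-strand overlap between kept members of different groups,
and tabulates per-category group counts before/after resolution with the
invariant total = Σ categories. Locus IDs follow the community
prefix + 2-digit chromosome code + `g` + 5-digit per-chromosome ordinal
scheme, chr00 = code 00, ties at one start broken by end then `+` first;
mRNA IDs append `_t` + 3-digit ordinal (the transcript-suffix convention is
this package's choice).

## Synthetic data

The simulator emulates the study conditions at desk scale: 3 chromosomes of
4–6 scaffolds of 8–14 kb, six parental maps, 2 kb inserts, 100 bp reads,
~90 genes, TTTAGGG telomeres — structural constants match the emulated
project, sizes are deliberately two to three orders below it so the suite
runs in seconds. Marker cM = chromosome position × 0.001 cM/bp × a per-map
scale (0.8–1.2) + N(0, 0.05) jitter, markers ≥ 1 kb apart so jitter cannot
flip within-scaffold gradients; each scaffold is anchored by two guaranteed
maps plus others at 60%. Mate pairs: 5 concordant pairs per true adjacency
plus 4 decoys each violating exactly one filter. Annotation errors: 10%
missing (source 1), 10% chimeric merges of adjacent same-strand pairs
(source 2, which also widens UTRs on clean copies so the longer-UTR rule is
exercised), 10% splits (source 3), 5% curated; hit tables are constructed
so true models read complete (both coverages ≈ 0.97), chimeras
chimeric-suspect (full subjects, half-covered queries) and fragments
truncated (full queries, ~0.45-covered subjects). All rates were fixed once
as plausible annotation-error magnitudes. Each sub-simulator draws from its
own seed-derived stream, so changing one stage's settings never perturbs
another's output; a fixed seed gives byte-identical files.

What the simulator does **not** model — realistic base composition,
repeats, read errors, marker segregation distortion, partial-overlap gene
nesting, paralog cross-hits in the homology tables — bounds what passing
tests show: they certify the algorithms and their contracts, not
performance on real libraries, where repeat-induced mis-mappings and
ambiguous homology are the dominant error sources.

## Numerical and degenerate-input choices

Strict inequalities wherever the rules say "more than" (coverage > 0.9,
e-value < 1e-20, majority > rest). Median over an even marker count is the
midpoint mean. Empty inputs return empty outputs (no junctions from no
links, empty GFF3 with only the version pragma, all-zero summaries).
A `?` orientation is serializable in AGP but refuses to enter GFF3 output —
strand must be resolved first. The gradient slope uses the covariance sign
only; exactly zero with distinct cM values is `flat` and contributes no
orientation.

## Known limitations

Junctions are pairwise only — no scaffolding through chains of unanchored
scaffolds (by design: the retention rule requires a map anchor). Ordering
ignores junction adjacency when maps agree, so a systematic multi-map error
cannot be corrected by mate pairs. The liftover requires an unchanged
scaffold set; split or re-joined scaffolds are out of scope. Reconciliation
compares gene spans, not exon chains, and does not attempt splice-variant
merging.
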