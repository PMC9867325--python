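# Methods

## The model

A CRISPR array is modelled as an alternating run of direct repeats (DRs)
and spacers: `R s R s ... R`, with `n` repeats and `n − 1` spacers. The
repeats are near-identical copies of one consensus; spacers are unique
sequences acquired from mobile genetic elements (MGEs). Three readouts
follow from this structure: the repertoire census (how many spacers, how
many unique), the spacer→protospacer map into an MGE database (which
encounters the array records, and how degraded the record is, measured
in mismatches), and position-based recency (new spacers enter at the
leader end). Two further analyses concern lysogeny: spacers matching the
host's own chromosome (self-targeting spacers, STS, usually inside an
integrated prophage) and the attachment core duplicated at prophage
boundaries. Finally, a phage collection is dereplicated by clustering
six marker proteins and reading each phage's class combination as a
barcode.

All internal coordinates are 0-based half-open on the forward strand;
GFF3 output converts to 1-based inclusive at serialization only.

## Array detection

Detection seeds on exact repeated words (default `seed_k = 8`) whose
spacing lies within one repeat+spacer period
(`[dr_len_min + spacer_len_min, dr_len_max + spacer_len_max]`),
chains colinear occurrences, and then determines the repeat extent as
the maximal run of columns conserved across the chained instances. A
column counts as conserved when at most `max(1, ⌊n/10⌋)` of the `n`
instances deviate from the majority base. Because a chain may hold only
a few instances (a weak quorum), boundaries are re-derived after
terminal rescue from the full repeat stack: edge columns failing the
deep quorum are shaved, conserved columns just outside are annexed,
within the configured length windows. Terminal repeats whose seed word
was mutated are rescued as full consensus copies; partial terminal
copies down to 50% of the consensus length are recorded as repeats (the
gap before them is an ordinary spacer, preserving alternation). Isolated
single DR copies — the footprint of a deleted array — are reported
separately by `find_orphan_repeats`, never as arrays.

Candidate solutions that overlap are reduced to one per locus: most
repeats first, then lowest total consensus mismatch, then leftmost. An
array is rejected when its spacers' mean pairwise identity exceeds
`max_spacer_pair_identity` (default 0.60) — that is a tandem repeat, not
a CRISPR array. Defaults (`dr` 23–47 nt, spacers 20–60 nt, ≥3 repeats,
per-repeat mismatch ≤20% of the consensus length) bracket the DR sizes
(29–36 nt) and spacer sizes (29–33 nt) of the *Oenococcus* arrays with
margin; every threshold is exposed in `ArrayFinderParams`.

Orientation: a cas-operon hint adjacent to one flank places the leader
on that side; otherwise a degenerate terminal repeat (more consensus
mismatches than the interior mean, or truncated) marks the trailing end.
With neither signal the leader defaults to the left end and the array is
flagged `orientation: unresolved`. Spacer indices count 1-based from the
leader-proximal end.

Known limitation: when a flank column happens to agree across all
repeat instances, the true boundary is genuinely ambiguous and the call
can be off by one — the classic ±1 nt uncertainty of repeat-boundary
callers. The probability decays as 4^−(n−1) per boundary, so it is
negligible for arrays of ≥8 repeats (real arrays here have 16–103).

## Census conventions

Spacer identity everywhere in the census is exact string equality after
reverse-complement folding (`min(s, revcomp(s))`), which makes totals,
duplicated blocks and overlap matrices invariant under
reverse-complementing the genome. Ratios are printed round-half-up to 2
decimals. A duplicated block is a maximal contiguous spacer run
occurring at ≥2 non-overlapping positions; blocks wholly explained by a
longer reported block are suppressed; counting non-overlapping
occurrences makes `[a,a,a]` one block `(a)×3` rather than `(a,a)×2`.

## Matching semantics

Each spacer is aligned end-to-end (query-global) against target infixes
on both strands. For the default, ungapped mode this is an exhaustive
full-length sliding comparison — every qualifying locus is found, not a
heuristic subset — so identity of a hit is exactly
(L − Hamming distance)/L and the acceptance rule
`identity ≥ 0.85 ∧ coverage ≥ 0.90` reduces to
`mismatches ≤ ⌊0.15·L⌋`: 4 mismatches for the 29–33 nt spacers that
match anything here. The query-global choice (rather than local
alignment) is deliberate: local alignment with unit scores silently
clips terminal mismatches, which inflates identity and makes the
per-hit mismatch count — the quantity interpreted downstream —
ill-defined.

Gapped matching (`allow_gaps=True`) adds an affine-gapped rescue pass
(match +1, mismatch −1, gap open −2, extend −1; gap columns count toward
the alignment length like mismatches). It is off by default because a
protospacer differing by k substitutions can admit a gapped alignment
with fewer edits, blurring the substitution-count readout; with gaps on,
rescue happens at each target's optimal edit-distance locus, so
suboptimal gapped loci can be missed. Per (spacer, target, strand,
locus) only the best hit is kept (highest identity, then leftmost); all
qualifying loci are reported, not best-only.

Flanks of `flank_len` (default 10) nt are read in protospacer
orientation and padded with `.` at contig ends. PAM inference uses the
`k` (default 3) positions adjacent to the protospacer: a position is
resolved when its majority base reaches `agreement` (default 0.75); the
motif is the maximal resolved run touching the protospacer. The 3/0.75
defaults reflect that a 3-nt upstream motif called from a handful of
hits is the realistic use case.

Recency cutoffs: leader-proximal at p ≤ 0.20 and leader-distal at
p ≥ 2/3. The proximal cutoff is the largest round value that separates
index 9 of 57 (p ≈ 0.143, proximal) from index 15 of 57 (p = 0.25, not
proximal); the distal cutoff is a symmetric convention. Both are
configurable.

## Self-targeting and the att core

All array spacers are searched against the full host genome; hits
overlapping any detected array interval, padded by one repeat length to
absorb boundary jitter, are the spacers' own loci and are excluded.
Remaining hits are annotated with every overlapping feature
(any-overlap, ≥1 shared base). Prophage regions are caller-supplied
annotations; prophage prediction is out of scope. The att core is the
longest exact direct repeat with one copy inside each boundary window
(default ±200 nt around the prophage start and end, minimum 12 nt,
ties to the leftmost copies) — an exhaustive longest-common-substring
computation, not a heuristic.

## Typing

Within one category, proteins are clustered greedily: process by
descending length (ties by id), join the first centroid with global
identity strictly above the threshold (default 0.90), else found a new
class. Global identity is matched columns over total columns of an
edit-distance-optimal global alignment. Greedy centroid clustering was
chosen over graph clustering for determinism and auditability; class
labels are numbered by descending size. Doc reduces to presence/absence;
a missing category yields an "absent" slot; a phage with two proteins in
one category is an error (pre-split such genomes). Conserved blocks per
class (centroid-coordinate runs identical across members) are emitted
for downstream primer design, which is itself out of scope.

## The simulator

`simulate_host`/`simulate_phage_db` generate i.i.d. backgrounds at a
configurable GC (default 0.40, typical for lactic acid bacteria), plant
arrays/prophage/protospacers/protein families with exact bookkeeping,
and emit the truth alongside. One integer seed drives independent
sub-streams per element, so adding a target leaves earlier targets
byte-identical. Substitution counts are exact Hamming distances
(positions without replacement, base forced to change).

Two constructions keep the planted truth well-defined rather than
merely probable: columns immediately flanking planted repeats are
resampled when they would pass the detector's conservation quorum by
chance (otherwise the planted boundary itself would be ambiguous in a
few percent of 5-repeat arrays), and the bases adjacent to the att-core
copies are resampled when equal (otherwise the duplicated core would
extend by chance in ~44% of genomes). Default scales — arrays of 10–31
repeats, a 9 kb prophage in a 60 kb chromosome, 34 targets of 8 kb,
193-phage protein panels — mirror the study system's design while
keeping the full test suite fast.

What the simulator does **not** emulate: real phage genome architecture
(gene order, codon usage), repeat-rich chromosomal backgrounds, array
turnover over time, indel-containing protospacers (plants are
substitution-only) and proteins with indels. Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
planted model, not calling accuracy on arbitrary real genomes; analyses
of the original GenBank set run through `crisprtrace.replication` on a
user-supplied copy.

## Numerical choices and degenerate inputs

Consensus column ties break to the alphabetically smallest base.
Spacers or repeats containing N are flagged and excluded from matching
(mismatch counting against N is undefined); N is otherwise legal in
genomes. Single-spacer arrays get p = 0 (leader-proximal). Empty hit
sets yield an empty PAM marker, never an exception. The whole pipeline
is deterministic for fixed inputs and configuration; `run_all` output
files are byte-identical across reruns.
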