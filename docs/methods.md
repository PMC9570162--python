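# Methods

## Problem

Given one reference sequence and a set of assembled query contigs,
determine where each contig sits on the reference, in which orientation,
and how completely the reference explains it — and present the answer as a
dot plot a biologist can read at a glance. The intended inputs are
genetically close sequences: contigs from an assembly of the same or a
closely related organism. The method is exact-match only; it is a
placement and visualization tool, not a variant-tolerant aligner.

## Model and procedure

### Exact matching via k-mer anchors

The reference is indexed by every one of its k-mers; a k-mer containing
`N` is never indexed, and query k-mers containing `N` never probe the
index, so an uncertain base breaks any match running through it. Each
query is scanned twice: once as given (forward strand) and once as its
reverse complement (reverse strand). Every (query k-mer, reference
position) pair found in the index is an anchor.

Anchors whose diagonal `ref_pos − query_pos` (computed on the scanned
orientation) is constant and whose query offsets step by one merge into a
single segment spanning `run + k − 1` bases. Because a common substring of
length `L ≥ k` contributes exactly the `L − k + 1` anchors of its
diagonal, merged segments are precisely the maximal exact matches of
length ≥ k — the property the test suite checks against a brute-force
diagonal scanner. Reverse-strand segments are stored in forward-query
coordinates (`q_fwd = L − q_scanned_end`) with a strand flag, so plotting
can draw them as descending diagonals without re-deriving orientation.

A display threshold `t ≥ k` (default `t = k`) discards segments shorter
than `t` bases. Raising `t` only removes segments; raising `k` only
removes matches (every match at `k+1` is a match at `k`), which is why
reference coverage is monotone non-increasing in `k`.

Repeated k-mers keep *all* their reference positions, and a query k-mer
matching several positions emits every pair: repeat regions must show all
their off-diagonal structure in the basic plot.

### Greedy tiling (optimal alignment)

Basic alignment leaves overlapping explanations of the same reference
region. The optimal step selects a subset of segments pairwise disjoint on
the reference by a greedy sweep: among the left-most unresolved segment
and everything overlapping it on the reference, keep the longest; discard
all segments overlapping the winner; repeat on the remainder. Length ties
break by smaller reference start, then forward strand, then smaller query
start — an arbitrary but fixed rule that makes runs reproducible. Losing
segments are removed whole, never trimmed, and only reference-axis overlap
is resolved; kept segments of one query may still overlap on the query
axis.

Conflicts are resolved **jointly across all queries**: the segments of
every query are pooled before the sweep, and the kept set is regrouped per
query afterwards. This matters. With per-query-only tiling, a chance k-bp
exact match between a query and an unrelated part of the reference (for a
50 kb reference and 6 kb queries at k = 15, a few such matches are
expected per run) would be kept whenever it is reference-disjoint from the
query's main placement, inflating that query's mapped bases — in the clean
split-and-shuffle experiment, above its own length. Joint resolution lets
the query that truly owns a reference region (with a long segment) displace
other queries' chance matches, keeping mapped ≤ length in practice and the
similarity a meaningful percentage. `select_optimal` still exposes the
single-query sweep for callers that want it; the pipeline uses the joint
form.

This is a greedy heuristic, not weighted interval scheduling by dynamic
programming; the greedy rule *is* the method, and the shipped behaviour is
checked against a naive best-first re-implementation, not against a DP
optimum.

### Similarity and rearrangement

A query's similarity is `100 × mapped_bases / query_length`, **truncated**
(floored) to three decimal places, computed in integer arithmetic
(`100000 · mapped // total`, then divided by 1000) so no floating-point
rounding can nudge the last digit. Truncation rather than rounding is
deliberate: it is the only rule consistent with pooled ratios like
576,855 / 576,874 printing as 99.996 while 72,098 / 72,100 prints as
99.997. The overall similarity pools numerators and denominators before
truncating; it is not the mean of the per-query values.

Queries are ranked by similarity descending, ties by mapped bases
descending, then input order (the sort is stable). The ranked order is the
bottom-to-top stacking order of the rearranged plot and the record order
of the rearranged FASTA.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `k` | 15 | bp | anchor size; 10–50 recommended (warning outside). Smaller k = more sensitive and slower; larger k = faster and blinder. |
| `threshold` | `k` | bp | minimum segment length displayed/kept; must be ≥ k. |
| `line_width` | 1.2 | pt | segment stroke width. |
| `point_size` | 2.0 | pt | endpoint marker size. |
| formats | pdf | — | also png, ps, svg. |

## Coordinate conventions

Internally all intervals are 0-based half-open. Text outputs (the optimal
segment listing) print 1-based inclusive start positions, matching the
convention biologists expect from genome coordinates. In the optimal
listing, the first numeric column is the 1-based start on the original
query ("initial position") and the second the 1-based start on the
reference ("aligned position"); reverse-strand subsequences are emitted
reverse-complemented so the file reads in reference orientation.

## Synthetic validation data

`contigplot.fixtures` generates the self-check this kind of tool is judged
by: a uniform i.i.d. A/C/G/T reference of given length, partitioned into
`n` fragments (the first `n − 1` of `chunk_size` bases, default
`floor(L/n)`, remainder last — `chunk_size` is explicit because real
datasets sometimes use a fixed chunk rather than an even split), with the
fragment order shuffled by a seeded uniform permutation. A clean run must
re-place every fragment; the suite asserts overall similarity ≥ 99.99%
across a 20-seed panel at 50 kb / 8 fragments, and the same at a
576,874 bp / 72,100 bp-chunk scale.

What this emulates — and what it does not: fragments are exact substrings,
so passing says the indexing, merging, strand handling, tiling and
bookkeeping are correct end to end. It says nothing about sequencing
error, indels, diverged references or compositional bias (real genomes
have repeat families far above Poisson expectation); on such data the
exact-match segments simply shorten and similarity drops, which is the
intended readout, not a failure mode.

Problem sizes in the default suite (50 kb pipeline runs, ≤ 2 kb oracle
pairs, 20 kb monotonicity fixture) were chosen so the whole suite runs in
well under a minute while still crossing every code path at a scale where
chance k-mer collisions actually occur.

## Numerical and degenerate-input choices

- Lowercase input is accepted and uppercased; `U` maps to `T`; IUPAC
  ambiguity codes map to `N`; `-` gap characters are stripped with a
  warning; any other character is an error.
- A query shorter than k aligns to nothing (empty result, not an error).
- An empty segment list tiles to an empty tiling with zero mapped bases;
  `similarity_percent` rejects `total ≤ 0` and `mapped > total` outright
  rather than clamping.
- SVG output pins matplotlib's hash salt and drops the date metadata so
  identical inputs give byte-identical files.

## Known limitations

- Exact matches only: a single substitution splits a segment; there is no
  mismatch tolerance, gapped extension or scoring matrix.
- The greedy tiling is not guaranteed to maximize total mapped bases; a
  long segment can displace two medium ones whose sum is larger.
- Per-query mapped bases can in principle exceed query length for
  pathological repeat structures even under joint tiling (reference-
  disjoint segments may reuse the same query interval); the similarity
  computation then fails loudly rather than reporting a percentage above
  100.
- Memory: the k-mer index holds one dict entry per distinct reference
  k-mer; hundreds of megabases will be slow and large. The tool targets
  plastid/bacterial/fungal-scale references.
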