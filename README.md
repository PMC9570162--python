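# contigplot

Dot-plot alignment of assembled contigs against a reference genome, built on
exact k-mer matching. `contigplot` answers the question an assembler leaves
open: *where do my contigs sit on a genetically close reference, in what
order, and on which strand?* It aligns one or more query FASTA files to a
single reference, resolves competing matches into a non-overlapping tiling
of the reference, ranks queries by similarity, and renders mummerplot-style
dot plots together with machine-readable text outputs.

## The method

Three stages, all exact (no mismatches or gaps):

1. **Basic alignment.** The reference is indexed by all of its k-mers
   (default k = 15; k-mers containing `N` are skipped). Each query is
   scanned on both orientations — the forward sequence and its reverse
   complement — and every shared k-mer yields an anchor `(ref_pos,
   query_pos)`. Anchors on the same diagonal (`ref_pos − query_pos`
   constant) at consecutive offsets merge into a maximal exact-match
   segment of length `run + k − 1`. Segments shorter than a display
   threshold `t ≥ k` (default `t = k`) are dropped. Forward matches plot
   as ascending blue diagonals, reverse matches as descending red ones.

2. **Optimal alignment.** Segments compete for reference territory
   (repeats, both-strand hits, chance matches). A greedy sweep walks the
   reference left to right: take the left-most unresolved segment, gather
   everything overlapping it, keep the longest, discard all segments
   overlapping the winner, repeat. Conflicts are resolved jointly across
   all queries, so each reference region is explained by the single best
   segment any query offers. The kept segments are pairwise disjoint on
   the reference; their total length is the query's *mapped bases*.

3. **Rearrangement.** Each query's similarity is
   `100 × mapped / length`, truncated (not rounded) to three decimals.
   Queries are re-stacked most-similar first, bottom to top, and written
   out in that order.

## Worked example

Generate a self-validation dataset — a 50 kb random reference split into 8
fragments and shuffled — then align it back:

```sh
contigplot simulate --length 50000 --fragments 8 --seed 7 --out-dir demo
contigplot align --reference demo/reference.fasta --query demo/query.fasta \
    --kmer 15 --format pdf,png --out-prefix demo/job
```

The align command prints the summary table (also written to
`demo/job_summary.tsv`):

```
Name	Length(bp)	Mapped(bp)	Similarity(%)
ref_seed7_T3	6250	6250	100.000
ref_seed7_T5	6250	6250	100.000
ref_seed7_T4	6250	6250	100.000
ref_seed7_T1	6250	6250	100.000
ref_seed7_T0	6250	6250	100.000
ref_seed7_T7	6250	6250	100.000
ref_seed7_T2	6250	6250	100.000
ref_seed7_T6	6250	6250	100.000
Total	50000	50000	100.000
```

Every shuffled fragment is an exact substring of the reference, so the
tiling places all 50,000 bases: each row's mapped count equals its length
and every similarity is 100.000. On real data (sequencing error, diverged
references) mapped < length and the rows order the contigs by how much of
each the reference explains.

Alongside the table the run writes, per requested image format:

- `job_basic.*` — every merged exact match (repeats included),
- `job_optimal.*` — the non-overlapping tiling,
- `job_rearranged.*` — the tiling with queries stacked most-similar first,
- `job_optimal.txt` — one record per tiling segment:
  `>query_id<TAB>query_start<TAB>ref_start` (1-based) followed by the
  strand-normalized subsequence; concatenated in file order these
  reconstruct the reference-ordered assembly,
- `job_rearranged.fasta` — full query sequences, most similar first, with
  a `similarity=` annotation.

The same machinery is importable as a library:

```python
from contigplot import align_queries, overall_similarity, random_sequence
from contigplot import split_reference, shuffle_fragments

ref = random_sequence(50_000, seed=42, record_id="ref")
queries = shuffle_fragments(split_reference(ref, 8), seed=7)
results = align_queries(ref, queries, k=15, threshold=15)
print(overall_similarity(results))   # 100.0
```

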