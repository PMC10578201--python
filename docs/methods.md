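# Methods

This note records the model, parameter choices, and numerical conventions
behind `homopart`, plus known limitations. All empirical figures quoted here
are computed by the test suite or by `scripts/acceptance.py`.

## Pairwise alignment

Global (Needleman–Wunsch) alignment with affine gap costs via the
three-state Gotoh recursion: state `M` (match/mismatch), `Ix` (gap in the
second sequence), `Iy` (gap in the first). A gap of length `L` costs
`gap_open + L·gap_extend` with defaults `gap_open = 10.0`,
`gap_extend = 0.5`; end gaps are penalized like internal ones. Substitution
scores come from BLOSUM62 (protein) or EDNAFULL/NUC.4.4 (nucleotide) as
shipped with Biopython; custom matrices can be supplied, with missing
symbols scored 0.

Identity is the number of identical aligned columns divided by the alignment
length (default) or by the length of the shorter sequence (option). Because
co-optimal alignments can differ in identity, the traceback is made
deterministic with a fixed state preference (match > gap-in-second >
gap-in-first) and pairs are canonicalized by sequence id before alignment,
so identity(a, b) = identity(b, a) exactly.

Correctness evidence: the tests compare score and identity against
exhaustive enumeration of *all* global alignments for hundreds of random
short pairs (both alphabets, both denominators), and against Biopython's
`PairwiseAligner` configured for the same gap convention. The dynamic
program is JIT-compiled with numba (`cache=True`); one length-150 pair
aligns in ~0.15 ms, so a 200-sequence all-vs-all (19,900 pairs) takes
roughly 3 s on one CPU core.

## Graph, clustering, assignment

Distances are `d = 1 − identity`. The similarity graph keeps an edge exactly
when identity **strictly exceeds** the threshold, i.e. `d <
1 − threshold`; pairs at exactly the threshold are acceptable across folds.

Restricted single-linkage clustering processes edges in ascending distance
(ties broken by the canonical id pair) through a union-find structure, and
skips a merge if the merged cluster would strictly exceed `N/k` sequences in
total or per class label (real-valued caps). With `k = 1` the caps are
vacuous and the result provably equals the connected components (tested
against `networkx` on random graphs). Clusters are emitted in first-touch
order over the sorted edge stream, then untouched singletons in input order,
which fixes downstream determinism.

Cluster-to-fold assignment is greedy: clusters are visited in descending
count of their most frequent label, and each goes to the fold where that
label is currently least represented (ties: smaller fold, lower index).

For train/test/validation splits, the data is clustered into `n` groups,
where `n` is the smallest integer (≤ 1000) making `n·test` and `n·val`
integral; the `n(1 − test − val)` most interconnected groups (greedy seed =
most total cross-group edges, grown by edges into the selection) are merged
into train, then test is drawn the same way from the remainder.

## Separation

Each iteration `i` (starting at 1) first runs a move pass in input order: a
sequence relocates to the fold containing the plurality of its neighbors if
that count strictly beats the count in its own fold (ties: lower fold
index). Then `c` is the number of sequences that still have cross-fold
neighbors, and the `max(1, floor(c·log10(i/100)) + 1)` worst offenders
(most cross-fold neighbors, ties by id) are removed. The schedule is
deliberately conservative for the first 100 iterations (one removal each)
and escalates afterwards so hard instances still terminate. The loop ends at
`c = 0`; if a fold is then empty, the dataset cannot support `k` folds at
this threshold and a `FoldLossError` is raised (downgradable to a warning).

With binary priorities, removal first runs restrained — candidates only from
the low-priority pool, `c` counted over that pool — and proceeds
unrestrained (counter carried over) only if conflicts persist among
high-priority sequences. Moves always apply to everyone.

The final assignment is audited by a function that realigns every retained
cross-fold pair from scratch; it shares no state with the graph used for
partitioning.

## Synthetic data model

The generator draws one random ancestor per family and derives members by
independent per-site substitution (to a different residue) with probability
`p`; the expected within-family identity of two members is
`(1 − p)² + p²/(q − 1)` for alphabet size `q`, ≈ 0.90 at `p = 0.05` for
DNA — comfortably above a 0.5 threshold, giving dense within-family graphs.
An optional indel rate perturbs lengths. The reference benchmark is 40
families × 5 members, length 150, nucleotide, threshold 0.5, `k = 5`.

**Realism limits.** Substitution-only evolution with uniform rates is far
simpler than real sequence families (no rate heterogeneity, domain
structure, or fragmentary sequences). More importantly, *unrelated* random
DNA is not dissimilar under a global aligner: random 150-nt pairs score a
mean identity around 0.41 under EDNAFULL with these gap costs, and across
~20,000 pairs the maximum reaches ≈ 0.5–0.55. A 0.5 nucleotide threshold
therefore sits near the random-background tail, so a handful of genuine
between-family edges appear and force removals: the benchmark retains
93–94% of sequences, not 100%. This is a property of global alignment
statistics on short DNA, not an artifact of the implementation (the edges
in question are confirmed by an independent aligner). Protein thresholds
(e.g. 0.25–0.3 under BLOSUM62) sit further from their random background.

## Problem sizes and budgets

The shipped tests and the acceptance script run at 200 sequences × length
150 (≈ 20k alignments, ~5 s end to end including clustering, separation,
baselines, a TVT split, and the full realignment audit). Alignment cost is
quadratic in both sequence count and length; for datasets beyond ~10⁴
sequences, precomputed edge lists from a faster heuristic aligner can be
supplied via `--edges`.
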