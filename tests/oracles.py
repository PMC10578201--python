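"""Independent reference implementations used only to check the package.

These deliberately take the slow, obviously-correct route: exhaustive
enumeration of all global alignments, brute-force subset search for minimum
removals and maximum independent sets, and Biopython's PairwiseAligner as a
second alignment engine.
"""

from __future__ import annotations

import itertools
from functools import lru_cache


def enumerate_global_alignments(len_a: int, len_b: int):
    """Yield every global alignment as a tuple of column moves.

    Moves: 'D' (residue vs residue), 'U' (residue of a vs gap),
    'L' (gap vs residue of b).
    """

    def rec(i, j, cols):
        if i == len_a and j == len_b:
            yield tuple(cols)
            return
        if i < len_a and j < len_b:
            yield from rec(i + 1, j + 1, cols + ["D"])
        if i < len_a:
            yield from rec(i + 1, j, cols + ["U"])
        if j < len_b:
            yield from rec(i, j + 1, cols + ["L"])

    yield from rec(0, 0, [])


def score_alignment(a: str, b: str, moves, score_fn, gap_open: float, gap_extend: float):
    """Affine-gap score of one explicit alignment.

    A gap run of length L costs gap_open + L * gap_extend; end gaps count.
    Returns (score, n_identical, alignment_length).
    """
    score = 0.0
    n_id = 0
    i = j = 0
    prev = "D"
    for move in moves:
        if move == "D":
            score += score_fn(a[i], b[j])
            if a[i] == b[j]:
                n_id += 1
            i += 1
            j += 1
        else:
            score -= gap_extend if move == prev else gap_open + gap_extend
            if move == "U":
                i += 1
            else:
                j += 1
        prev = move
    return score, n_id, len(moves)


def best_alignment_by_enumeration(a: str, b: str, score_fn, gap_open, gap_extend):
    """Optimal score over ALL global alignments, plus the identity-count range
    among co-optimal alignments. Tractable for len <= 8."""
    best_score = None
    id_counts = set()
    lengths = {}
    for moves in enumerate_global_alignments(len(a), len(b)):
        s, n_id, length = score_alignment(a, b, moves, score_fn, gap_open, gap_extend)
        if best_score is None or s > best_score + 1e-9:
            best_score = s
            id_counts = {n_id}
            lengths = {n_id: {length}}
        elif abs(s - best_score) <= 1e-9:
            id_counts.add(n_id)
            lengths.setdefault(n_id, set()).add(length)
    return best_score, id_counts, lengths


def maximum_independent_set_size(nodes, edges) -> int:
    """Exact MIS size by subset enumeration (<= ~15 nodes)."""
    nodes = list(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    best = 0
    for mask in range(1 << len(nodes)):
        ok = True
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            if adj[i] & mask:
                ok = False
                break
            m &= m - 1
        if ok:
            best = max(best, mask.bit_count())
    return best


def minimum_separating_removal(nodes, edges, partition_of) -> int:
    """Smallest number of node deletions after which no remaining edge
    crosses partitions; exhaustive over removal subsets (<= ~10 nodes)."""
    nodes = list(nodes)
    cross = [(u, v) for u, v in edges if partition_of[u] != partition_of[v]]
    if not cross:
        return 0
    for size in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, size):
            removed = set(subset)
            if all(u in removed or v in removed for u, v in cross):
                return size
    return len(nodes)
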