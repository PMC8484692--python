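"""Independent oracle implementations used by the test suite.

Everything here is deliberately written straight-line, separate from the
package's code paths, so tests compare two independent routes to the same
answer.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# QC cascade: straight-line re-implementation of the seven rules

def qc_oracle_fates(pairs, cfg) -> list[tuple[str | None, str | None]]:
    """Per-mate fate for each pair: None = kept, else the filter name."""

    def phred(q):
        return [ord(c) - 33 for c in q]

    def hits_decoy(seq, index, k, min_hits):
        if index is None or len(seq) < k:
            return False
        kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
        t = min_hits if min_hits is not None else math.ceil(len(kmers) / 2)
        return sum(1 for km in kmers if km in index) >= t

    def adapter_cut(seq, adapter, min_ov, max_err):
        for i in range(len(seq)):
            ov = min(len(adapter), len(seq) - i)
            if ov < min_ov:
                break
            mism = sum(1 for a, b in zip(seq[i:i + ov], adapter[:ov]) if a != b)
            if mism <= int(max_err * ov):
                return i
        return None

    def mate_fate(seq, qual, adapter, min_ov):
        if "N" in seq:
            return "n_bases", seq, qual
        if hits_decoy(seq, cfg.phix_index, cfg.decoy_k, cfg.decoy_min_hits):
            return "phix", seq, qual
        cut = adapter_cut(seq, adapter, min_ov, cfg.adapter_max_error_rate)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
        qv = phred(qual)
        end = len(qv)
        while end > 0 and qv[end - 1] <= cfg.tail_quality_cutoff:
            end -= 1
        seq, qual = seq[:end], qual[:end]
        if len(seq) < cfg.min_length:
            return "length", seq, qual
        if qual and sum(phred(qual)) / len(qual) <= cfg.min_mean_quality:
            return "mean_quality", seq, qual
        if not qual:
            return "mean_quality", seq, qual
        if hits_decoy(seq, cfg.host_index, cfg.decoy_k, cfg.decoy_min_hits):
            return "host", seq, qual
        return None, seq, qual

    fates = []
    for p in pairs:
        f1, _, _ = mate_fate(p.seq1, p.qual1, cfg.adapter_fwd, cfg.adapter_min_overlap_fwd)
        f2, _, _ = mate_fate(p.seq2, p.qual2, cfg.adapter_rev, cfg.adapter_min_overlap_rev)
        if f1 is None and f2 is not None:
            f1 = "unpaired"
        if f2 is None and f1 is not None:
            f2 = "unpaired"
        fates.append((f1, f2))
    return fates


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum: exhaustive enumeration of all labelings

def wilcoxon_enumeration_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating all C(n1+n2, n1) labelings."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    ranks = _average_ranks(list(x) + list(y))
    w_obs = sum(ranks[:n1])
    all_ranks = _average_ranks(pooled)
    n = len(pooled)
    mean = n1 * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        w = sum(all_ranks[i] for i in combo)
        total += 1
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            count += 1
    return count / total


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# random additive trees for the NJ exactness property

def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths and its leaf distances.

    Returns (taxa, distance matrix, set of non-trivial splits).
    """
    # start from 3-leaf star, attach remaining leaves to random edges
    nodes = {0: [], 1: [], 2: [], 3: []}  # node -> list of (neighbor, length)
    edges = []

    def connect(a, b, ln):
        nodes[a].append([b, ln])
        nodes[b].append([a, ln])
        edges.append((a, b))

    def length():
        return float(rng.uniform(0.05, 1.0))

    connect(3, 0, length())
    connect(3, 1, length())
    connect(3, 2, length())
    next_id = 4
    leaves = [0, 1, 2]
    for _ in range(n_leaves - 3):
        a, b = edges[rng.integers(0, len(edges))]
        # split edge (a,b) with a new internal node, hang a new leaf on it
        ln = next(l for nb, l in nodes[a] if nb == b)
        nodes[a] = [e for e in nodes[a] if e[0] != b]
        nodes[b] = [e for e in nodes[b] if e[0] != a]
        edges.remove((a, b))
        mid, leaf = next_id, next_id + 1
        next_id += 2
        nodes[mid] = []
        nodes[leaf] = []
        f = float(rng.uniform(0.2, 0.8))
        connect(a, mid, ln * f)
        connect(mid, b, ln * (1 - f))
        connect(mid, leaf, length())
        leaves.append(leaf)

    taxa = [f"t{l}" for l in leaves]
    n = len(leaves)
    dist = np.zeros((n, n))
    for i, src in enumerate(leaves):
        # BFS accumulating path lengths
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, ln in nodes[cur]:
                if nb not in seen:
                    seen[nb] = seen[cur] + ln
                    stack.append(nb)
        for j, dst in enumerate(leaves):
            dist[i, j] = seen[dst]
    dist = (dist + dist.T) / 2  # remove float asymmetry from path order

    leafset = frozenset(taxa)
    splits = set()
    for a, b in edges:
        # leaves on the 'a' side of edge (a,b)
        side = set()
        stack = [a]
        seen = {a, b}
        while stack:
            cur = stack.pop()
            if cur in leaves:
                side.add(f"t{cur}")
            for nb, _ in nodes[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side_f = frozenset(side)
        other = leafset - side_f
        if 1 < len(side_f) < n - 1:
            splits.add(min(side_f, other, key=lambda s: (len(s), sorted(s))))
    return taxa, dist, splits


# ---------------------------------------------------------------------------
# Smith-Waterman score oracle (plain DP)

def sw_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    rows = len(a) + 1
    cols = len(b) + 1
    best = 0.0
    prev = [0.0] * cols
    for i in range(1, rows):
        cur = [0.0] * cols
        for j in range(1, cols):
            s = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0.0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best
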