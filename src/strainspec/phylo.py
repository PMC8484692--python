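"""Kimura 2-parameter distances, neighbor-joining and bootstrap support.

K2P corrects the observed transition proportion P and transversion
proportion Q over pairwise-retained sites (columns with a gap or N in
either sequence are excluded):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Neighbor joining is the classic Saitou-Nei agglomeration with Q-matrix
minimization and lowest-index tie-breaking, which reconstructs additive
distance matrices exactly; negative branch-length estimates are clamped to
zero.  Bootstrap support resamples alignment columns with replacement and
reports, for each internal split of the original tree, the percentage of
replicates whose tree contains the same split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "K2PSaturationError",
    "k2p_distance",
    "k2p_matrix",
    "TreeNode",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T", "-", "N"}


class K2PSaturationError(ValueError):
    """Observed divergence outside the K2P model's domain."""


def k2p_distance(seq1: str, seq2: str) -> float:
    """Kimura 2-parameter distance with pairwise deletion of gaps/N sites."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    seq1, seq2 = seq1.upper(), seq2.upper()
    bad = (set(seq1) | set(seq2)) - _VALID
    if bad:
        raise ValueError(f"unsupported characters: {sorted(bad)}")
    n = transitions = transversions = 0
    for a, b in zip(seq1, seq2):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p = transitions / n
    q = transversions / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PSaturationError(f"saturated divergence (P={p:.3f}, Q={q:.3f})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_matrix(alignment: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise K2P matrix for a list of (taxon, aligned sequence)."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {len(s) for _, s in alignment}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    taxa = [t for t, _ in alignment]
    n = len(taxa)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = k2p_distance(alignment[i][1], alignment[j][1])
    return taxa, mat


@dataclass
class TreeNode:
    """Unrooted tree node; leaves carry a name, internal nodes a support."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-or-sorted leaf set side."""
        all_leaves = frozenset(self.leaves())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self)
        return splits


def nj_tree(taxa: list[str], dist: np.ndarray, clamp_negative: bool = True) -> TreeNode:
    """Classic neighbor joining; deterministic lowest-index tie-breaking."""
    d = np.asarray(dist, dtype=float)
    n = len(taxa)
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("diagonal must be zero")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    active = list(range(n))
    d = d.copy()

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        flat = np.argmin(qmat)
        i, j = divmod(flat, m)  # argmin returns the first minimum: lowest index
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode(children=[(nodes[ai], clamp(li)), (nodes[aj], clamp(lj))])
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for k_pos, ak in enumerate(active):
            if ak in (ai, aj):
                continue
            d[new_idx, ak] = d[ak, new_idx] = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - dij)
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    # three-point closed form for the final star
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return TreeNode(children=[
        (nodes[a], clamp(la)), (nodes[b], clamp(lb)), (nodes[c], clamp(lc)),
    ])


def bootstrap_support(
    alignment: list[tuple[str, str]],
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, int]:
    """NJ tree with per-split bootstrap support percentages.

    Columns are resampled with replacement per replicate; replicates whose
    K2P matrix saturates are skipped but counted.  Returns the original
    tree with ``support`` set on internal nodes, plus the number of
    skipped replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    taxa, mat = k2p_matrix(alignment)
    tree = nj_tree(taxa, mat)
    target_splits = tree.bipartitions()
    hits = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    length = len(alignment[0][1])
    rows = [np.frombuffer(s.encode(), dtype="S1") for _, s in alignment]
    skipped = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, length)
        rep = [(t, rows[i][cols].tobytes().decode()) for i, (t, _) in enumerate(alignment)]
        try:
            rep_taxa, rep_mat = k2p_matrix(rep)
            rep_tree = nj_tree(rep_taxa, rep_mat)
        except K2PSaturationError:
            skipped += 1
            continue
        rep_splits = rep_tree.bipartitions()
        for s in target_splits:
            if s in rep_splits:
                hits[s] += 1
    effective = n_replicates - skipped

    def annotate(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c, all_leaves) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            key = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            node.support = 100.0 * hits[key] / effective if effective else 0.0
        return below

    annotate(tree, frozenset(tree.leaves()))
    return tree, skipped


def write_newick(tree: TreeNode) -> str:
    """Newick text with branch lengths and supports as internal labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name
        inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
        label = f"{node.support:.1f}" if node.support is not None else ""
        return f"({inner}){label}"

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse the subset of Newick written by :func:`write_newick`."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick text must end with ';'")
    pos = 0

    def parse() -> TreeNode:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            node = TreeNode()
            while True:
                child = parse()
                length = 0.0
                if text[pos] == ":":
                    pos += 1
                    start = pos
                    while text[pos] not in ",();":
                        pos += 1
                    length = float(text[start:pos])
                node.children.append((child, length))
                if text[pos] == ",":
                    pos += 1
                    continue
                break
            assert text[pos] == ")"
            pos += 1
            start = pos
            while text[pos] not in ",():;":
                pos += 1
            label = text[start:pos]
            if label:
                node.support = float(label)
            return node
        start = pos
        while text[pos] not in ",():;":
            pos += 1
        return TreeNode(name=text[start:pos])

    tree = parse()
    if text[pos] == ":":  # root branch length (ignored)
        pos += 1
        while text[pos] not in ";":
            pos += 1
    if text[pos] != ";":
        raise ValueError("trailing characters in newick text")
    return tree
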