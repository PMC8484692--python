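"""Ortholog-group construction across bacterial strain gene sets.

Two independent clustering strategies are provided so that downstream
specificity calls can be gated on their consensus:

* method ``A`` — single-linkage components over similarity edges whose
  percent identity and coverage clear configurable thresholds;
* method ``B`` — connected components of the bidirectional-best-hit (BBH)
  graph, where for every ordered strain pair each gene keeps only its
  best-scoring hit and an edge survives only if it is mutual.

The module also assigns KEGG-Ortholog (KO) labels by best reference hit
under strict identity/score/coverage thresholds, and carries a transparent
hydropathy-window heuristic for the three-way localization contract
(intracellular / extracellular / transmembrane).  The localization rule is
a stand-in classifier, not a trained membrane-topology HMM, and its calls
on real proteins should be labelled as such in any report.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
from Bio.Align import PairwiseAligner

__all__ = [
    "Gene",
    "StrainGeneSet",
    "SimilarityEdge",
    "OrthologClustering",
    "KOAnnotation",
    "LocalizationCall",
    "pairwise_similarity",
    "cluster_orthologs",
    "assign_ko",
    "classify_localization",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class Gene:
    """One gene: 1-based chromosomal order plus both sequence forms."""

    gene_index: int
    gene_id: str
    nucleotide: str
    protein: str


@dataclass
class StrainGeneSet:
    """Ordered gene repertoire of a single strain."""

    strain_id: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        indices = [g.gene_index for g in self.genes]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError(f"{self.strain_id}: gene_index must be strictly increasing")
        for g in self.genes:
            if not g.nucleotide or not g.protein:
                raise ValueError(f"{self.strain_id}/{g.gene_id}: empty sequence")
            if abs(len(g.protein) - len(g.nucleotide) // 3) > 1:
                raise ValueError(
                    f"{self.strain_id}/{g.gene_id}: protein/nucleotide length mismatch"
                )

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class SimilarityEdge:
    """Local-alignment similarity between two genes of different strains."""

    query: tuple[str, str]  # (strain_id, gene_id)
    subject: tuple[str, str]
    percent_identity: float
    alignment_score: float
    query_coverage: float
    subject_coverage: float


@dataclass
class OrthologClustering:
    """A partition of the gene universe into ortholog groups."""

    method_tag: str
    groups: dict[str, frozenset[tuple[str, str]]]

    def gene_to_group(self) -> dict[tuple[str, str], str]:
        return {m: og for og, members in self.groups.items() for m in members}

    def n_genes(self) -> int:
        return sum(len(m) for m in self.groups.values())


@dataclass
class KOAnnotation:
    """Per-gene KO labels plus the supporting best hit statistics."""

    labels: dict[tuple[str, str], str | None]
    hits: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)

    def ko_of(self, gene: tuple[str, str]) -> str | None:
        return self.labels.get(gene)


@dataclass(frozen=True)
class LocalizationCall:
    category: str  # intracellular | extracellular | transmembrane
    n_predicted_helices: int


def make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_stats(aligner: PairwiseAligner, a: str, b: str) -> tuple[float, float, float, float]:
    """Align ``a`` (query) vs ``b`` (subject) locally.

    Returns (percent_identity, score, query_coverage, subject_coverage);
    identity is matched positions over the length of the shorter sequence
    (so a short high-scoring local segment between unrelated sequences
    still reads as low identity), coverage is the aligned span over full
    sequence length, both in percent.
    """
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / min(len(a), len(b))
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return identity, float(aln.score), 100.0 * span_a / len(a), 100.0 * span_b / len(b)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def pairwise_similarity(
    gene_sets: list[StrainGeneSet],
    level: str = "nucleotide",
    kmer_size: int | None = None,
    min_shared_kmers: int | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> list[SimilarityEdge]:
    """All-vs-all cross-strain gene similarity with a k-mer prefilter.

    ``level`` selects the compared sequence: ``"nucleotide"`` (default —
    the scale on which the clustering identity thresholds are calibrated
    for the synthetic generator's substitution process) or ``"protein"``.
    Only cross-strain pairs sharing >= ``min_shared_kmers`` k-mers are
    aligned; each unordered pair yields one edge (the reverse query is the
    same edge with coverages swapped).
    """
    if level not in ("nucleotide", "protein"):
        raise ValueError("level must be 'nucleotide' or 'protein'")
    if kmer_size is None:
        kmer_size = 12 if level == "nucleotide" else 5
    if min_shared_kmers is None:
        min_shared_kmers = 5 if level == "nucleotide" else 3
    if len(gene_sets) < 2:
        raise ValueError("pairwise_similarity requires at least 2 strains")
    for gs in gene_sets:
        if not gs.genes:
            raise ValueError(f"empty gene set: {gs.strain_id}")

    def seq_of(gene: Gene) -> str:
        return gene.nucleotide if level == "nucleotide" else gene.protein

    entries: list[tuple[str, Gene]] = [
        (gs.strain_id, g) for gs in gene_sets for g in gs.genes
    ]
    postings: dict[str, list[int]] = defaultdict(list)
    for idx, (_, gene) in enumerate(entries):
        for kmer in _kmer_set(seq_of(gene), kmer_size):
            postings[kmer].append(idx)

    shared: Counter[tuple[int, int]] = Counter()
    for idxs in postings.values():
        if len(idxs) < 2:
            continue
        for i, j in itertools.combinations(idxs, 2):
            if entries[i][0] != entries[j][0]:  # cross-strain only
                shared[(i, j)] += 1

    aligner = make_aligner(match, mismatch, gap)
    edges: list[SimilarityEdge] = []
    for (i, j), count in sorted(shared.items()):
        if count < min_shared_kmers:
            continue
        (strain_a, gene_a), (strain_b, gene_b) = entries[i], entries[j]
        identity, score, cov_a, cov_b = align_stats(aligner, seq_of(gene_a), seq_of(gene_b))
        edges.append(
            SimilarityEdge(
                query=(strain_a, gene_a.gene_id),
                subject=(strain_b, gene_b.gene_id),
                percent_identity=identity,
                alignment_score=score,
                query_coverage=cov_a,
                subject_coverage=cov_b,
            )
        )
    return edges


def gene_universe(gene_sets: list[StrainGeneSet]) -> list[tuple[str, str]]:
    return [(gs.strain_id, g.gene_id) for gs in gene_sets for g in gs.genes]


def _components_to_clustering(
    graph: nx.Graph, universe: list[tuple[str, str]], method_tag: str
) -> OrthologClustering:
    graph.add_nodes_from(universe)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    groups = {
        f"OG{i:07d}": frozenset(comp) for i, comp in enumerate(components, start=1)
    }
    return OrthologClustering(method_tag=method_tag, groups=groups)


def cluster_orthologs(
    edges: list[SimilarityEdge],
    gene_sets: list[StrainGeneSet],
    method: str = "A",
    identity_threshold: float = 95.0,
    min_coverage: float = 50.0,
) -> OrthologClustering:
    """Partition genes into ortholog groups by one of the two strategies.

    Method A: single-linkage components over edges with
    identity >= ``identity_threshold`` and both coverages >= ``min_coverage``.
    Method B: connected components of the bidirectional-best-hit graph
    (edges below ``min_coverage`` are not eligible as hits).
    Singleton genes always form singleton groups.
    """
    universe = gene_universe(gene_sets)
    if method == "A":
        graph = nx.Graph()
        for e in edges:
            if (
                e.percent_identity >= identity_threshold
                and e.query_coverage >= min_coverage
                and e.subject_coverage >= min_coverage
            ):
                graph.add_edge(e.query, e.subject)
        return _components_to_clustering(graph, universe, "A")
    if method == "B":
        # best hit per (gene, other strain), keyed on score then identity,
        # lowest gene id breaking remaining ties deterministically
        best: dict[tuple[tuple[str, str], str], tuple[float, float, tuple[str, str]]] = {}

        def consider(src: tuple[str, str], dst: tuple[str, str], score: float, ident: float) -> None:
            # higher score wins, then higher identity, then lowest gene id
            key = (src, dst[0])
            cand = (score, ident, dst)
            prev = best.get(key)
            if prev is None or (cand[0], cand[1], prev[2]) > (prev[0], prev[1], cand[2]):
                best[key] = cand

        for e in edges:
            if e.query_coverage < min_coverage or e.subject_coverage < min_coverage:
                continue
            consider(e.query, e.subject, e.alignment_score, e.percent_identity)
            consider(e.subject, e.query, e.alignment_score, e.percent_identity)
        graph = nx.Graph()
        for (src, _), (_, _, dst) in best.items():
            back = best.get((dst, src[0]))
            if back is not None and back[2] == src:
                graph.add_edge(src, dst)
        return _components_to_clustering(graph, universe, "B")
    raise ValueError(f"unknown clustering method: {method!r}")


def assign_ko(
    gene_sets: list[StrainGeneSet],
    ko_reference: dict[str, str],
    min_identity: float = 40.0,
    min_score: float = 70.0,
    min_coverage: float = 80.0,
    kmer_size: int = 5,
    min_shared_kmers: int = 3,
) -> KOAnnotation:
    """Label genes with the KO of their best-scoring reference hit.

    A label is assigned only when the best hit satisfies all three strict
    thresholds (identity > 40, score > 70, coverage > 80 by default, where
    coverage is min(query, subject) coverage).  ``ko_reference`` maps a
    reference protein id to its sequence; the KO label is taken as the part
    of the id before the first ``"|"`` (or the whole id).
    """
    if not ko_reference:
        raise ValueError("empty KO reference")
    ref_entries = sorted(ko_reference.items())
    postings: dict[str, list[int]] = defaultdict(list)
    for idx, (_, seq) in enumerate(ref_entries):
        for kmer in _kmer_set(seq, kmer_size):
            postings[kmer].append(idx)

    aligner = make_aligner()
    labels: dict[tuple[str, str], str | None] = {}
    hits: dict[tuple[str, str], tuple[float, float, float]] = {}
    for gs in gene_sets:
        for gene in gs.genes:
            key = (gs.strain_id, gene.gene_id)
            shared: Counter[int] = Counter()
            for kmer in _kmer_set(gene.protein, kmer_size):
                for idx in postings.get(kmer, ()):
                    shared[idx] += 1
            best: tuple[float, float, float, str] | None = None
            for idx, count in sorted(shared.items()):
                if count < min_shared_kmers:
                    continue
                ref_id, ref_seq = ref_entries[idx]
                identity, score, qcov, scov = align_stats(aligner, gene.protein, ref_seq)
                cov = min(qcov, scov)
                cand = (score, identity, cov, ref_id)
                if best is None or cand[0] > best[0]:
                    best = cand
            if best is not None and best[1] > min_identity and best[0] > min_score and best[2] > min_coverage:
                ref_id = best[3]
                labels[key] = ref_id.split("|")[0]
                hits[key] = (best[1], best[0], best[2])
            else:
                labels[key] = None
    return KOAnnotation(labels=labels, hits=hits)


def classify_localization(
    protein: str,
    window: int = 19,
    hydropathy_cutoff: float = 1.6,
    signal_min_len: int = 8,
    signal_region: int = 30,
) -> LocalizationCall:
    """Three-way localization call from Kyte-Doolittle hydropathy windows.

    Predicted helices are maximal runs of length-``window`` windows whose
    mean hydropathy exceeds ``hydropathy_cutoff``; >= 1 helix means
    transmembrane.  Without helices, a hydrophobic N-terminal stretch
    (a window of ``signal_min_len`` residues with mean hydropathy above the
    cutoff starting within the first ``signal_region`` residues) yields
    extracellular, otherwise intracellular.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    values = [KYTE_DOOLITTLE[a] for a in protein]

    n_helices = 0
    if len(values) >= window:
        total = sum(values[:window])
        hits = [total / window > hydropathy_cutoff]
        for i in range(1, len(values) - window + 1):
            total += values[i + window - 1] - values[i - 1]
            hits.append(total / window > hydropathy_cutoff)
        in_region = False
        for h in hits:
            if h and not in_region:
                n_helices += 1
            in_region = h
    if n_helices >= 1:
        return LocalizationCall("transmembrane", n_helices)

    limit = min(signal_region, len(values)) - signal_min_len + 1
    for i in range(max(limit, 0)):
        seg = values[i:i + signal_min_len]
        if sum(seg) / signal_min_len > hydropathy_cutoff:
            return LocalizationCall("extracellular", 0)
    return LocalizationCall("intracellular", 0)
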