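"""Plain-text persistence for pipeline stages.

Each stage reads and writes small standard formats — per-strain gene FASTA
plus a tab-separated gene table, edges/clustering/calls TSVs — so any
stage can be re-run from the files its upstream stage persisted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .orthology import Gene, KOAnnotation, OrthologClustering, SimilarityEdge, StrainGeneSet

__all__ = [
    "write_gene_sets",
    "read_gene_sets",
    "write_edges",
    "read_edges",
    "write_clustering",
    "read_clustering",
    "write_ko",
    "read_ko",
    "write_calls",
]


def write_gene_sets(gene_sets: list[StrainGeneSet], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gs in gene_sets:
        with open(out / f"{gs.strain_id}.fasta", "w") as fh:
            for g in gs.genes:
                fh.write(f">{g.gene_id}\n{g.nucleotide}\n")
        table = pd.DataFrame(
            [(gs.strain_id, g.gene_index, g.gene_id) for g in gs.genes],
            columns=["strain", "gene_index", "gene_id"],
        )
        table.to_csv(out / f"{gs.strain_id}.genes.tsv", sep="\t", index=False)


def read_gene_sets(in_dir: str | Path) -> list[StrainGeneSet]:
    """Load per-strain FASTA + gene-order TSV back into gene sets.

    Proteins are re-derived by translation (stops kept as ``W``, matching
    the generator's convention for post-mutation stops).
    """
    in_dir = Path(in_dir)
    gene_sets = []
    for table_path in sorted(in_dir.glob("*.genes.tsv")):
        strain = table_path.name.removesuffix(".genes.tsv")
        table = pd.read_csv(table_path, sep="\t")
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(in_dir / f"{strain}.fasta", "fasta")}
        genes = []
        for _, row in table.sort_values("gene_index").iterrows():
            nt = seqs[row["gene_id"]]
            prot = str(Seq(nt).translate()).replace("*", "W")
            genes.append(Gene(int(row["gene_index"]), row["gene_id"], nt, prot))
        gene_sets.append(StrainGeneSet(strain_id=strain, genes=genes))
    if not gene_sets:
        raise FileNotFoundError(f"no *.genes.tsv found in {in_dir}")
    return gene_sets


def write_edges(edges: list[SimilarityEdge], path: str | Path) -> None:
    pd.DataFrame(
        [
            (e.query[0], e.query[1], e.subject[0], e.subject[1],
             e.percent_identity, e.alignment_score, e.query_coverage, e.subject_coverage)
            for e in edges
        ],
        columns=["query_strain", "query_gene", "subject_strain", "subject_gene",
                 "percent_identity", "alignment_score", "query_coverage", "subject_coverage"],
    ).to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> list[SimilarityEdge]:
    table = pd.read_csv(path, sep="\t")
    return [
        SimilarityEdge(
            query=(row.query_strain, row.query_gene),
            subject=(row.subject_strain, row.subject_gene),
            percent_identity=row.percent_identity,
            alignment_score=row.alignment_score,
            query_coverage=row.query_coverage,
            subject_coverage=row.subject_coverage,
        )
        for row in table.itertuples()
    ]


def write_clustering(clustering: OrthologClustering, path: str | Path) -> None:
    rows = [
        (og, strain, gene)
        for og, members in sorted(clustering.groups.items())
        for strain, gene in sorted(members)
    ]
    table = pd.DataFrame(rows, columns=["og_id", "strain", "gene_id"])
    with open(path, "w") as fh:
        fh.write(f"# method={clustering.method_tag}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_clustering(path: str | Path) -> OrthologClustering:
    with open(path) as fh:
        header = fh.readline().strip()
        method = header.split("method=")[1] if "method=" in header else "?"
        table = pd.read_csv(fh, sep="\t")
    groups: dict[str, set] = {}
    for row in table.itertuples():
        groups.setdefault(row.og_id, set()).add((row.strain, row.gene_id))
    return OrthologClustering(method_tag=method,
                              groups={og: frozenset(m) for og, m in groups.items()})


def write_ko(ko: KOAnnotation, path: str | Path) -> None:
    rows = []
    for (strain, gene), label in sorted(ko.labels.items()):
        identity, score, coverage = ko.hits.get((strain, gene), (None, None, None))
        rows.append((strain, gene, label or "", identity, score, coverage))
    pd.DataFrame(rows, columns=["strain", "gene_id", "ko", "identity", "score", "coverage"]
                 ).to_csv(path, sep="\t", index=False)


def read_ko(path: str | Path) -> KOAnnotation:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    labels = {}
    hits = {}
    for row in table.itertuples():
        key = (row.strain, row.gene_id)
        labels[key] = row.ko or None
        if row.ko and row.identity != "":
            hits[key] = (float(row.identity), float(row.score), float(row.coverage))
    return KOAnnotation(labels=labels, hits=hits)


def write_calls(calls, path: str | Path) -> None:
    rows = [
        (c.og_id, ",".join(sorted(c.target_set)), c.rule,
         ",".join(c.triggering_kos),
         ";".join(f"{s}:{g}" if not g.startswith(f"{s}:") else g
                  for s, g in sorted(c.members)))
        for c in calls
    ]
    pd.DataFrame(rows, columns=["og_id", "target_set", "rule", "kos", "members"]
                 ).to_csv(path, sep="\t", index=False)
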