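"""Read-to-gene assignment, TPM and ortholog-group aggregation.

Assignment is plurality voting over canonical gene k-mers: each read votes
for the gene(s) collecting the most of its k-mer hits, with exact ties
split fractionally.  This is a deterministic stand-in for pseudo-alignment
counting (no EM redistribution of multi-mapping reads); it is adequate
when genes are mutually dissimilar except for within-ortholog copies,
which is what the synthetic pan-genomes provide.  TPM uses the full gene
length as the effective length (no fragment-length correction).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthology import OrthologClustering, StrainGeneSet
from .qc import revcomp

__all__ = [
    "GeneIndex",
    "build_gene_index",
    "assign_reads",
    "compute_tpm",
    "tpm_table",
    "aggregate_orthologs",
]


def _canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class GeneIndex:
    kmers: dict[str, tuple[str, ...]]  # canonical k-mer -> gene ids
    lengths: dict[str, int]  # gene id -> nucleotide length
    k: int


def gene_key(strain_id: str, gene_id: str) -> str:
    return gene_id if ":" in gene_id else f"{strain_id}:{gene_id}"


def build_gene_index(gene_sets: list[StrainGeneSet], k: int = 31) -> GeneIndex:
    """Index the k-mers of every gene on both strands.

    Storing both strands lets read lookup skip per-k-mer
    reverse-complementing; genes shorter than k are skipped with a warning.
    """
    postings: dict[str, list[str]] = defaultdict(list)
    lengths: dict[str, int] = {}
    for gs in gene_sets:
        for g in gs.genes:
            gid = gene_key(gs.strain_id, g.gene_id)
            if len(g.nucleotide) < k:
                warnings.warn(f"gene {gid} shorter than k={k}; skipped")
                continue
            lengths[gid] = len(g.nucleotide)
            seen: set[str] = set()
            for seq in (g.nucleotide, revcomp(g.nucleotide)):
                for i in range(len(seq) - k + 1):
                    kmer = seq[i:i + k]
                    if kmer not in seen:
                        seen.add(kmer)
                        postings[kmer].append(gid)
    return GeneIndex(kmers={k_: tuple(v) for k_, v in postings.items()}, lengths=lengths, k=k)


def assign_reads(
    reads, index: GeneIndex, max_kmers_per_read: int | None = None
) -> dict[str, float]:
    """Fractional per-gene counts from k-mer plurality voting.

    Each read's (optionally subsampled, evenly spaced) k-mers are looked up
    in the index; the gene(s) with the plurality of hits share one count
    equally.  Reads with no hits are left unassigned.
    """
    k = index.k
    kmers_get = index.kmers.get
    counts: dict[str, float] = defaultdict(float)
    position_cache: dict[int, tuple[int, ...]] = {}

    def positions_for(n_kmers: int) -> tuple[int, ...]:
        cached = position_cache.get(n_kmers)
        if cached is None:
            if max_kmers_per_read is None or n_kmers <= max_kmers_per_read:
                cached = tuple(range(n_kmers))
            elif max_kmers_per_read == 1:
                cached = (0,)
            else:
                step = (n_kmers - 1) / (max_kmers_per_read - 1)
                cached = tuple(round(i * step) for i in range(max_kmers_per_read))
            position_cache[n_kmers] = cached
        return cached

    for seq in reads:
        n_kmers = len(seq) - k + 1
        if n_kmers <= 0:
            continue
        votes: dict[str, int] = {}
        for i in positions_for(n_kmers):
            hit = kmers_get(seq[i:i + k])
            if hit:
                for g in hit:
                    votes[g] = votes.get(g, 0) + 1
        if not votes:
            continue
        top = max(votes.values())
        winners = [g for g, v in votes.items() if v == top]
        share = 1.0 / len(winners)
        for g in winners:
            counts[g] += share
    return dict(counts)


def compute_tpm(counts: pd.Series | dict, lengths: pd.Series | dict) -> pd.Series:
    """TPM_i = (count_i / length_i) / sum_j(rate_j) * 1e6 (all-zero -> zeros)."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (lengths <= 0).any():
        raise ValueError("non-positive gene length")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return rates * 0.0
    return rates / total * 1e6


def tpm_table(
    per_sample_counts: dict[str, dict[str, float]], lengths: dict[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x genes TPM matrix and the companion raw count matrix."""
    genes = sorted(lengths)
    count_df = pd.DataFrame(
        {s: pd.Series(c, dtype=float).reindex(genes).fillna(0.0)
         for s, c in per_sample_counts.items()}
    ).T
    lengths_s = pd.Series(lengths, dtype=float)
    tpm_df = count_df.apply(lambda row: compute_tpm(row, lengths_s), axis=1)
    return tpm_df, count_df


def aggregate_orthologs(
    tpm: pd.DataFrame, clustering: OrthologClustering
) -> tuple[pd.DataFrame, list[str]]:
    """Sum member-gene TPM per ortholog group; mass is conserved.

    Returns the samples x OG table plus the list of genes present in the
    TPM table but absent from the clustering (reported, not silently
    dropped).
    """
    gene_to_og: dict[str, str] = {}
    for og, members in clustering.groups.items():
        for strain, gid in members:
            gene_to_og[gene_key(strain, gid)] = og
    assigned = [g for g in tpm.columns if g in gene_to_og]
    unassigned = [g for g in tpm.columns if g not in gene_to_og]
    og_of = [gene_to_og[g] for g in assigned]
    og_df = tpm[assigned].T.groupby(og_of).sum().T
    og_df.attrs["method_tag"] = clustering.method_tag
    return og_df, unassigned
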