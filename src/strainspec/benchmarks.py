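"""Self-contained study runs that exercise the whole pipeline on synthetic
data with planted truth: strain-specificity recovery at the target study's
scale, end-to-end cohort power, and null-calibration checks for the
statistical layer.  Each function runs the package's own public operations
from scratch and measures the outcome against the generator's truth table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .orthology import assign_ko, cluster_orthologs, pairwise_similarity
from .phylo import TreeNode, nj_tree
from .quantify import aggregate_orthologs, assign_reads, build_gene_index, tpm_table
from .simulate import (
    CohortSimSpec,
    PanGenomeSpec,
    PlantedDirective,
    simulate_genus_table,
    simulate_metagenome_cohort,
    simulate_pangenome,
    truth_ko_reference,
)
from .specificity import call_specific_orthologs, consensus_calls, find_adjacent_blocks
from .stats import bray_curtis, clr_mc_differential_abundance, ortholog_da_report, permanova

__all__ = [
    "planted_recovery_study",
    "power_study",
    "tpm_conservation_study",
    "clr_null_type1",
    "genus_power_study",
    "permanova_null_pvalues",
    "nj_additive_study",
]

PAIR = ("Fp02", "Fp10")


def _study_pangenome(seed: int):
    """12 strains at the target study's specificity scale: 4 ortholog groups
    shared only by two strains (3 of them adjacent), 150 exclusive to one
    of the pair and 214 exclusive to the other, mutation rate 0.01."""
    planted = [PlantedDirective(PAIR, 3), PlantedDirective(PAIR, 1)]
    planted += [PlantedDirective((PAIR[0],), 1) for _ in range(150)]
    planted += [PlantedDirective((PAIR[1],), 1) for _ in range(214)]
    n_planted_groups = sum(d.length for d in planted)  # 368
    spec = PanGenomeSpec(
        n_strains=12,
        core_size=30,
        accessory_size=n_planted_groups + 20,  # plus 20 random accessory groups
        planted_specific=planted,
        mutation_rate=0.01,
        seed=seed,
    )
    return simulate_pangenome(spec)


def planted_recovery_study(seed: int = 0) -> dict:
    """Precision/recall of the two-method consensus against planted truth.

    Returns per-target precision/recall plus the length of the adjacency
    block recovered for the two-strain target.
    """
    genomes, truth = _study_pangenome(seed)
    strains = [g.strain_id for g in genomes]
    edges = pairwise_similarity(genomes)
    clus_a = cluster_orthologs(edges, genomes, "A")
    clus_b = cluster_orthologs(edges, genomes, "B")
    ko = assign_ko(genomes, truth_ko_reference(genomes, truth))

    truth_members = {
        og: frozenset(truth.og_membership[og]) for og in truth.planted_specific_ids
    }
    out: dict = {}
    for label, target in (("pair", set(PAIR)),
                          (PAIR[0], {PAIR[0]}),
                          (PAIR[1], {PAIR[1]})):
        calls_a = call_specific_orthologs(clus_a, ko, target, strains)
        calls_b = call_specific_orthologs(clus_b, ko, target, strains)
        res = consensus_calls(calls_a, calls_b)
        got = {frozenset(a.members) for a, _ in res.consensus}
        want = {m for og, m in truth_members.items()
                if set(truth.planted_targets[og]) == target}
        tp = len(got & want)
        out[label] = {
            "n_called": len(got),
            "n_planted": len(want),
            "precision": tp / len(got) if got else 0.0,
            "recall": tp / len(want) if want else 0.0,
        }
        if label == "pair":
            blocks = find_adjacent_blocks([a for a, _ in res.consensus], genomes)
            out["pair_block_lengths"] = sorted(
                {b.length for b in blocks if b.length > 1}
            )
    out["precision"] = min(v["precision"] for k, v in out.items() if isinstance(v, dict))
    out["recall"] = min(v["recall"] for k, v in out.items() if isinstance(v, dict))
    return out


def _power_pangenome(seed: int):
    spec = PanGenomeSpec(
        n_strains=12, core_size=20, accessory_size=10,
        planted_specific=[PlantedDirective(PAIR, 4)],
        mutation_rate=0.01, seed=seed,
    )
    return simulate_pangenome(spec)


def _quantify_cohort(genomes, truth, clus, cohort_seed: int,
                     reads_per_sample: int = 3000, group_sizes=(20, 15),
                     effect_size: float = 4.0, index=None):
    cohort_spec = CohortSimSpec(
        group_sizes=group_sizes, target_strains=PAIR, effect_size=effect_size,
        reads_per_sample=reads_per_sample, with_quality=False, seed=cohort_seed,
    )
    cohort = simulate_metagenome_cohort(genomes, truth, cohort_spec)
    if index is None:
        index = build_gene_index(genomes)
    per_sample = {
        s.sample_id: assign_reads(
            [p.seq1 for p in s.pairs] + [p.seq2 for p in s.pairs],
            index, max_kmers_per_read=2)
        for s in cohort.samples
    }
    tpm, _ = tpm_table(per_sample, index.lengths)
    og_table, _ = aggregate_orthologs(tpm, clus)
    return cohort, tpm, og_table


def power_study(n_runs: int = 200, seed: int = 0,
                reads_per_sample: int = 2000) -> dict:
    """End-to-end detection power for the planted healthy-enriched orthologs.

    One fixed pan-genome and clustering; ``n_runs`` independent cohort
    draws (n = 20 vs 15, effect size 4).  A run succeeds when every
    planted consensus ortholog is flagged at Wilcoxon p < 0.05.
    """
    genomes, truth = _power_pangenome(seed)
    strains = [g.strain_id for g in genomes]
    edges = pairwise_similarity(genomes)
    clus_a = cluster_orthologs(edges, genomes, "A")
    clus_b = cluster_orthologs(edges, genomes, "B")
    ko = assign_ko(genomes, truth_ko_reference(genomes, truth))
    res = consensus_calls(
        call_specific_orthologs(clus_a, ko, set(PAIR), strains),
        call_specific_orthologs(clus_b, ko, set(PAIR), strains),
    )
    consensus_ids = [a.og_id for a, _ in res.consensus]
    index = build_gene_index(genomes)
    successes = 0
    for run in range(n_runs):
        cohort, _, og_table = _quantify_cohort(
            genomes, truth, clus_a, cohort_seed=seed * 100_000 + run + 1,
            reads_per_sample=reads_per_sample, index=index,
        )
        da = ortholog_da_report(og_table, cohort.metadata["group"],
                                case_label="MCI", og_ids=consensus_ids)
        tested = da[da["tested"] == True]  # noqa: E712
        if len(tested) == len(consensus_ids) and bool(tested["significant"].all()):
            successes += 1
    return {
        "n_runs": n_runs,
        "n_planted": len(consensus_ids),
        "power_pct": 100.0 * successes / n_runs,
    }


def tpm_conservation_study(seed: int = 0) -> dict:
    """Per-sample TPM normalization and aggregation mass conservation."""
    genomes, truth = _power_pangenome(seed)
    edges = pairwise_similarity(genomes)
    clus = cluster_orthologs(edges, genomes, "A")
    _, tpm, og_table = _quantify_cohort(genomes, truth, clus, cohort_seed=seed + 7,
                                        reads_per_sample=1500, group_sizes=(5, 5))
    sums = tpm.sum(axis=1).to_numpy()
    og_sums = og_table.sum(axis=1).to_numpy()
    return {
        "max_tpm_rel_error": float(np.abs(sums - 1e6).max() / 1e6),
        "max_aggregation_rel_error": float(np.abs(og_sums - sums).max() / 1e6),
        "n_samples": len(sums),
    }


def clr_null_type1(n_tests: int = 5000, seed: int = 0) -> dict:
    """Fraction of null genus features flagged at p < 0.05 by the CLR
    Monte-Carlo differential-abundance test."""
    hits = 0
    total = 0
    rep = 0
    while total < n_tests:
        table, meta = simulate_genus_table(seed=seed * 10_000 + rep)
        res = clr_mc_differential_abundance(
            table, meta["group"], case_label="MCI",
            n_instances=128, seed=seed * 10_000 + rep,
        )
        hits += int((res["p_value"] < 0.05).sum())
        total += res.shape[0]
        rep += 1
    return {"type1_rate": hits / total, "n_tests": total}


def genus_power_study(n_runs: int = 200, fold: float = 3.0, seed: int = 0) -> dict:
    """Detection rate of a planted fold-change genus at n = 20 vs 15."""
    flagged = 0
    for rep in range(n_runs):
        table, meta = simulate_genus_table(
            planted_effects={"g__007": fold}, seed=seed * 10_000 + rep
        )
        res = clr_mc_differential_abundance(
            table, meta["group"], case_label="MCI",
            n_instances=64, seed=seed * 10_000 + rep,
        )
        flagged += bool(res.loc["g__007", "p_value"] < 0.05)
    return {"power_pct": 100.0 * flagged / n_runs, "n_runs": n_runs}


def permanova_null_pvalues(n_runs: int = 500, seed: int = 0) -> dict:
    """PERMANOVA p values under shuffled (null) labels; KS test vs uniform."""
    rng = np.random.default_rng(seed)
    ps = []
    for rep in range(n_runs):
        x = np.abs(rng.normal(2.0, 1.0, size=(20, 5)))
        d = bray_curtis(pd.DataFrame(x))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=d.index)
        _, _, p = permanova(d, groups, n_permutations=999,
                            seed=int(rng.integers(0, 2**31)))
        ps.append(p)
    ks = sps.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "n_runs": n_runs,
            "mean_p": float(np.mean(ps))}


def _random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree by sequential joining; leaf distances are
    accumulated at each join, so the matrix is additive by construction.
    Returns (taxa, distance matrix, non-trivial splits)."""
    items = [(TreeNode(name=f"t{i}"), {f"t{i}": 0.0}) for i in range(n_leaves)]
    pair_dist: dict[frozenset, float] = {}
    split_sets: list[frozenset] = []
    while len(items) > 1:
        if len(items) == 2:
            i, j = 0, 1
        else:
            i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, da), (nb, db) = items[i], items[j]
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0))
        for x, dx in da.items():
            for y, dy in db.items():
                pair_dist[frozenset((x, y))] = dx + la + dy + lb
        node = TreeNode(children=[(na, la), (nb, lb)])
        dmap = {**{k: v + la for k, v in da.items()},
                **{k: v + lb for k, v in db.items()}}
        if len(items) > 2:
            split_sets.append(frozenset(dmap))
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [(node, dmap)]
    taxa = sorted(items[0][1])
    n = len(taxa)
    dist = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                dist[i, j] = dist[j, i] = pair_dist[frozenset((a, b))]
    leafset = frozenset(taxa)
    norm = set()
    for s in split_sets:
        other = leafset - s
        if 1 < len(s) < n - 1:
            norm.add(min(s, other, key=lambda x: (len(x), sorted(x))))
    return taxa, dist, norm


def nj_additive_study(n_trees: int = 100, seed: int = 0,
                      max_leaves: int = 8) -> dict:
    """Fraction of random additive matrices reconstructed exactly by NJ."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_trees):
        n_leaves = int(rng.integers(4, max_leaves + 1))
        taxa, dist, splits = _random_additive_tree(n_leaves, rng)
        tree = nj_tree(taxa, dist)
        if tree.bipartitions() == splits:
            exact += 1
    return {"exact_fraction": exact / n_trees, "n_trees": n_trees}
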