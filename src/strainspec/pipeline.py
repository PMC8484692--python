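"""End-to-end orchestration: simulate -> orthology -> specificity -> qc ->
quantify -> cohort statistics, with a single global seed fanned out to
per-stage seeds by a fixed counter scheme and a provenance-stamped summary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .orthology import assign_ko, cluster_orthologs, pairwise_similarity
from .qc import FilterConfig, qc_pipeline, qc_report_summary
from .quantify import aggregate_orthologs, assign_reads, build_gene_index, tpm_table
from .simulate import (
    CohortSimSpec,
    ContaminantFractions,
    PanGenomeSpec,
    PlantedDirective,
    simulate_metagenome_cohort,
    simulate_pangenome,
    truth_ko_reference,
)
from .specificity import call_specific_orthologs, consensus_calls, find_adjacent_blocks
from .stats import ortholog_da_report

__all__ = ["DEFAULT_CONFIG", "validate_config", "stage_seed", "run_all"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "pangenome": {
        "n_strains": 12,
        "core_size": 30,
        "accessory_size": 40,
        "gene_length_range": [300, 900],
        "mutation_rate": 0.01,
        "planted": [
            {"strains": ["Fp02", "Fp10"], "length": 4, "ko_policy": "unique"},
        ],
    },
    "cohort": {
        "group_sizes": [20, 15],
        "reads_per_sample": 3000,
        "read_length": 150,
        "target_weight_healthy": 0.35,
        "effect_size": 4.0,
        "contaminants": {"phix": 0.0, "host": 0.0, "adapter": 0.0,
                         "n_base": 0.0, "lowq_tail": 0.0},
        "with_quality": False,
    },
    "orthology": {"identity_threshold": 95.0, "min_coverage": 50.0},
    "specificity": {"consensus_jaccard": 0.5, "require_all_targets": True},
    "qc": {"enabled": False, "tail_quality_cutoff": 17, "min_length": 50,
           "min_mean_quality": 25.0, "adapter_min_overlap": 32},
    "quantify": {"k": 31, "max_kmers_per_read": 8},
}

_STAGE_OFFSETS = {"pangenome": 1, "cohort": 2, "clr": 3, "permanova": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: (global * 1000 + stage counter) mod 2^31."""
    return (int(global_seed) * 1000 + _STAGE_OFFSETS.get(stage, 0)) % (2**31)


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | dict | None = None) -> dict:
    """Fill defaults, reject unknown keys and out-of-range values."""
    if source is None:
        overrides: dict = {}
    elif isinstance(source, dict):
        overrides = source
    else:
        with open(source) as fh:
            overrides = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, overrides)
    errors = []
    if cfg["qc"]["tail_quality_cutoff"] < 0:
        errors.append("qc.tail_quality_cutoff must be >= 0")
    if cfg["qc"]["min_length"] <= 0:
        errors.append("qc.min_length must be > 0")
    if cfg["cohort"]["reads_per_sample"] <= 0:
        errors.append("cohort.reads_per_sample must be > 0")
    if cfg["cohort"]["effect_size"] <= 0:
        errors.append("cohort.effect_size must be > 0")
    if not 0 < cfg["specificity"]["consensus_jaccard"] <= 1:
        errors.append("specificity.consensus_jaccard must be in (0, 1]")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_all(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic pipeline; returns (and optionally writes) a summary.

    The summary includes the consensus specific-ortholog calls, their
    cohort p/q values, adjacency blocks and QC totals; reruns with an
    identical config are byte-identical apart from no timestamp being
    recorded at all.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]

    pg = cfg["pangenome"]
    planted = [
        PlantedDirective(tuple(d["strains"]), int(d["length"]), d.get("ko_policy", "unique"))
        for d in pg["planted"]
    ]
    if not planted:
        raise ValueError("empty config: at least one planted directive is required")
    spec = PanGenomeSpec(
        n_strains=pg["n_strains"],
        core_size=pg["core_size"],
        accessory_size=pg["accessory_size"],
        planted_specific=planted,
        gene_length_range=tuple(pg["gene_length_range"]),
        mutation_rate=pg["mutation_rate"],
        seed=stage_seed(seed, "pangenome"),
    )
    genomes, truth = simulate_pangenome(spec)
    target = planted[0].strains

    edges = pairwise_similarity(genomes)
    ortho = cfg["orthology"]
    clus_a = cluster_orthologs(edges, genomes, "A",
                               identity_threshold=ortho["identity_threshold"],
                               min_coverage=ortho["min_coverage"])
    clus_b = cluster_orthologs(edges, genomes, "B", min_coverage=ortho["min_coverage"])
    ko_reference = truth_ko_reference(genomes, truth)
    strains = [g.strain_id for g in genomes]
    if ko_reference:
        ko = assign_ko(genomes, ko_reference)
    else:
        from .orthology import KOAnnotation
        ko = KOAnnotation(labels={(gs.strain_id, g.gene_id): None
                                  for gs in genomes for g in gs.genes})
    spc = cfg["specificity"]
    calls_a = call_specific_orthologs(clus_a, ko, set(target), strains,
                                      require_all_targets=spc["require_all_targets"])
    calls_b = call_specific_orthologs(clus_b, ko, set(target), strains,
                                      require_all_targets=spc["require_all_targets"])
    consensus = consensus_calls(calls_a, calls_b, min_jaccard=spc["consensus_jaccard"])
    blocks = find_adjacent_blocks([a for a, _ in consensus.consensus], genomes)

    co = cfg["cohort"]
    cohort_spec = CohortSimSpec(
        group_sizes=tuple(co["group_sizes"]),
        target_strains=tuple(target),
        target_weight_healthy=co["target_weight_healthy"],
        effect_size=co["effect_size"],
        reads_per_sample=co["reads_per_sample"],
        read_length=co["read_length"],
        contaminant_fractions=ContaminantFractions(**co["contaminants"]),
        with_quality=bool(co["with_quality"]),
        seed=stage_seed(seed, "cohort"),
    )
    cohort = simulate_metagenome_cohort(genomes, truth, cohort_spec)

    qc_summary = None
    if cfg["qc"]["enabled"]:
        fc = FilterConfig.with_packaged_decoys(
            tail_quality_cutoff=cfg["qc"]["tail_quality_cutoff"],
            min_length=cfg["qc"]["min_length"],
            min_mean_quality=cfg["qc"]["min_mean_quality"],
            adapter_min_overlap_fwd=cfg["qc"]["adapter_min_overlap"],
            adapter_min_overlap_rev=cfg["qc"]["adapter_min_overlap"],
        )
        tallies = []
        for sample in cohort.samples:
            survivors, tally = qc_pipeline(sample.pairs, fc, sample.sample_id)
            sample.pairs = survivors
            tallies.append(tally)
        qc_summary = qc_report_summary(tallies).to_dict()

    qf = cfg["quantify"]
    index = build_gene_index(genomes, k=qf["k"])
    per_sample = {}
    for sample in cohort.samples:
        seqs = [p.seq1 for p in sample.pairs] + [p.seq2 for p in sample.pairs]
        per_sample[sample.sample_id] = assign_reads(
            seqs, index, max_kmers_per_read=qf["max_kmers_per_read"]
        )
    tpm, _counts = tpm_table(per_sample, index.lengths)
    og_table, _unassigned = aggregate_orthologs(tpm, clus_a)

    og_map_a = {frozenset(m): og for og, m in clus_a.groups.items()}
    consensus_ids = [a.og_id for a, _ in consensus.consensus]
    groups = cohort.metadata["group"]
    da = ortholog_da_report(og_table, groups, case_label=cohort_spec.group_labels[1],
                            og_ids=consensus_ids)

    planted_in_a = {og_map_a.get(frozenset(m)) for tid, m in truth.og_membership.items()
                    if tid in truth.planted_specific_ids}
    summary = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "n_strains": len(genomes),
        "consensus_calls": consensus_ids,
        "method_exclusive": {
            "A": [c.og_id for c in consensus.only_a],
            "B": [c.og_id for c in consensus.only_b],
        },
        "adjacency_blocks": [
            {"strain": b.strain_id, "start": b.start_index, "end": b.end_index,
             "og_ids": list(b.og_ids)} for b in blocks
        ],
        "differential_abundance": {
            og: {"p_value": float(da.loc[og, "p_value"]),
                 "q_value": float(da.loc[og, "q_value"]),
                 "log2_fold_change": float(da.loc[og, "log2_fold_change"])}
            for og in consensus_ids if og in da.index and bool(da.loc[og, "tested"])
        },
        "planted_recovered": sorted(x for x in planted_in_a if x is not None),
        "qc": qc_summary,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        og_table.to_csv(out / "ortholog_abundance.tsv", sep="\t")
        da.to_csv(out / "ortholog_da.tsv", sep="\t")
        cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    return summary
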