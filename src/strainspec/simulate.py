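"""Synthetic pan-genomes, cohort metagenomes and genus tables with planted truth.

The generator emulates the study design the toolkit targets: a dozen
conspecific bacterial strains sharing a core gene set plus accessory genes,
with "specific" ortholog blocks planted in designated strain subsets; two
cohorts (healthy vs an MCI-like case group) of paired-end 150-bp shotgun
samples whose strain mixtures differ so the planted orthologs become
group-differential; and genus-level count tables with planted fold-changes
and a cognitive-score covariate.  Every planted feature is recorded in a
truth table so downstream stages can be scored exactly.

Gene sequences are i.i.d. stop-free codons (no phylogenetic realism); the
within-group copies differ by an i.i.d. per-site substitution process.
Reads are exact substrings of gene sequences, so the k-mer quantifier can
recover planted abundances without a sequencing-error model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .orthology import Gene, StrainGeneSet
from .qc import ReadPair, packaged_decoy, revcomp

__all__ = [
    "PlantedDirective",
    "PanGenomeSpec",
    "TruthTable",
    "CohortSimSpec",
    "ContaminantFractions",
    "SampleReads",
    "CohortData",
    "simulate_pangenome",
    "simulate_metagenome_cohort",
    "simulate_genus_table",
    "make_group_mixtures",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


@dataclass(frozen=True)
class PlantedDirective:
    """One planted specific-ortholog block: strain subset, run length, KO policy."""

    strains: tuple[str, ...]
    length: int
    ko_policy: str = "unique"  # "unique" labels each planted group; "none" leaves them blank


@dataclass
class PanGenomeSpec:
    n_strains: int = 12
    core_size: int = 30
    accessory_size: int = 40
    planted_specific: list[PlantedDirective] = field(default_factory=list)
    gene_length_range: tuple[int, int] = (300, 900)
    mutation_rate: float = 0.01
    seed: int = 0
    strain_names: tuple[str, ...] | None = None

    def names(self) -> tuple[str, ...]:
        if self.strain_names is not None:
            return self.strain_names
        return tuple(f"Fp{i:02d}" for i in range(1, self.n_strains + 1))

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if not 0.0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")
        lo, hi = self.gene_length_range
        if lo < 90 or hi < lo:
            raise ValueError("invalid gene_length_range")
        names = set(self.names())
        if len(names) != self.n_strains:
            raise ValueError("strain names must be unique and match n_strains")
        planted_total = 0
        for d in self.planted_specific:
            if d.length < 1:
                raise ValueError("planted block length must be >= 1")
            if not d.strains or not set(d.strains) <= names:
                raise ValueError(f"planted strain subset {d.strains} not a subset of strains")
            planted_total += d.length
        if planted_total > self.accessory_size:
            raise ValueError(
                f"planted blocks need {planted_total} accessory groups but "
                f"accessory_size is {self.accessory_size}"
            )


@dataclass
class TruthTable:
    """Ground truth recorded by the generator."""

    og_membership: dict[str, set[tuple[str, str]]]
    planted_specific_ids: set[str]
    planted_targets: dict[str, tuple[str, ...]]
    ko_truth: dict[tuple[str, str], str | None]
    adjacency_blocks: list[tuple[str, int, int, tuple[str, ...]]]

    def partition_ok(self) -> bool:
        seen: set[tuple[str, str]] = set()
        for members in self.og_membership.values():
            if seen & members:
                return False
            seen |= members
        return True


def _random_gene_nt(rng: np.random.Generator, length_codons: int) -> str:
    return "".join(_SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), length_codons)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [b for b in "ACGT" if b != base]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def _translate(nt: str) -> str:
    return str(Seq(nt).translate()).replace("*", "W")  # mutated stops kept as residues


def simulate_pangenome(spec: PanGenomeSpec) -> tuple[list[StrainGeneSet], TruthTable]:
    """Generate strain gene sets and the matching truth table.

    Core groups have one copy per strain; planted directives yield runs of
    consecutive genes present only (and in every one) of their strain
    subset; the remaining accessory groups land on random strain subsets of
    size >= 2 that never coincide with a planted subset (so planted truth
    is unambiguous).  Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    strains = spec.names()
    lo, hi = spec.gene_length_range
    planted_subsets = {frozenset(d.strains) for d in spec.planted_specific}

    # one entry per group: (og_id, member strains, planted?, block tag)
    og_counter = 0
    groups: list[tuple[str, tuple[str, ...], bool, int | None]] = []
    for _ in range(spec.core_size):
        og_counter += 1
        groups.append((f"tOG{og_counter:05d}", strains, False, None))
    planted_total = 0
    for block_no, d in enumerate(spec.planted_specific):
        planted_total += d.length
        for _ in range(d.length):
            og_counter += 1
            groups.append((f"tOG{og_counter:05d}", tuple(d.strains), True, block_no))
    for _ in range(spec.accessory_size - planted_total):
        og_counter += 1
        while True:
            size = int(rng.integers(2, spec.n_strains)) if spec.n_strains > 2 else 2
            members = frozenset(rng.choice(spec.n_strains, size=size, replace=False))
            member_names = frozenset(strains[i] for i in members)
            if member_names not in planted_subsets:
                break
        groups.append((f"tOG{og_counter:05d}", tuple(sorted(member_names)), False, None))

    ancestral = {
        og: _random_gene_nt(rng, int(rng.integers(lo // 3, hi // 3 + 1)))
        for og, *_ in groups
    }

    # per strain: assemble units (planted blocks stay contiguous), shuffle, lay out
    ko_truth: dict[tuple[str, str], str | None] = {}
    og_membership: dict[str, set[tuple[str, str]]] = {og: set() for og, *_ in groups}
    planted_ids = {og for og, _, planted, _ in groups if planted}
    planted_targets = {og: members for og, members, planted, _ in groups if planted}
    planted_ko = {}
    for d_no, d in enumerate(spec.planted_specific):
        block_ogs = [og for og, _, planted, b in groups if planted and b == d_no]
        for og in block_ogs:
            planted_ko[og] = f"K{90000 + int(og[3:]):05d}" if d.ko_policy == "unique" else None

    gene_sets: list[StrainGeneSet] = []
    adjacency: list[tuple[str, int, int, tuple[str, ...]]] = []
    for strain in strains:
        units: list[list[str]] = []
        for d_no in range(len(spec.planted_specific)):
            d = spec.planted_specific[d_no]
            if strain in d.strains:
                units.append([og for og, _, planted, b in groups if planted and b == d_no])
        for og, members, planted, _ in groups:
            if not planted and strain in members:
                units.append([og])
        order = rng.permutation(len(units))
        genes: list[Gene] = []
        idx = 0
        for u in order:
            unit = units[u]
            start = idx + 1
            for og in unit:
                idx += 1
                nt = _mutate(rng, ancestral[og], spec.mutation_rate)
                gene_id = f"{strain}:g{idx:05d}"
                genes.append(Gene(idx, gene_id, nt, _translate(nt)))
                og_membership[og].add((strain, gene_id))
                ko_truth[(strain, gene_id)] = planted_ko.get(og)
            if len(unit) > 1:
                adjacency.append((strain, start, idx, tuple(unit)))
        gene_sets.append(StrainGeneSet(strain_id=strain, genes=genes))

    truth = TruthTable(
        og_membership=og_membership,
        planted_specific_ids=planted_ids,
        planted_targets=planted_targets,
        ko_truth=ko_truth,
        adjacency_blocks=adjacency,
    )
    assert truth.partition_ok()
    return gene_sets, truth


@dataclass(frozen=True)
class ContaminantFractions:
    phix: float = 0.0
    host: float = 0.0
    adapter: float = 0.0
    n_base: float = 0.0
    lowq_tail: float = 0.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.phix, self.host, self.adapter, self.n_base, self.lowq_tail)


@dataclass
class CohortSimSpec:
    group_sizes: tuple[int, int] = (20, 15)
    group_labels: tuple[str, str] = ("healthy", "MCI")
    strain_mixtures: dict[str, np.ndarray] | None = None
    target_strains: tuple[str, ...] = ()
    target_weight_healthy: float = 0.35
    effect_size: float = 4.0
    reads_per_sample: int = 3000  # read pairs (fragments)
    read_length: int = 150
    contaminant_fractions: ContaminantFractions = field(default_factory=ContaminantFractions)
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    with_quality: bool = True
    seed: int = 0

    def validate(self, strains: list[str]) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        fr = self.contaminant_fractions.as_tuple()
        if any(f < 0 or f > 1 for f in fr) or sum(fr) >= 1:
            raise ValueError("contaminant fractions must lie in [0,1] and sum < 1")
        if self.strain_mixtures is not None:
            for label, mix in self.strain_mixtures.items():
                if len(mix) != len(strains) or not np.isclose(np.sum(mix), 1.0):
                    raise ValueError(f"mixture for {label} must sum to 1 over {len(strains)} strains")


def make_group_mixtures(
    strains: list[str],
    target_strains: tuple[str, ...],
    target_weight_healthy: float,
    effect_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Healthy/case probability vectors differing only in target-strain weight.

    The target strains carry ``target_weight_healthy`` total weight in the
    healthy group and that weight divided by ``effect_size`` in the case
    group; the remainder is spread uniformly over the other strains.
    """
    n = len(strains)
    targets = [i for i, s in enumerate(strains) if s in target_strains]
    if not targets:
        raise ValueError("no target strains found")
    others = [i for i in range(n) if i not in targets]

    def mixture(weight: float) -> np.ndarray:
        mix = np.zeros(n)
        mix[targets] = weight / len(targets)
        mix[others] = (1.0 - weight) / len(others)
        return mix

    return mixture(target_weight_healthy), mixture(target_weight_healthy / effect_size)


@dataclass
class SampleReads:
    sample_id: str
    group: str
    pairs: list[ReadPair]
    origin_counts: Counter  # gene_key (strain, gene_id) -> fragment count
    contaminant_counts: Counter  # category -> fragment count


@dataclass
class CohortData:
    samples: list[SampleReads]
    metadata: pd.DataFrame
    truth_abundance: pd.DataFrame  # samples x gene_id fragment-origin counts


_CATEGORIES = ("clean", "phix", "host", "adapter", "n_base", "lowq_tail")


def simulate_metagenome_cohort(
    genomes: list[StrainGeneSet],
    truth: TruthTable | None,
    spec: CohortSimSpec,
) -> CohortData:
    """Simulate paired-end cohort samples from strain mixtures.

    Clean fragments are exact substrings of gene sequences; strain is drawn
    per the group mixture and the gene within a strain proportionally to
    its length.  Contaminant fragments are injected at the configured
    fractions.  Per-sample fragment-origin counts (the truth abundances)
    plus contaminant counts always sum to ``reads_per_sample``.
    """
    if not genomes:
        raise ValueError("no genomes")
    strains = [gs.strain_id for gs in genomes]
    spec.validate(strains)
    rng = np.random.default_rng(spec.seed)
    L = spec.read_length

    if spec.strain_mixtures is None:
        healthy_mix, case_mix = make_group_mixtures(
            strains, spec.target_strains, spec.target_weight_healthy, spec.effect_size
        )
        mixtures = {spec.group_labels[0]: healthy_mix, spec.group_labels[1]: case_mix}
    else:
        mixtures = {k: np.asarray(v, dtype=float) for k, v in spec.strain_mixtures.items()}

    genes_flat: list[tuple[tuple[str, str], str, int]] = []
    strain_of_gene: list[int] = []
    for si, gs in enumerate(genomes):
        for g in gs.genes:
            genes_flat.append(((gs.strain_id, g.gene_id), g.nucleotide, len(g.nucleotide)))
            strain_of_gene.append(si)
    lengths = np.array([g[2] for g in genes_flat], dtype=float)
    strain_idx = np.array(strain_of_gene)
    strain_len_tot = np.zeros(len(strains))
    np.add.at(strain_len_tot, strain_idx, lengths)

    phix_seq = packaged_decoy("phix")
    host_seq = packaged_decoy("host")
    frac = spec.contaminant_fractions
    cat_p = np.array([1.0 - sum(frac.as_tuple()), *frac.as_tuple()])
    adapter_fwd = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

    flat_q = "I" * L  # Phred 40 placeholder when qualities are disabled

    def qual_block(n: int) -> np.ndarray | None:
        if not spec.with_quality:
            return None
        q = rng.normal(spec.quality_mean, spec.quality_sd, size=(n, L))
        return np.clip(np.rint(q), 2, 40).astype(np.uint8) + 33

    samples: list[SampleReads] = []
    meta_rows = []
    for gi, (label, n_samples) in enumerate(zip(spec.group_labels, spec.group_sizes)):
        mix = mixtures[label]
        p_gene = mix[strain_idx] * lengths / strain_len_tot[strain_idx]
        p_gene = p_gene / p_gene.sum()
        for k in range(n_samples):
            sid = f"{label}_{k + 1:03d}"
            n = spec.reads_per_sample
            cats = rng.choice(len(_CATEGORIES), size=n, p=cat_p)
            gene_choice = rng.choice(len(genes_flat), size=n, p=p_gene)
            u_start = rng.random(n)
            u_frag = rng.random(n)
            q1 = qual_block(n)
            q2 = qual_block(n)
            pairs: list[ReadPair] = []
            origin: Counter = Counter()
            contam: Counter = Counter()
            for i in range(n):
                cat = _CATEGORIES[cats[i]]
                rid = f"{sid}:r{i:07d}"
                if cat in ("phix", "host"):
                    src = phix_seq if cat == "phix" else host_seq
                    start = int(u_start[i] * (len(src) - 2 * L))
                    frag = src[start:start + 2 * L]
                    contam[cat] += 1
                else:
                    gidx = int(gene_choice[i])
                    key, seq, glen = genes_flat[gidx]
                    if cat == "adapter":
                        flen = int(L - 60 + u_frag[i] * 40)  # insert shorter than a read
                    else:
                        flen = int(L + u_frag[i] * (min(2 * L, glen) - L + 1))
                    flen = max(min(flen, glen), 30)
                    start = int(u_start[i] * (glen - flen + 1))
                    frag = seq[start:start + flen]
                    if cat == "clean":
                        origin[key] += 1
                    else:  # adapter / n_base / lowq_tail fragments count as contaminants
                        contam[cat] += 1
                s1 = frag[:L]
                s2 = revcomp(frag[-L:]) if len(frag) >= L else revcomp(frag)
                if cat == "adapter":
                    s1 = s1 + adapter_fwd[: L - len(s1)] if len(s1) < L else s1
                    s2 = s2 + adapter_fwd[: L - len(s2)] if len(s2) < L else s2
                qs1 = q1[i, : len(s1)].tobytes().decode() if q1 is not None else flat_q[: len(s1)]
                qs2 = q2[i, : len(s2)].tobytes().decode() if q2 is not None else flat_q[: len(s2)]
                if cat == "n_base":
                    pos = int(u_frag[i] * len(s1))
                    s1 = s1[:pos] + "N" + s1[pos + 1:]
                elif cat == "lowq_tail":
                    run = 10 + int(u_frag[i] * 51)  # 10-60 low-quality 3' bases
                    run = min(run, len(qs1))
                    low = (rng.integers(2, 18, run).astype(np.uint8) + 33).tobytes().decode()
                    qs1 = qs1[: len(qs1) - run] + low
                pairs.append(ReadPair(rid, s1, qs1, s2, qs2))
            assert sum(origin.values()) + sum(contam.values()) == n
            samples.append(SampleReads(sid, label, pairs, origin, contam))
            meta_rows.append({"sample_id": sid, "group": label})

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    all_genes = [key for key, _, _ in genes_flat]
    truth_ab = pd.DataFrame(
        [[s.origin_counts.get(g, 0) for g in all_genes] for s in samples],
        index=[s.sample_id for s in samples],
        columns=[f"{k[0]}|{k[1]}" for k in all_genes],
    )
    return CohortData(samples=samples, metadata=metadata, truth_abundance=truth_ab)


def truth_ko_reference(genomes: list[StrainGeneSet], truth: TruthTable) -> dict[str, str]:
    """KO reference built from one representative protein per labelled planted group."""
    by_strain = {g.strain_id: g for g in genomes}
    reference: dict[str, str] = {}
    for og in sorted(truth.planted_specific_ids):
        strain, gid = sorted(truth.og_membership[og])[0]
        label = truth.ko_truth[(strain, gid)]
        if label is not None:
            reference[f"{label}|{og}"] = by_strain[strain].gene_by_id(gid).protein
    return reference


def simulate_genus_table(
    n_per_group: tuple[int, int] = (20, 15),
    n_genera: int = 60,
    planted_effects: dict[str, float] | None = None,
    score_link: tuple[str, float] | None = None,
    depth: int = 30000,
    group_labels: tuple[str, str] = ("healthy", "MCI"),
    noise_sd: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genus count table with planted group fold-changes and a score covariate.

    Counts follow a compositional log-normal/multinomial model: per-genus
    baseline log-abundances, per-sample log-normal noise, then multinomial
    sampling at the stated depth.  ``planted_effects`` maps genus name to
    the case/healthy fold-change in expectation (must be > 0).
    ``score_link`` ties a continuous cognitive-like score to one genus's
    latent abundance with the requested correlation via a Gaussian copula.
    """
    if n_per_group[0] <= 0 or n_per_group[1] <= 0 or n_genera <= 0:
        raise ValueError("counts must be positive")
    planted_effects = planted_effects or {}
    rng = np.random.default_rng(seed)
    genera = [f"g__{i:03d}" for i in range(1, n_genera + 1)]
    for g, fold in planted_effects.items():
        if fold <= 0:
            raise ValueError(f"fold-change for {g} must be > 0")
        if g not in genera:
            raise KeyError(g)

    base = rng.normal(0.0, 1.5, n_genera)
    n_total = sum(n_per_group)
    group = np.array([group_labels[0]] * n_per_group[0] + [group_labels[1]] * n_per_group[1])
    z = rng.normal(0.0, 1.0, size=(n_total, n_genera))
    logab = base[None, :] + noise_sd * z
    for g, fold in planted_effects.items():
        j = genera.index(g)
        logab[group == group_labels[1], j] += np.log(fold)
    rel = np.exp(logab)
    rel = rel / rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, rel[i]) for i in range(n_total)])

    sample_ids = [f"{lab}_{i + 1:03d}" for lab in group_labels
                  for i in range(n_per_group[group_labels.index(lab)])]
    table = pd.DataFrame(counts, index=sample_ids, columns=genera)
    meta = pd.DataFrame({"group": group}, index=sample_ids)
    if score_link is not None:
        genus, rho = score_link
        j = genera.index(genus)
        eps = rng.normal(0.0, 1.0, n_total)
        zscore = rho * z[:, j] + np.sqrt(max(1.0 - rho**2, 0.0)) * eps
        meta["score"] = 23.0 + 4.0 * zscore
    return table, meta
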