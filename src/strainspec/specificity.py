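"""Strain-specific ortholog calling, two-method consensus, adjacency blocks.

A "specific ortholog" for a target strain subset is an ortholog group that
either (i) occurs only in the target strains — and, by default, in every
one of them — (presence rule), or (ii) contains a gene whose KO label
occurs, across all genes of all strains, only in genes of the target
strains (KO rule).  Calls from the two independent clusterings are matched
into a consensus by member-gene Jaccard overlap; groups called by only one
method are reported as method-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orthology import KOAnnotation, OrthologClustering, StrainGeneSet

__all__ = [
    "SpecificOrthologCall",
    "AdjacencyBlock",
    "ConsensusResult",
    "presence_absence",
    "call_specific_orthologs",
    "consensus_calls",
    "find_adjacent_blocks",
]


@dataclass(frozen=True)
class SpecificOrthologCall:
    og_id: str
    target_set: frozenset[str]
    rule: str  # presence_only | ko_only | both
    triggering_kos: tuple[str, ...]
    members: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class AdjacencyBlock:
    strain_id: str
    start_index: int
    end_index: int
    og_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class ConsensusResult:
    consensus: list[tuple[SpecificOrthologCall, SpecificOrthologCall]]
    only_a: list[SpecificOrthologCall] = field(default_factory=list)
    only_b: list[SpecificOrthologCall] = field(default_factory=list)


def presence_absence(clustering: OrthologClustering, strains: list[str]) -> pd.DataFrame:
    """OG x strain matrix of member gene counts (no thresholding)."""
    known = set(strains)
    for members in clustering.groups.values():
        for strain, _ in members:
            if strain not in known:
                raise ValueError(f"strain {strain} in clustering but not in strain list")
    rows = {}
    for og, members in clustering.groups.items():
        counts = dict.fromkeys(strains, 0)
        for strain, _ in members:
            counts[strain] += 1
        rows[og] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=strains).fillna(0).astype(int)


def call_specific_orthologs(
    clustering: OrthologClustering,
    ko: KOAnnotation,
    target_set: set[str],
    all_strains: list[str],
    require_all_targets: bool = True,
) -> list[SpecificOrthologCall]:
    """Apply the presence and KO rules against one target strain subset."""
    targets = frozenset(target_set)
    if not targets or not targets <= set(all_strains):
        raise ValueError(f"target set {sorted(targets)} is not a non-empty subset of strains")

    # genome-wide KO -> strains owning a gene with that KO
    ko_strains: dict[str, set[str]] = {}
    for (strain, _), label in ko.labels.items():
        if label is not None:
            ko_strains.setdefault(label, set()).add(strain)

    def covers(strains_present: set[str]) -> bool:
        if not strains_present <= targets:
            return False
        return strains_present == targets if require_all_targets else bool(strains_present)

    calls: list[SpecificOrthologCall] = []
    for og, members in sorted(clustering.groups.items()):
        member_strains = {s for s, _ in members}
        presence = covers(member_strains)
        exclusive_kos = []
        for label in sorted({ko.labels.get(m) for m in members} - {None}):
            if covers(ko_strains.get(label, set())):
                exclusive_kos.append(label)
        if presence and exclusive_kos:
            rule = "both"
        elif presence:
            rule = "presence_only"
        elif exclusive_kos:
            rule = "ko_only"
        else:
            continue
        calls.append(
            SpecificOrthologCall(
                og_id=og,
                target_set=targets,
                rule=rule,
                triggering_kos=tuple(exclusive_kos),
                members=frozenset(members),
            )
        )
    return calls


def _target_genes(call: SpecificOrthologCall) -> frozenset[tuple[str, str]]:
    return frozenset(m for m in call.members if m[0] in call.target_set)


def consensus_calls(
    calls_a: list[SpecificOrthologCall],
    calls_b: list[SpecificOrthologCall],
    min_jaccard: float = 0.5,
) -> ConsensusResult:
    """Pair calls across methods by member-gene Jaccard within target strains.

    Greedy best-first matching: highest-Jaccard pair first, each call used
    at most once; pairs below ``min_jaccard`` are left unpaired and
    reported as method-exclusive.
    """
    if calls_a and calls_b:
        ta = {c.target_set for c in calls_a}
        tb = {c.target_set for c in calls_b}
        if ta != tb:
            raise ValueError("call lists target different strain sets")
    scored = []
    for i, ca in enumerate(calls_a):
        ga = _target_genes(ca)
        for j, cb in enumerate(calls_b):
            gb = _target_genes(cb)
            union = ga | gb
            jac = len(ga & gb) / len(union) if union else 0.0
            if jac >= min_jaccard:
                scored.append((jac, i, j))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[SpecificOrthologCall, SpecificOrthologCall]] = []
    for jac, i, j in scored:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((calls_a[i], calls_b[j]))
    only_a = [c for i, c in enumerate(calls_a) if i not in used_a]
    only_b = [c for j, c in enumerate(calls_b) if j not in used_b]
    return ConsensusResult(consensus=pairs, only_a=only_a, only_b=only_b)


def find_adjacent_blocks(
    calls: list[SpecificOrthologCall],
    gene_sets: list[StrainGeneSet],
) -> list[AdjacencyBlock]:
    """Maximal runs of called groups at consecutive gene indices, per strain.

    Blocks of length 1 are reported too.  Linear order only: a wraparound
    of a circular chromosome is not treated as adjacent.
    """
    index_of: dict[tuple[str, str], int] = {
        (gs.strain_id, g.gene_id): g.gene_index for gs in gene_sets for g in gs.genes
    }
    per_strain: dict[str, list[tuple[int, str]]] = {}
    for call in calls:
        for strain, gene_id in call.members:
            if strain in call.target_set:
                per_strain.setdefault(strain, []).append((index_of[(strain, gene_id)], call.og_id))
    blocks: list[AdjacencyBlock] = []
    for strain in sorted(per_strain):
        entries = sorted(set(per_strain[strain]))
        run: list[tuple[int, str]] = []
        for idx, og in entries:
            if run and idx == run[-1][0] + 1:
                run.append((idx, og))
            else:
                if run:
                    blocks.append(AdjacencyBlock(strain, run[0][0], run[-1][0], tuple(o for _, o in run)))
                run = [(idx, og)]
        if run:
            blocks.append(AdjacencyBlock(strain, run[0][0], run[-1][0], tuple(o for _, o in run)))
    return blocks
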