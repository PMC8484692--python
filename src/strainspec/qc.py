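"""Seven-step quality-control cascade for paired shotgun metagenome reads.

Filter order, applied per read with orphan removal last:

1. discard reads containing ``N``;
2. discard reads matching the PhiX-like decoy;
3. trim the 3' adapter (minimum-overlap match, 10% mismatches allowed) and
   then cut the maximal 3' suffix whose qualities are all <= the cutoff;
4. discard reads shorter than the minimum length;
5. discard reads whose mean quality is <= the mean-quality cutoff;
6. discard reads matching the host-like decoy;
7. discard reads whose mate was discarded at any earlier step.

Decoy "mapping" is shared-k-mer containment against a packaged synthetic
decoy sequence (both synthetic stand-ins, not real PhiX/GRCh38), with a
read flagged when at least T of its distinct canonical k-mers occur in the
decoy (default T = half the read's k-mer count, rounded up).

The report arithmetic mirrors the read/base-pair accounting convention of
shotgun QC summaries: totals, per-sample averages (rounded half away from
zero for display) and base pairs as reads x nominal length for fixed-length
stages or the sum of surviving lengths after trimming.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ReadPair",
    "FilterConfig",
    "SampleTally",
    "QCReport",
    "qc_pipeline",
    "trim_read_3prime",
    "decoy_match",
    "build_decoy_index",
    "qc_report_summary",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "packaged_decoy",
]

FILTER_STAGES = ("n_bases", "phix", "length", "mean_quality", "host", "unpaired")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadPair:
    """A paired-end read: id plus (sequence, Phred+33 quality) per mate."""

    __slots__ = ("read_id", "seq1", "qual1", "seq2", "qual2")

    def __init__(self, read_id: str, seq1: str, qual1: str, seq2: str, qual2: str):
        self.read_id = read_id
        self.seq1 = seq1
        self.qual1 = qual1
        self.seq2 = seq2
        self.qual2 = qual2

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReadPair({self.read_id!r}, {len(self.seq1)}bp/{len(self.seq2)}bp)"


def packaged_decoy(which: str) -> str:
    """Return one of the packaged synthetic decoy sequences ('phix'|'host')."""
    name = {"phix": "phix_like_synthetic.fasta", "host": "host_like_synthetic.fasta"}[which]
    ref = resources.files("strainspec") / "data" / name
    with ref.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def build_decoy_index(sequences: Iterable[str], k: int = 21) -> frozenset[str]:
    """Canonical k-mer set of the decoy sequences (both strands)."""
    kmers: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                kmers.add(s[i:i + k])
    return frozenset(kmers)


@dataclass
class FilterConfig:
    """Cascade parameters; defaults follow the shotgun-metagenome settings."""

    adapter_fwd: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    adapter_rev: str = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"
    adapter_min_overlap_fwd: int = 32
    adapter_min_overlap_rev: int = 32
    adapter_max_error_rate: float = 0.10
    tail_quality_cutoff: int = 17
    min_length: int = 50
    min_mean_quality: float = 25.0
    decoy_k: int = 21
    decoy_min_hits: int | None = None  # None -> ceil(n_kmers / 2)
    phix_index: frozenset[str] | None = None
    host_index: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.tail_quality_cutoff < 0 or self.min_length <= 0 or self.decoy_k <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def with_packaged_decoys(cls, **kwargs) -> "FilterConfig":
        cfg = cls(**kwargs)
        cfg.phix_index = build_decoy_index([packaged_decoy("phix")], cfg.decoy_k)
        cfg.host_index = build_decoy_index([packaged_decoy("host")], cfg.decoy_k)
        return cfg


def decoy_match(seq: str, decoy_index: frozenset[str] | None, k: int, min_hits: int | None = None) -> bool:
    """True iff >= T distinct k-mers of the read occur in the decoy index.

    The index stores both strands, so the read itself need not be
    reverse-complemented.  T defaults to half the read's k-mer count
    (rounded up); a read shorter than k never matches.
    """
    if not decoy_index or len(seq) < k:
        return False
    kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    threshold = min_hits if min_hits is not None else math.ceil(len(kmers) / 2)
    found = 0
    for kmer in kmers:
        if kmer in decoy_index:
            found += 1
            if found >= threshold:
                return True
    return False


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_error_rate: float) -> int | None:
    """Leftmost 3' adapter start, or None.

    A match is either the adapter (or its prefix, for matches running off
    the read's 3' end) aligned at position i with overlap >= ``min_overlap``
    and at most ``floor(max_error_rate * overlap)`` mismatches.
    """
    n, m = len(seq), len(adapter)
    for i in range(n - min_overlap + 1):
        overlap = min(m, n - i)
        if overlap < min_overlap:
            break
        allowed = int(max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i:i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return None


def trim_read_3prime(
    seq: str,
    qual: str,
    adapter: str,
    min_overlap: int = 32,
    q_cutoff: int = 17,
    max_error_rate: float = 0.10,
) -> tuple[str, str]:
    """Remove a 3' adapter match, then the maximal all-low-quality 3' suffix."""
    pos = _find_adapter(seq, adapter, min_overlap, max_error_rate)
    if pos is not None:
        seq, qual = seq[:pos], qual[:pos]
    cut = len(qual)
    while cut > 0 and ord(qual[cut - 1]) - 33 <= q_cutoff:
        cut -= 1
    return seq[:cut], qual[:cut]


def _mean_quality(qual: str) -> float:
    return sum(qual.encode()) / len(qual) - 33.0 if qual else 0.0


@dataclass
class SampleTally:
    """Read/base-pair accounting for one sample through the cascade."""

    sample_id: str
    input_reads: int = 0
    input_bp: int = 0
    surviving_reads: int = 0
    surviving_bp: int = 0
    discarded: dict[str, int] = field(default_factory=lambda: {s: 0 for s in FILTER_STAGES})

    def check_conservation(self) -> None:
        if self.input_reads != self.surviving_reads + sum(self.discarded.values()):
            raise AssertionError(f"{self.sample_id}: read accounting does not balance")


def _mate_fate(seq: str, qual: str, cfg: FilterConfig, adapter: str, min_overlap: int
               ) -> tuple[str | None, str, str]:
    """Fate of one mate through steps 1-6: (discard stage or None, seq, qual)."""
    if "N" in seq:
        return "n_bases", seq, qual
    if decoy_match(seq, cfg.phix_index, cfg.decoy_k, cfg.decoy_min_hits):
        return "phix", seq, qual
    seq, qual = trim_read_3prime(
        seq, qual, adapter, min_overlap, cfg.tail_quality_cutoff, cfg.adapter_max_error_rate
    )
    if len(seq) < cfg.min_length:
        return "length", seq, qual
    if _mean_quality(qual) <= cfg.min_mean_quality:
        return "mean_quality", seq, qual
    if decoy_match(seq, cfg.host_index, cfg.decoy_k, cfg.decoy_min_hits):
        return "host", seq, qual
    return None, seq, qual


def qc_pipeline(
    pairs: Iterable[ReadPair],
    config: FilterConfig,
    sample_id: str = "sample",
) -> tuple[list[ReadPair], SampleTally]:
    """Run the full cascade over read pairs; returns survivors and the tally.

    Mates run through steps 1-6 independently; a read whose mate died at
    any earlier step is discarded as unpaired (step 7).
    """
    tally = SampleTally(sample_id=sample_id)
    survivors: list[ReadPair] = []
    for pair in pairs:
        if len(pair.seq1) != len(pair.qual1) or len(pair.seq2) != len(pair.qual2):
            raise ValueError(f"sequence/quality length mismatch in read {pair.read_id}")
        tally.input_reads += 2
        tally.input_bp += len(pair.seq1) + len(pair.seq2)
        fate1, s1, q1 = _mate_fate(
            pair.seq1, pair.qual1, config, config.adapter_fwd, config.adapter_min_overlap_fwd
        )
        fate2, s2, q2 = _mate_fate(
            pair.seq2, pair.qual2, config, config.adapter_rev, config.adapter_min_overlap_rev
        )
        if fate1 is None and fate2 is None:
            tally.surviving_reads += 2
            tally.surviving_bp += len(s1) + len(s2)
            survivors.append(ReadPair(pair.read_id, s1, q1, s2, q2))
        else:
            for fate in (fate1, fate2):
                tally.discarded[fate if fate is not None else "unpaired"] += 1
    tally.check_conservation()
    return survivors, tally


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class QCReport:
    """Aggregate accounting over samples, with display-rounded averages."""

    n_samples: int
    total_input_reads: int
    total_input_bp: int
    total_surviving_reads: int
    total_surviving_bp: int
    mean_input_reads: int
    mean_input_bp: int
    mean_surviving_reads: int
    mean_surviving_bp: int
    discarded: dict[str, int]
    per_sample: list[SampleTally]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "total_input_reads": self.total_input_reads,
            "total_input_bp": self.total_input_bp,
            "total_surviving_reads": self.total_surviving_reads,
            "total_surviving_bp": self.total_surviving_bp,
            "mean_input_reads": self.mean_input_reads,
            "mean_input_bp": self.mean_input_bp,
            "mean_surviving_reads": self.mean_surviving_reads,
            "mean_surviving_bp": self.mean_surviving_bp,
            "discarded": dict(self.discarded),
        }


def qc_report_summary(
    tallies: list[SampleTally],
    nominal_read_length: int | None = None,
) -> QCReport:
    """Aggregate per-sample tallies into totals and per-sample averages.

    With ``nominal_read_length`` given, base pairs are computed as
    reads x nominal length at both the input and surviving stages (the
    fixed-length accounting convention); otherwise the recorded
    (post-trimming) base-pair sums are used.
    """
    if not tallies:
        raise ValueError("no tallies")
    n = len(tallies)
    total_in = sum(t.input_reads for t in tallies)
    total_out = sum(t.surviving_reads for t in tallies)
    if nominal_read_length is not None:
        total_in_bp = total_in * nominal_read_length
        total_out_bp = total_out * nominal_read_length
    else:
        total_in_bp = sum(t.input_bp for t in tallies)
        total_out_bp = sum(t.surviving_bp for t in tallies)
    discarded: dict[str, int] = {s: 0 for s in FILTER_STAGES}
    for t in tallies:
        for stage, count in t.discarded.items():
            discarded[stage] = discarded.get(stage, 0) + count
    return QCReport(
        n_samples=n,
        total_input_reads=total_in,
        total_input_bp=total_in_bp,
        total_surviving_reads=total_out,
        total_surviving_bp=total_out_bp,
        mean_input_reads=_round_half_away(total_in / n),
        mean_input_bp=_round_half_away(total_in_bp / n),
        mean_surviving_reads=_round_half_away(total_out / n),
        mean_surviving_bp=_round_half_away(total_out_bp / n),
        discarded=discarded,
        per_sample=tallies,
    )


def read_fastq_pairs(r1_path: str, r2_path: str) -> Iterator[ReadPair]:
    """Stream read pairs from (optionally gzipped) FASTQ mate files."""

    def _open(path: str):
        return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            base1 = rec1.id.split("/")[0]
            base2 = rec2.id.split("/")[0]
            if base1 != base2:
                raise ValueError(f"mate id mismatch: {rec1.id} vs {rec2.id}")
            q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
            q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
            yield ReadPair(base1, str(rec1.seq), q1, str(rec2.seq), q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str, r2_path: str) -> None:
    """Write pairs to gzipped FASTQ mate files with /1 and /2 suffixes."""
    with gzip.open(r1_path, "wt") as fh1, gzip.open(r2_path, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
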