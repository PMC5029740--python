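"""Read size selection, exact mapping with fractional multi-mapper weights,
and per-reference start/end/depth coverage profiles.

Mapping is exact full-length, sense-strand substring matching. A read placed
at k locations (counting every position on every reference) carries weight
1/k at each location, so total weight is conserved per mapped read. Reads are
mapped to the mature reference first; only reads absent from every mature
sequence are offered to the extended (pre-tRNA) reference, which keeps mature
fragments from being double counted as leader/trailer coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .reference import normalize_rna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmallRNARead:
    read_id: str
    sequence: str
    library_id: str


@dataclass(frozen=True)
class Alignment:
    """One placement of a read. ``start``/``end`` are 1-based inclusive."""

    read_id: str
    library_id: str
    ref_id: str
    start: int
    end: int
    weight: float


@dataclass
class CoverageProfile:
    """Per-(reference, library) boundary and depth profiles.

    Arrays are 1-based: index 0 is unused padding so that ``start_counts[p]``
    is the weight of alignments starting at reference position p.
    """

    ref_id: str
    library_id: str
    start_counts: np.ndarray
    end_counts: np.ndarray
    depth: np.ndarray

    @property
    def length(self) -> int:
        return len(self.start_counts) - 1


def read_fastx(path: str | Path, library_id: str) -> list[SmallRNARead]:
    """Load reads from FASTA or FASTQ (by extension); qualities are ignored."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    return [
        SmallRNARead(rec.id, normalize_rna(str(rec.seq)), library_id)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def size_filter(
    reads: Sequence[SmallRNARead], min_len: int = 15, max_len: int = 35
) -> list[SmallRNARead]:
    """Keep reads whose length is within [min_len, max_len], order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in reads if min_len <= len(r.sequence) <= max_len]
    logger.info(
        "size filter [%d,%d]: kept %d / %d reads", min_len, max_len, len(kept), len(reads)
    )
    return kept


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i >= 0:
        hits.append(i + 1)
        i = haystack.find(needle, i + 1)
    return hits


def find_placements(
    sequences: Iterable[str], references: Mapping[str, str]
) -> dict[str, list[tuple[str, int, int]]]:
    """Map each distinct read sequence to all (ref_id, start, end) placements."""
    ref_items = sorted(references.items())
    placements: dict[str, list[tuple[str, int, int]]] = {}
    for seq in sequences:
        hits = []
        for ref_id, ref_seq in ref_items:
            for start in _occurrences(seq, ref_seq):
                hits.append((ref_id, start, start + len(seq) - 1))
        placements[seq] = hits
    return placements


def map_reads(
    reads: Sequence[SmallRNARead], references: Mapping[str, str]
) -> tuple[list[Alignment], list[SmallRNARead]]:
    """Exact-match reads against references, splitting weight across placements.

    Returns (alignments, unmapped_reads). Every mapped read contributes total
    weight exactly 1 spread uniformly over its k placements.
    """
    placements = find_placements({r.sequence for r in reads}, references)
    alignments: list[Alignment] = []
    unmapped: list[SmallRNARead] = []
    for read in reads:
        hits = placements[read.sequence]
        if not hits:
            unmapped.append(read)
            continue
        w = 1.0 / len(hits)
        for ref_id, start, end in hits:
            alignments.append(
                Alignment(read.read_id, read.library_id, ref_id, start, end, w)
            )
    logger.info(
        "mapped %d / %d reads (%d alignments)",
        len(reads) - len(unmapped), len(reads), len(alignments),
    )
    return alignments, unmapped


def map_two_pass(
    reads: Sequence[SmallRNARead],
    mature_refs: Mapping[str, str],
    extended_refs: Mapping[str, str],
) -> tuple[list[Alignment], list[Alignment], list[SmallRNARead]]:
    """Mature-first two-pass mapping.

    Reads placed on any mature sequence are consumed by pass 1; the remainder
    is mapped to the extended reference. Returns
    (mature_alignments, extended_alignments, unmapped_reads).
    """
    mature_aln, leftover = map_reads(reads, mature_refs)
    extended_aln, unmapped = map_reads(leftover, extended_refs)
    return mature_aln, extended_aln, unmapped


def build_profiles(
    alignments: Sequence[Alignment], ref_lengths: Mapping[str, int]
) -> dict[tuple[str, str], CoverageProfile]:
    """Accumulate start/end/depth profiles per (ref_id, library_id)."""
    profiles: dict[tuple[str, str], CoverageProfile] = {}
    for aln in alignments:
        if aln.ref_id not in ref_lengths:
            raise KeyError(f"alignment on unknown reference {aln.ref_id!r}")
        n = ref_lengths[aln.ref_id]
        if not (1 <= aln.start <= aln.end <= n):
            raise ValueError(
                f"alignment [{aln.start},{aln.end}] outside reference "
                f"{aln.ref_id} of length {n}"
            )
        key = (aln.ref_id, aln.library_id)
        prof = profiles.get(key)
        if prof is None:
            prof = CoverageProfile(
                ref_id=aln.ref_id,
                library_id=aln.library_id,
                start_counts=np.zeros(n + 1),
                end_counts=np.zeros(n + 1),
                depth=np.zeros(n + 1),
            )
            profiles[key] = prof
        prof.start_counts[aln.start] += aln.weight
        prof.end_counts[aln.end] += aln.weight
        prof.depth[aln.start : aln.end + 1] += aln.weight
    return profiles


def pool_profiles(
    profiles: Mapping[tuple[str, str], CoverageProfile]
) -> dict[str, CoverageProfile]:
    """Sum per-library profiles into one pooled profile per reference."""
    pooled: dict[str, CoverageProfile] = {}
    for (ref_id, _lib), prof in sorted(profiles.items()):
        agg = pooled.get(ref_id)
        if agg is None:
            pooled[ref_id] = CoverageProfile(
                ref_id=ref_id,
                library_id="__pooled__",
                start_counts=prof.start_counts.copy(),
                end_counts=prof.end_counts.copy(),
                depth=prof.depth.copy(),
            )
        else:
            agg.start_counts += prof.start_counts
            agg.end_counts += prof.end_counts
            agg.depth += prof.depth
    return pooled


def write_alignments_tsv(alignments: Sequence[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tlibrary_id\tref_id\tstart\tend\tweight\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.library_id}\t{a.ref_id}\t{a.start}\t{a.end}\t"
                f"{a.weight:.10g}\n"
            )
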