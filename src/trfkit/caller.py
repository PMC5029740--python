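"""Fragment boundary calling from start/end coverage peaks.

Fragment ends of genuine tRFs pile up sharply at a few reference positions,
so candidate 5'/3' boundaries are local maxima of the start- and end-count
profiles. A (start, end) pair becomes a fragment call only when enough reads
support *both* boundaries jointly — a read must begin at the start peak and
finish at the end peak (within the boundary tolerance). Joint support is what
prevents chimeric calls when two distinct fragment populations overlap on one
precursor: a spurious pairing of one population's start with the other's end
has no jointly matching reads.

Peak detection and pairing run on profiles pooled across all libraries, so a
single fragment catalog is shared by the whole cohort; quantification is then
per library by re-mapping reads to the catalog sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mapping import Alignment, CoverageProfile, SmallRNARead


@dataclass
class CallerParams:
    """Tunable knobs of the boundary caller (all surfaced on the CLI)."""

    window: int = 4              # half-width of the local-maximum window, positions
    noise_fraction: float = 0.10  # peak must carry >= this fraction of the window max
    min_count: float = 2.0        # absolute floor on boundary weight at a peak
    min_support: float = 5.0      # minimum joint read weight for a call
    tol: int = 0                  # boundary tolerance when gathering support
    min_len: int = 15
    max_len: int = 35


@dataclass
class FragmentCall:
    ref_id: str
    start: int
    end: int
    sequence: str
    support: float
    per_library_support: dict[str, float] = field(default_factory=dict)

    @property
    def call_id(self) -> str:
        return f"{self.ref_id}:{self.start}-{self.end}"


def detect_boundary_peaks(
    counts: np.ndarray,
    noise_fraction: float = 0.10,
    min_count: float = 2.0,
    window: int = 4,
) -> list[int]:
    """Positions that are local maxima of a 1-based boundary-count vector.

    A position p qualifies when counts[p] >= min_count, counts[p] is at least
    noise_fraction of the maximum within [p-window, p+window], and no position
    in that window exceeds it; among tied positions within one window the
    smaller position wins.
    """
    if np.any(counts < 0):
        raise ValueError("boundary counts must be non-negative")
    n = len(counts) - 1
    peaks = []
    for p in range(1, n + 1):
        c = counts[p]
        if c < min_count:
            continue
        lo = max(1, p - window)
        hi = min(n, p + window)
        seg = counts[lo : hi + 1]
        wmax = seg.max()
        if c < noise_fraction * wmax:
            continue
        if c < wmax:
            continue
        # tie toward the smaller position: reject p if an equal count sits earlier
        if np.any(counts[lo:p] == c):
            continue
        peaks.append(p)
    return peaks


def call_fragments(
    pooled_profiles: Mapping[str, CoverageProfile],
    alignments: Sequence[Alignment],
    ref_seqs: Mapping[str, str],
    params: CallerParams | None = None,
) -> list[FragmentCall]:
    """Pair start and end peaks into fragment calls backed by joint read support."""
    params = params or CallerParams()
    # aggregate joint-boundary weight per (ref, start, end, library) once
    boundary_w: dict[str, dict[tuple[int, int], dict[str, float]]] = {}
    for aln in alignments:
        pairs = boundary_w.setdefault(aln.ref_id, {})
        libs = pairs.setdefault((aln.start, aln.end), {})
        libs[aln.library_id] = libs.get(aln.library_id, 0.0) + aln.weight

    calls: list[FragmentCall] = []
    for ref_id in sorted(pooled_profiles):
        prof = pooled_profiles[ref_id]
        starts = detect_boundary_peaks(
            prof.start_counts, params.noise_fraction, params.min_count, params.window
        )
        ends = detect_boundary_peaks(
            prof.end_counts, params.noise_fraction, params.min_count, params.window
        )
        if not starts or not ends:
            continue
        pairs = boundary_w.get(ref_id, {})
        tol = params.tol
        for s in starts:
            for e in ends:
                length = e - s + 1
                if not (params.min_len <= length <= params.max_len):
                    continue
                support = 0.0
                per_lib: dict[str, float] = {}
                for ds in range(-tol, tol + 1):
                    for de in range(-tol, tol + 1):
                        libs = pairs.get((s + ds, e + de))
                        if libs:
                            for lib, w in libs.items():
                                support += w
                                per_lib[lib] = per_lib.get(lib, 0.0) + w
                if support >= params.min_support:
                    calls.append(
                        FragmentCall(
                            ref_id=ref_id,
                            start=s,
                            end=e,
                            sequence=ref_seqs[ref_id][s - 1 : e],
                            support=support,
                            per_library_support=dict(sorted(per_lib.items())),
                        )
                    )
    calls.sort(key=lambda c: (c.ref_id, c.start, c.end))
    return calls


def quantify_calls(
    calls: Sequence[FragmentCall], reads: Sequence[SmallRNARead]
) -> "pd.DataFrame":
    """Re-map reads to the fragment catalog by exact sequence identity.

    Returns a call_id x library count matrix. A read whose sequence equals the
    sequence of k catalog calls contributes weight 1/k to each (identical-
    sequence calls are subsequently merged, restoring the full count).
    """
    import pandas as pd

    seq_to_calls: dict[str, list[str]] = {}
    for call in calls:
        seq_to_calls.setdefault(call.sequence, []).append(call.call_id)

    libraries = sorted({r.library_id for r in reads})
    counts: dict[str, dict[str, float]] = {c.call_id: {} for c in calls}
    for read in reads:
        hit = seq_to_calls.get(read.sequence)
        if not hit:
            continue
        w = 1.0 / len(hit)
        for call_id in hit:
            row = counts[call_id]
            row[read.library_id] = row.get(read.library_id, 0.0) + w

    mat = pd.DataFrame(
        [[counts[c.call_id].get(lib, 0.0) for lib in libraries] for c in calls],
        index=[c.call_id for c in calls],
        columns=libraries,
    )
    mat.index.name = "call_id"
    return mat


def write_calls_tsv(calls: Sequence[FragmentCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("call_id\tref_id\tstart\tend\tlength\tsequence\tsupport\n")
        for c in calls:
            fh.write(
                f"{c.call_id}\t{c.ref_id}\t{c.start}\t{c.end}\t{c.end - c.start + 1}\t"
                f"{c.sequence}\t{c.support:.10g}\n"
            )
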