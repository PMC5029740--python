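"""Unique-tRF catalog: identical-sequence merging, positional classification
and uniqueness/abundance summaries.

tRNA sequences are so conserved that the same fragment sequence is often
called on several precursors; such calls are merged into a single tRF and
their counts summed, because sequencing cannot attribute an identical read
to one locus. Every unique tRF then receives:

* an *origin* label — 5'-derived if its 3' end lies at mature position <= 40,
  3'-derived if its 5' end lies at position >= 30, otherwise "other";
* a *type* label from the five-class positional taxonomy keyed on the start
  position of the fragment on the mature tRNA: 5e (start 1), D (12-23),
  A (31-39), V (45-49), 3e (50-60); starts in the gaps stay unclassified;
* for fragments on the extended reference, a pre-tRNA label (5' leader /
  3' trailer) plus the gap in nucleotides to the mature boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import FragmentCall
from .reference import ExtendedReference

ORIGIN_FIVE = "five_prime"
ORIGIN_THREE = "three_prime"
ORIGIN_OTHER = "other"

TYPE_CLASSES = ("5e", "D", "A", "V", "3e")
_TYPE_RANGES = {"5e": (1, 1), "D": (12, 23), "A": (31, 39), "V": (45, 49), "3e": (50, 60)}


@dataclass
class TRFRecord:
    """One unique tRF: a sequence, its precursor placements, and class labels."""

    trf_id: str
    sequence: str
    members: list[tuple[str, int, int]]
    counts: dict[str, float]
    origin_class: str = ORIGIN_OTHER
    type_class: str = "unclassified"
    pre_trna_class: str = "none"
    adjacency_gap: int | None = None
    minority_classes: list[str] = field(default_factory=list)

    @property
    def total_count(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def length(self) -> int:
        return len(self.sequence)


def classify_origin(start: int, end: int) -> str:
    """5'/3' origin of a fragment from its mature-tRNA coordinates.

    End position <= 40 means 5'-derived; start position >= 30 means
    3'-derived. For any fragment of length >= 15 the two rules cannot both
    fire (start >= 30 and end <= 40 would force length <= 11).
    """
    if start < 1:
        raise ValueError(f"start {start} must be >= 1")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    if end <= 40:
        return ORIGIN_FIVE
    if start >= 30:
        return ORIGIN_THREE
    return ORIGIN_OTHER


def classify_type(start: int) -> str:
    """Five-class positional taxonomy from the fragment start on the mature tRNA."""
    if start < 1:
        raise ValueError(f"start {start} must be >= 1")
    for name, (lo, hi) in _TYPE_RANGES.items():
        if lo <= start <= hi:
            return name
    return "unclassified"


def classify_pre_trna(
    start: int, end: int, extended_ref: ExtendedReference
) -> tuple[str, int | None]:
    """Leader/trailer status of a fragment on an extended reference.

    Fragments entirely upstream of the mature gene are 5' leader (5'U)
    fragments; entirely downstream, 3' trailer (3'U). The gap is the number
    of nucleotides separating the fragment from the mature boundary (0 =
    directly adjacent). Any overlap with the mature gene yields ("none", None).
    """
    if end < extended_ref.mature_start:
        return "leader_5U", extended_ref.mature_start - end - 1
    if start > extended_ref.mature_end:
        return "trailer_3U", start - extended_ref.mature_end - 1
    return "none", None


def merge_identical_sequences(
    calls: Sequence[FragmentCall], counts: pd.DataFrame
) -> list[TRFRecord]:
    """Collapse identical-sequence calls into single tRFs, summing counts.

    The representative member used for classification is the member with the
    highest pre-merge support (ties broken by (ref_id, start)); the record
    keeps all members. tRF ids are assigned by decreasing total count
    (ties by sequence) for stable, diff-friendly output.
    """
    by_seq: dict[str, list[FragmentCall]] = {}
    for call in calls:
        by_seq.setdefault(call.sequence, []).append(call)

    records = []
    for seq, members in by_seq.items():
        members = sorted(members, key=lambda c: (-c.support, c.ref_id, c.start))
        lib_counts: dict[str, float] = {}
        for call in members:
            if call.call_id in counts.index:
                for lib, value in counts.loc[call.call_id].items():
                    lib_counts[lib] = lib_counts.get(lib, 0.0) + float(value)
        records.append(
            TRFRecord(
                trf_id="",
                sequence=seq,
                members=[(c.ref_id, c.start, c.end) for c in members],
                counts=dict(sorted(lib_counts.items())),
            )
        )

    records.sort(key=lambda r: (-r.total_count, r.sequence))
    width = max(4, len(str(len(records))))
    for i, rec in enumerate(records):
        rec.trf_id = f"TRF-{i + 1:0{width}d}"
    return records


def classify_catalog(
    records: Sequence[TRFRecord],
    extended_index: Mapping[str, ExtendedReference] | None = None,
) -> list[TRFRecord]:
    """Fill class labels on every record from its representative member.

    Members on an extended (pre-tRNA) reference are labelled leader/trailer;
    members on the mature reference get origin and type classes. Minority
    members that disagree with the representative's labels are recorded in a
    diagnostics column.
    """
    extended_index = extended_index or {}
    for rec in records:
        labels = []
        for ref_id, start, end in rec.members:
            ext = extended_index.get(ref_id)
            if ext is not None:
                pre, gap = classify_pre_trna(start, end, ext)
                labels.append((ORIGIN_OTHER, "unclassified", pre, gap))
            else:
                labels.append(
                    (classify_origin(start, end), classify_type(start), "none", None)
                )
        rep = labels[0]
        rec.origin_class, rec.type_class, rec.pre_trna_class, rec.adjacency_gap = rep
        rec.minority_classes = sorted(
            {f"{o}/{t}/{p}" for (o, t, p, _g) in labels[1:] if (o, t, p) != rep[:3]}
        )
    return list(records)


def _two_view_table(values: Sequence, weights: Sequence[float]) -> pd.DataFrame:
    """Percent distribution of `values`, unweighted (uniqueness) and weighted
    by counts (abundance)."""
    df = pd.DataFrame({"value": list(values), "weight": list(weights)})
    if df.empty:
        return pd.DataFrame(columns=["uniqueness_pct", "abundance_pct"])
    uniq = df["value"].value_counts(normalize=True) * 100.0
    total_w = df["weight"].sum()
    if total_w > 0:
        abund = df.groupby("value")["weight"].sum() / total_w * 100.0
    else:
        abund = uniq * np.nan
    out = pd.DataFrame({"uniqueness_pct": uniq, "abundance_pct": abund}).fillna(0.0)
    out = out.sort_index()
    out.index.name = "value"
    return out


def summarize(records: Sequence[TRFRecord]) -> dict[str, pd.DataFrame]:
    """Catalog summaries, each in a uniqueness view (every tRF counted once)
    and an abundance view (weighted by summed counts).

    Type-class and origin summaries cover mature-derived tRFs; pre-tRNA
    (leader/trailer) tRFs are summarised separately together with the
    fraction lying within 1 nt of the mature boundary.
    """
    if not records:
        return {
            "length": pd.DataFrame(),
            "origin": pd.DataFrame(),
            "type": pd.DataFrame(),
            "start": pd.DataFrame(),
            "end": pd.DataFrame(),
            "pre_trna": pd.DataFrame(),
            "adjacency": pd.DataFrame(),
        }
    mature = [r for r in records if r.pre_trna_class == "none"]
    pre = [r for r in records if r.pre_trna_class != "none"]

    def starts_ends(recs):
        return (
            [r.members[0][1] for r in recs],
            [r.members[0][2] for r in recs],
            [r.total_count for r in recs],
        )

    m_starts, m_ends, m_w = starts_ends(mature)
    out = {
        "length": _two_view_table([r.length for r in records], [r.total_count for r in records]),
        "origin": _two_view_table([r.origin_class for r in mature], m_w),
        "type": _two_view_table([r.type_class for r in mature], m_w),
        "start": _two_view_table(m_starts, m_w),
        "end": _two_view_table(m_ends, m_w),
        "pre_trna": _two_view_table([r.pre_trna_class for r in pre], [r.total_count for r in pre]),
    }
    adjacency_rows = []
    for cls in ("leader_5U", "trailer_3U"):
        group = [r for r in pre if r.pre_trna_class == cls]
        if group:
            close = sum(1 for r in group if r.adjacency_gap is not None and r.adjacency_gap <= 1)
            adjacency_rows.append(
                {"pre_trna_class": cls, "n": len(group), "pct_gap_le_1": 100.0 * close / len(group)}
            )
    out["adjacency"] = pd.DataFrame(adjacency_rows)
    return out


def catalog_to_frame(records: Sequence[TRFRecord]) -> pd.DataFrame:
    """Flatten the catalog to a table (one row per tRF, one count column per library)."""
    libraries = sorted({lib for r in records for lib in r.counts})
    rows = []
    for r in records:
        row = {
            "trf_id": r.trf_id,
            "sequence": r.sequence,
            "length": r.length,
            "members": ";".join(f"{m[0]}:{m[1]}-{m[2]}" for m in r.members),
            "origin_class": r.origin_class,
            "type_class": r.type_class,
            "pre_trna_class": r.pre_trna_class,
            "adjacency_gap": "" if r.adjacency_gap is None else r.adjacency_gap,
            "minority_classes": ";".join(r.minority_classes),
        }
        for lib in libraries:
            row[f"count_{lib}"] = r.counts.get(lib, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def counts_matrix(records: Sequence[TRFRecord]) -> pd.DataFrame:
    """tRF x library count matrix from the catalog."""
    libraries = sorted({lib for r in records for lib in r.counts})
    mat = pd.DataFrame(
        [[r.counts.get(lib, 0.0) for lib in libraries] for r in records],
        index=[r.trf_id for r in records],
        columns=libraries,
    )
    mat.index.name = "trf_id"
    return mat


def write_catalog_tsv(records: Sequence[TRFRecord], path: str | Path) -> None:
    catalog_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g")
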