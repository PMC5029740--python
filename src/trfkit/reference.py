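"""Construction of mature and extended (pre-tRNA) mapping references.

A mature tRNA reference is built from genomic tRNA gene sequences by
excising annotated introns, appending the post-transcriptionally added
CCA tail, and collapsing genes with identical final sequences into a
single entry (tRNA genes are highly redundant; identical-sequence genes
would otherwise split read counts arbitrarily).

An extended reference keeps each locus separate and pads the *unspliced*
genomic sequence with flanking genomic context on both sides, so that
fragments of the pre-tRNA 5' leader and 3' trailer can be mapped and
placed relative to the mature boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


class InvalidAnnotationError(ValueError):
    """Raised when a gene record violates its structural invariants."""


def _check_dna(seq: str, what: str) -> None:
    if not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise InvalidAnnotationError(f"{what} contains non-ACGT characters: {bad}")


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and map U to T (reads and references live in DNA space)."""
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One genomic tRNA gene with its annotation.

    Coordinates are 1-based inclusive on ``genomic_seq``; introns are the
    annotated intervals to be excised when producing the mature sequence.
    """

    gene_id: str
    isotype: str
    anticodon: str
    genomic_seq: str
    intron_intervals: tuple[tuple[int, int], ...] = ()
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.genomic_seq, f"gene {self.gene_id} genomic_seq")
        if self.flank5:
            _check_dna(self.flank5, f"gene {self.gene_id} flank5")
        if self.flank3:
            _check_dna(self.flank3, f"gene {self.gene_id} flank3")
        n = len(self.genomic_seq)
        prev_end = 0
        for start, end in self.intron_intervals:
            if start > end:
                raise InvalidAnnotationError(
                    f"gene {self.gene_id}: intron [{start},{end}] is reversed"
                )
            if start < 2 or end > n - 1:
                raise InvalidAnnotationError(
                    f"gene {self.gene_id}: intron [{start},{end}] is not strictly "
                    f"inside [2,{n - 1}]"
                )
            if start <= prev_end:
                raise InvalidAnnotationError(
                    f"gene {self.gene_id}: intron intervals overlap or are unsorted"
                )
            prev_end = end


@dataclass(frozen=True)
class MatureReference:
    """A deduplicated mature-tRNA mapping target (spliced, CCA-appended)."""

    ref_id: str
    sequence: str
    source_gene_ids: tuple[str, ...]
    isotype: str
    anticodon: str


@dataclass(frozen=True)
class ExtendedReference:
    """One gene's unspliced genomic sequence padded with genomic flanks.

    ``mature_start``/``mature_end`` are the 1-based inclusive positions of the
    first/last gene nucleotide on ``sequence``.
    """

    ref_id: str
    sequence: str
    mature_start: int
    mature_end: int
    gene_id: str


def splice_introns(gene: TRNAGeneRecord) -> str:
    """Return the genomic sequence with every annotated intron excised."""
    seq = gene.genomic_seq
    pieces = []
    cursor = 0  # 0-based, exclusive end of the last kept piece
    for start, end in gene.intron_intervals:
        pieces.append(seq[cursor : start - 1])
        cursor = end
    pieces.append(seq[cursor:])
    return "".join(pieces)


def append_cca(spliced_seq: str) -> str:
    """Append the CCA tail. Applied unconditionally: genomic tRNA genes do not
    encode the tail, so an existing CCA suffix is genomic coincidence."""
    if not spliced_seq:
        raise ValueError("cannot append CCA to an empty sequence")
    return spliced_seq + "CCA"


def build_mature_reference(genes: Sequence[TRNAGeneRecord]) -> list[MatureReference]:
    """Splice, CCA-append and merge identical sequences into single entries.

    Genes whose processed sequences are identical collapse into one reference;
    all contributing gene ids are retained. When merged genes disagree on
    isotype/anticodon, the annotation of the lexicographically first gene_id
    wins and a warning is emitted.
    """
    seen_ids: set[str] = set()
    for g in genes:
        if g.gene_id in seen_ids:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen_ids.add(g.gene_id)

    by_seq: dict[str, list[TRNAGeneRecord]] = {}
    for gene in genes:
        mature = append_cca(splice_introns(gene))
        by_seq.setdefault(mature, []).append(gene)

    entries = []
    for seq, members in by_seq.items():
        members = sorted(members, key=lambda g: g.gene_id)
        rep = members[0]
        if len({(g.isotype, g.anticodon) for g in members}) > 1:
            warnings.warn(
                f"identical-sequence genes {[g.gene_id for g in members]} disagree "
                f"on isotype/anticodon; keeping annotation of {rep.gene_id}",
                stacklevel=2,
            )
        entries.append((rep.isotype, rep.anticodon, seq, tuple(g.gene_id for g in members)))

    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    width = max(4, len(str(len(entries))))
    refs = [
        MatureReference(
            ref_id=f"TRF-REF-{i + 1:0{width}d}",
            sequence=seq,
            source_gene_ids=gene_ids,
            isotype=isotype,
            anticodon=anticodon,
        )
        for i, (isotype, anticodon, seq, gene_ids) in enumerate(entries)
    ]
    logger.info("mature reference: %d genes -> %d unique sequences", len(genes), len(refs))
    return refs


def build_extended_reference(
    genes: Sequence[TRNAGeneRecord], flank: int = 50
) -> list[ExtendedReference]:
    """Pad each gene's genomic sequence with ``flank`` nt of genomic context.

    No merging: leaders and trailers are locus-specific even when the gene
    bodies are identical. No splicing or CCA: leader/trailer fragments are
    products of the unprocessed precursor.
    """
    refs = []
    for gene in genes:
        if len(gene.flank5) < flank or len(gene.flank3) < flank:
            raise ValueError(
                f"gene {gene.gene_id}: flanks shorter than requested flank={flank} "
                f"(flank5={len(gene.flank5)}, flank3={len(gene.flank3)})"
            )
        left = gene.flank5[len(gene.flank5) - flank :] if flank else ""
        right = gene.flank3[:flank]
        seq = left + gene.genomic_seq + right
        refs.append(
            ExtendedReference(
                ref_id=f"PRE-{gene.gene_id}",
                sequence=seq,
                mature_start=flank + 1,
                mature_end=flank + len(gene.genomic_seq),
                gene_id=gene.gene_id,
            )
        )
    return refs


# ---------------------------------------------------------------------------
# I/O: FASTA + tab-delimited annotation (GtRNAdb-style inputs)
# ---------------------------------------------------------------------------

def parse_intron_field(text: str) -> tuple[tuple[int, int], ...]:
    """Parse 's1-e1,s2-e2' (or '-' / '' for none) into interval tuples."""
    text = text.strip()
    if text in ("", "-", "none", "NA"):
        return ()
    intervals = []
    for chunk in text.split(","):
        start_s, _, end_s = chunk.partition("-")
        intervals.append((int(start_s), int(end_s)))
    return tuple(intervals)


def format_intron_field(intervals: Iterable[tuple[int, int]]) -> str:
    parts = [f"{s}-{e}" for s, e in intervals]
    return ",".join(parts) if parts else "-"


def read_gene_set(fasta_path: str | Path, annot_path: str | Path) -> list[TRNAGeneRecord]:
    """Load a gene set from FASTA (header = gene_id) plus a TSV annotation.

    Annotation columns: gene_id, isotype, anticodon, introns, flank5, flank3.
    U residues in any sequence are normalized to T.
    """
    seqs = {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes = []
    with open(annot_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "isotype", "anticodon", "introns", "flank5", "flank3"}
        missing = required - set(idx)
        if missing:
            raise InvalidAnnotationError(f"annotation is missing columns: {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            gene_id = row[idx["gene_id"]]
            if gene_id not in seqs:
                raise InvalidAnnotationError(f"gene {gene_id} has no FASTA sequence")
            genes.append(
                TRNAGeneRecord(
                    gene_id=gene_id,
                    isotype=row[idx["isotype"]],
                    anticodon=normalize_rna(row[idx["anticodon"]]),
                    genomic_seq=seqs[gene_id],
                    intron_intervals=parse_intron_field(row[idx["introns"]]),
                    flank5=normalize_rna(row[idx["flank5"]]),
                    flank3=normalize_rna(row[idx["flank3"]]),
                )
            )
    return genes


def write_gene_set(
    genes: Sequence[TRNAGeneRecord], fasta_path: str | Path, annot_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(g.genomic_seq), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annot_path, "w") as fh:
        fh.write("gene_id\tisotype\tanticodon\tintrons\tflank5\tflank3\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.isotype}\t{g.anticodon}\t"
                f"{format_intron_field(g.intron_intervals)}\t{g.flank5}\t{g.flank3}\n"
            )


def write_reference_fasta(
    refs: Sequence[MatureReference | ExtendedReference], path: str | Path
) -> None:
    records = [SeqRecord(Seq(r.sequence), id=r.ref_id, description="") for r in refs]
    SeqIO.write(records, str(path), "fasta")


def write_source_map(refs: Sequence[MatureReference], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tisotype\tanticodon\tsource_gene_ids\n")
        for r in refs:
            fh.write(f"{r.ref_id}\t{r.isotype}\t{r.anticodon}\t{','.join(r.source_gene_ids)}\n")
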