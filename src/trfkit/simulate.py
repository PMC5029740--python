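"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a pooled small-RNA-seq
tRF study: a redundant tRNA gene set (exact duplicate genes, intron-carrying
genes, genes sharing a 5' prefix so that 5' fragments multi-map), a fragment
population concentrated at tRNA loop boundaries with a 5'-end-dominated
abundance mix (~75% of read mass in 5e fragments), multinomial sequencing
sampling at a configurable depth per library, group-specific >= 4-fold
effects on a subset of fragments, a qPCR cohort with a stable reference
gene, and survival times whose hazard follows the ratio-defined stratum.

All generators are pure functions of (config, seed): the same inputs
reproduce identical output byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mapping import SmallRNARead
from .reference import (
    ExtendedReference,
    MatureReference,
    TRNAGeneRecord,
    build_extended_reference,
    build_mature_reference,
)

_AMINO_ACIDS = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val SeC"
).split()

# start-position ranges of the five positional classes on the mature tRNA
CLASS_START_RANGES = {"5e": (1, 1), "D": (12, 23), "A": (31, 39), "V": (45, 49), "3e": (50, 60)}

# fragment length distribution: 15-35 nt window, mode at 19 nt (~40%), a
# secondary shoulder at 25-29 nt
DEFAULT_LENGTH_WEIGHTS = {
    15: 0.03, 16: 0.04, 17: 0.06, 18: 0.10, 19: 0.40, 20: 0.10, 21: 0.08,
    22: 0.05, 23: 0.04, 25: 0.02, 26: 0.02, 27: 0.02, 28: 0.02, 29: 0.02,
}

LEADER_LENGTH_WEIGHTS = {15: 0.10, 16: 0.15, 17: 0.40, 18: 0.15, 19: 0.10, 20: 0.05, 21: 0.05}
TRAILER_LENGTH_WEIGHTS = {15: 0.05, 16: 0.10, 17: 0.15, 18: 0.40, 19: 0.15, 20: 0.10, 21: 0.05}

# gap-to-mature-boundary distributions (index = gap in nt): trailers sit
# adjacent (gap <= 1) ~60% of the time, leaders ~30%
LEADER_GAP_WEIGHTS = (0.20, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10)
TRAILER_GAP_WEIGHTS = (0.35, 0.25, 0.06, 0.06, 0.06, 0.06, 0.06, 0.05, 0.05)


@dataclass
class QPCRGroupConfig:
    name: str
    n: int
    folds: dict[str, float] = field(default_factory=dict)
    hazard: float | None = None  # per-month event hazard; None = no follow-up


@dataclass
class QPCRConfig:
    mu_ref: float = 20.0          # reference-gene CT cycles
    sigma: float = 0.2            # CT noise s.d., cycles
    dct_base: dict[str, float] = field(
        default_factory=lambda: {"tRF-315": 5.0, "tRF-544": 5.0}
    )
    reference_assay: str = "SNORD38B"
    censor_max: float = 120.0     # months; censoring ~ Uniform(0, censor_max)
    cohort_name: str = "cohort_1"
    groups: tuple[QPCRGroupConfig, ...] = (
        QPCRGroupConfig("NAP", 40),
        QPCRGroupConfig(
            "PCa_cured", 20, {"tRF-315": 2.0, "tRF-544": 0.5}, hazard=1.0 / 60.0
        ),
        QPCRGroupConfig(
            "PCa_recurrent", 20, {"tRF-315": 8.0, "tRF-544": 0.125}, hazard=3.0 / 60.0
        ),
    )


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort.

    The class abundance mix puts ~75% of fragment read mass in 5e fragments;
    20 fragments (10 up x4, 10 down x4) carry group effects; each library is
    a multinomial sample of 1e5 reads, one pooled library per group.
    """

    seed: int = 0
    n_genes: int = 80
    duplicate_fraction: float = 0.1
    intron_fraction: float = 0.15
    shared_prefix_pairs: int = 3
    shared_prefix_len: int = 40
    gene_length_range: tuple[int, int] = (70, 95)
    flank_length: int = 60
    class_abundance_mix: dict[str, float] = field(
        default_factory=lambda: {"5e": 0.75, "D": 0.07, "A": 0.06, "V": 0.05, "3e": 0.07}
    )
    n_trfs: int = 200
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    lognormal_sigma: float = 1.0
    n_pre_trfs: int = 12
    pre_trna_abundance: float = 0.03
    library_depth: int = 100_000
    groups: tuple[str, ...] = ("NAP", "PCa")
    de_effects: list[tuple[int, str, float]] | None = None
    n_de_up: int = 10
    n_de_down: int = 10
    de_fold: float = 4.0
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)

    def __post_init__(self) -> None:
        total = sum(self.class_abundance_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_abundance_mix must sum to 1, got {total}")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")


@dataclass
class PlantedFragment:
    ref_id: str
    start: int
    end: int
    sequence: str
    kind: str          # "mature", "leader_5U" or "trailer_3U"
    type_class: str    # one of the five classes, or "pre_trna"
    abundance: float   # expected fraction of a control library's reads


@dataclass
class GroundTruth:
    genes: list[TRNAGeneRecord]
    mature_refs: list[MatureReference]
    extended_refs: list[ExtendedReference]
    fragments: list[PlantedFragment]
    effects: list[tuple[int, str, float]]
    group_probs: dict[str, np.ndarray]

    def expected_ppm(self, group: str) -> np.ndarray:
        return self.group_probs[group] * 1e6


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_trna_genes(config: SimConfig, rng: np.random.Generator) -> list[TRNAGeneRecord]:
    """Generate a redundant synthetic tRNA gene set.

    ``duplicate_fraction`` of the genes are exact sequence copies of earlier
    genes (these collapse in the mature reference); ``intron_fraction`` of the
    base genes carry one 10-20 nt intron inserted after gene position 37; a
    few intron-free gene pairs share their first ``shared_prefix_len`` nt so
    that short 5' fragments map to more than one unique reference.
    """
    n_dup = int(round(config.duplicate_fraction * config.n_genes))
    n_base = config.n_genes - n_dup
    lo, hi = config.gene_length_range

    genes: list[TRNAGeneRecord] = []
    n_intron = int(round(config.intron_fraction * n_base))
    intron_idx = set(rng.choice(n_base, size=n_intron, replace=False).tolist()) if n_intron else set()

    bodies: list[str] = []
    for i in range(n_base):
        bodies.append(_random_dna(rng, int(rng.integers(lo, hi + 1))))

    # shared 5' prefixes between intron-free pairs
    free = [i for i in range(n_base) if i not in intron_idx]
    pairs = min(config.shared_prefix_pairs, len(free) // 2)
    for k in range(pairs):
        src, dst = free[2 * k], free[2 * k + 1]
        plen = min(config.shared_prefix_len, len(bodies[src]), len(bodies[dst]))
        bodies[dst] = bodies[src][:plen] + bodies[dst][plen:]

    for i in range(n_base):
        body = bodies[i]
        introns: tuple[tuple[int, int], ...] = ()
        if i in intron_idx:
            ilen = int(rng.integers(10, 21))
            body = body[:37] + _random_dna(rng, ilen) + body[37:]
            introns = ((38, 37 + ilen),)
        aa = _AMINO_ACIDS[i % len(_AMINO_ACIDS)]
        anticodon = _random_dna(rng, 3)
        genes.append(
            TRNAGeneRecord(
                gene_id=f"tRNA{i + 1:03d}-{aa}-{anticodon}",
                isotype=aa,
                anticodon=anticodon,
                genomic_seq=body,
                intron_intervals=introns,
                flank5=_random_dna(rng, config.flank_length),
                flank3=_random_dna(rng, config.flank_length),
            )
        )

    for j in range(n_dup):
        src = genes[j % n_base]
        genes.append(
            TRNAGeneRecord(
                gene_id=f"tRNA{n_base + j + 1:03d}-{src.isotype}-{src.anticodon}-dup",
                isotype=src.isotype,
                anticodon=src.anticodon,
                genomic_seq=src.genomic_seq,
                intron_intervals=src.intron_intervals,
                flank5=_random_dna(rng, config.flank_length),
                flank3=_random_dna(rng, config.flank_length),
            )
        )
    return genes


def _largest_remainder(weights: dict[str, float], total: int) -> dict[str, int]:
    raw = {k: w * total for k, w in weights.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))[:leftover]:
        counts[k] += 1
    return counts


def _weighted_choice(rng: np.random.Generator, table: dict[int, float]) -> int:
    keys = sorted(table)
    probs = np.array([table[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(keys, p=probs))


def simulate_fragment_truth(
    genes: Sequence[TRNAGeneRecord], config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Plant fragments on the references with class-anchored start positions.

    Boundary identifiability: on any one reference, two distinct planted
    start (or end) values must differ by more than 4 nt — equal shared
    boundaries are allowed — so that every planted boundary survives
    local-maximum peak detection. Class read-mass totals follow
    ``class_abundance_mix`` exactly; within a class the mass is spread over
    fragments by i.i.d. lognormal factors.
    """
    mature_refs = build_mature_reference(list(genes))
    extended_refs = build_extended_reference(list(genes), flank=50)

    per_class = _largest_remainder(config.class_abundance_mix, config.n_trfs)
    used_starts: dict[str, set[int]] = {}
    used_ends: dict[str, set[int]] = {}
    used_pairs: set[tuple[str, int, int]] = set()
    used_seqs: set[str] = set()

    def spaced(value: int, used: set[int]) -> bool:
        return all(value == u or abs(value - u) > 4 for u in used)

    def all_hits(seq: str) -> list[tuple[str, int, int]]:
        """All occurrences of seq across the mature set (a fragment shared by
        several references raises boundary counts on each of them)."""
        hits = []
        for ref in mature_refs:
            i = ref.sequence.find(seq)
            while i >= 0:
                hits.append((ref.ref_id, i + 1, i + len(seq)))
                i = ref.sequence.find(seq, i + 1)
        return hits

    fragments: list[PlantedFragment] = []
    class_members: dict[str, list[int]] = {c: [] for c in per_class}
    for cls in sorted(per_class):
        lo, hi = CLASS_START_RANGES[cls]
        for _ in range(per_class[cls]):
            placed = False
            for _attempt in range(5000):
                ref = mature_refs[int(rng.integers(0, len(mature_refs)))]
                start = int(rng.integers(lo, hi + 1))
                length = _weighted_choice(rng, config.length_weights)
                end = start + length - 1
                if end > len(ref.sequence):
                    continue
                seq = ref.sequence[start - 1 : end]
                key = (ref.ref_id, start, end)
                if key in used_pairs or seq in used_seqs:
                    continue
                hits = all_hits(seq)
                if any(h in used_pairs for h in hits):
                    continue
                if not all(
                    spaced(s, used_starts.setdefault(r, set()))
                    and spaced(e, used_ends.setdefault(r, set()))
                    for r, s, e in hits
                ):
                    continue
                for r, s, e in hits:
                    used_pairs.add((r, s, e))
                    used_starts[r].add(s)
                    used_ends[r].add(e)
                used_seqs.add(seq)
                class_members[cls].append(len(fragments))
                fragments.append(PlantedFragment(ref.ref_id, start, end, seq, "mature", cls, 0.0))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place a {cls} fragment after 5000 attempts; "
                    "increase n_genes or relax the configuration"
                )

    # pre-tRNA leader/trailer fragments, one per extended reference
    pre_indices: list[int] = []
    if config.n_pre_trfs:
        gene_pick = rng.choice(len(extended_refs), size=config.n_pre_trfs, replace=False)
        for k, gi in enumerate(gene_pick):
            ext = extended_refs[int(gi)]
            if k % 2 == 0:
                gaps, lengths, kind = LEADER_GAP_WEIGHTS, LEADER_LENGTH_WEIGHTS, "leader_5U"
            else:
                gaps, lengths, kind = TRAILER_GAP_WEIGHTS, TRAILER_LENGTH_WEIGHTS, "trailer_3U"
            for _attempt in range(1000):
                gap = int(rng.choice(len(gaps), p=np.array(gaps) / sum(gaps)))
                length = _weighted_choice(rng, lengths)
                if kind == "leader_5U":
                    end = ext.mature_start - 1 - gap
                    start = end - length + 1
                else:
                    start = ext.mature_end + 1 + gap
                    end = start + length - 1
                if start < 1 or end > len(ext.sequence):
                    continue
                seq = ext.sequence[start - 1 : end]
                if seq in used_seqs:
                    continue
                used_seqs.add(seq)
                pre_indices.append(len(fragments))
                fragments.append(PlantedFragment(ext.ref_id, start, end, seq, kind, "pre_trna", 0.0))
                break
            else:
                raise RuntimeError("could not place a pre-tRNA fragment")

    # abundances: exact class mass split, lognormal heterogeneity within class
    mature_mass = 1.0 - (config.pre_trna_abundance if pre_indices else 0.0)
    for cls, idxs in class_members.items():
        w = rng.lognormal(0.0, config.lognormal_sigma, size=len(idxs))
        w = w / w.sum() * config.class_abundance_mix[cls] * mature_mass
        for i, frag_i in enumerate(idxs):
            fragments[frag_i].abundance = float(w[i])
    if pre_indices:
        w = rng.lognormal(0.0, config.lognormal_sigma, size=len(pre_indices))
        w = w / w.sum() * config.pre_trna_abundance
        for i, frag_i in enumerate(pre_indices):
            fragments[frag_i].abundance = float(w[i])

    effects = config.de_effects
    if effects is None:
        effects = _auto_effects(fragments, config)

    base = np.array([f.abundance for f in fragments])
    group_probs: dict[str, np.ndarray] = {}
    for group in config.groups:
        v = base.copy()
        for idx, grp, fold in effects:
            if grp == group:
                v[idx] *= fold
        group_probs[group] = v / v.sum()

    return GroundTruth(
        genes=list(genes),
        mature_refs=mature_refs,
        extended_refs=extended_refs,
        fragments=fragments,
        effects=list(effects),
        group_probs=group_probs,
    )


def _auto_effects(
    fragments: Sequence[PlantedFragment], config: SimConfig
) -> list[tuple[int, str, float]]:
    """Assign default group effects: n_de_up x fold and n_de_down x 1/fold on
    mid-abundance mature fragments, with the down-regulated mass chosen to
    roughly offset the up-regulated mass so null proportions barely shift
    under the per-library renormalization."""
    if len(config.groups) < 2 or (config.n_de_up + config.n_de_down) == 0:
        return []
    case = config.groups[1]
    mature = [(i, f.abundance) for i, f in enumerate(fragments) if f.kind == "mature"]
    abund = np.array([a for _, a in mature])
    lo_q, hi_q = np.quantile(abund, [0.2, 0.8])
    candidates = sorted(
        [(i, a) for i, a in mature if lo_q <= a <= hi_q], key=lambda t: t[1]
    )
    ups = candidates[: config.n_de_up]
    target = config.de_fold * sum(a for _, a in ups)
    pool = sorted(candidates[config.n_de_up :], key=lambda t: -t[1])
    downs: list[tuple[int, float]] = []
    s = 0.0
    for i, a in pool:
        if len(downs) == config.n_de_down:
            break
        if s + a <= target:
            downs.append((i, a))
            s += a
    for i, a in pool:
        if len(downs) == config.n_de_down:
            break
        if (i, a) not in downs:
            downs.append((i, a))
    effects = [(i, case, config.de_fold) for i, _ in ups]
    effects += [(i, case, 1.0 / config.de_fold) for i, _ in downs]
    return effects


def simulate_libraries(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, list[SmallRNARead]], pd.DataFrame]:
    """Multinomial sequencing of one pooled library per group.

    Returns (reads per library, fragment x library truth-count table).
    Reads are exact fragment sequences (no sequencing error is modeled), so
    the expected ppm of a fragment equals 1e6 x its group probability.
    """
    reads: dict[str, list[SmallRNARead]] = {}
    counts = {}
    for group in config.groups:
        vec = rng.multinomial(config.library_depth, truth.group_probs[group])
        counts[group] = vec
        lib_reads = []
        r = 0
        for frag, c in zip(truth.fragments, vec):
            for _ in range(int(c)):
                lib_reads.append(SmallRNARead(f"{group}_r{r:07d}", frag.sequence, group))
                r += 1
        reads[group] = lib_reads
    truth_counts = pd.DataFrame(
        counts, index=[f"frag{i:04d}" for i in range(len(truth.fragments))]
    )
    truth_counts.index.name = "fragment"
    return reads, truth_counts


def simulate_qpcr_cohort(config: QPCRConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic qPCR/survival cohort table.

    The reference gene is stable (CT ~ Normal(mu_ref, sigma)); each target's
    CT equals the reference CT plus a true dCT shifted by -log2(fold) in
    affected groups, plus independent Normal(0, sigma) noise. Survival times
    are exponential with the group's hazard, censored by an independent
    Uniform(0, censor_max) time; groups without a hazard get no follow-up.
    """
    rows = []
    sid = 0
    for grp in config.groups:
        for _ in range(grp.n):
            sid += 1
            ct_ref = rng.normal(config.mu_ref, config.sigma)
            row = {
                "sample_id": f"S{sid:04d}",
                "cohort": config.cohort_name,
                "group": grp.name,
                f"ct_{config.reference_assay}": ct_ref,
            }
            for assay, dct0 in config.dct_base.items():
                fold = grp.folds.get(assay, 1.0)
                dct_true = dct0 - math.log2(fold)
                row[f"ct_{assay}"] = ct_ref + dct_true + rng.normal(0.0, config.sigma)
            if grp.hazard is not None:
                t = rng.exponential(1.0 / grp.hazard)
                c = rng.uniform(0.0, config.censor_max)
                row["pfs_time"] = min(t, c)
                row["event"] = int(t <= c)
            else:
                row["pfs_time"] = np.nan
                row["event"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def write_reads_fasta(reads: Sequence[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "fragments": [asdict(f) for f in truth.fragments],
        "effects": [list(e) for e in truth.effects],
        "group_probs": {g: p.tolist() for g, p in truth.group_probs.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
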