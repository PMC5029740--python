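"""Ground-truth evaluation of a pipeline run on synthetic data.

These metrics compare a `RunResult` against the generator's planted truth:
exact-boundary fragment recovery, positional-class accuracy of recovered
fragments, detection of planted differential-expression effects, and the
family-wise error rate of the proportion test on fully null resamples.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .de import kal_z_test

if TYPE_CHECKING:
    from .pipeline import RunResult


def boundary_recovery(result: "RunResult", min_reads: float = 50.0) -> dict:
    """Fraction of planted fragments recovered with exact boundaries.

    Only fragments whose realized pooled read count reaches ``min_reads``
    are eligible (a fragment that was barely sequenced cannot clear the
    caller's support floor, by design).
    """
    pooled = result.truth_counts.sum(axis=1).to_numpy()
    call_keys = {(c.ref_id, c.start, c.end) for c in result.calls}
    eligible = recovered = 0
    for i, frag in enumerate(result.truth.fragments):
        if pooled[i] < min_reads:
            continue
        eligible += 1
        if (frag.ref_id, frag.start, frag.end) in call_keys:
            recovered += 1
    pct = 100.0 * recovered / eligible if eligible else float("nan")
    return {"eligible": eligible, "recovered": recovered, "pct": pct}


def class_accuracy(result: "RunResult") -> dict:
    """Fraction of recovered mature fragments whose catalog record carries
    the planted positional class."""
    by_seq = {r.sequence: r for r in result.records}
    checked = correct = 0
    for frag in result.truth.fragments:
        if frag.kind != "mature":
            continue
        rec = by_seq.get(frag.sequence)
        if rec is None:
            continue
        checked += 1
        correct += rec.type_class == frag.type_class
    pct = 100.0 * correct / checked if checked else float("nan")
    return {"checked": checked, "correct": correct, "pct": pct}


def pre_trna_accuracy(result: "RunResult") -> dict:
    """Leader/trailer labelling accuracy for recovered pre-tRNA fragments."""
    by_seq = {r.sequence: r for r in result.records}
    checked = correct = 0
    for frag in result.truth.fragments:
        if frag.kind == "mature":
            continue
        rec = by_seq.get(frag.sequence)
        if rec is None:
            continue
        checked += 1
        correct += rec.pre_trna_class == frag.kind
    pct = 100.0 * correct / checked if checked else float("nan")
    return {"checked": checked, "correct": correct, "pct": pct}


def de_detection(result: "RunResult", case_group: str) -> dict:
    """Detection of planted >= 4-fold effects and false calls on nulls."""
    de = result.de_results[case_group]
    frag_seqs = [f.sequence for f in result.truth.fragments]
    by_seq = {r.sequence: r.trf_id for r in result.records}
    effect_seqs = set()
    detected = 0
    n_effects = 0
    for idx, grp, _fold in result.truth.effects:
        if grp != case_group:
            continue
        n_effects += 1
        seq = frag_seqs[idx]
        effect_seqs.add(seq)
        trf_id = by_seq.get(seq)
        if trf_id is not None and bool(de.loc[trf_id, "significant"]):
            detected += 1
    null_ids = [r.trf_id for r in result.records if r.sequence not in effect_seqs]
    n_null_sig = int(de.loc[null_ids, "significant"].sum())
    pct = 100.0 * detected / n_effects if n_effects else float("nan")
    return {
        "n_effects": n_effects,
        "detected": detected,
        "pct": pct,
        "n_null": len(null_ids),
        "null_significant": n_null_sig,
    }


def five_e_abundance_pct(result: "RunResult") -> float:
    """Abundance-weighted share of the 5e class in the catalog summary."""
    return float(result.summaries["type"].loc["5e", "abundance_pct"])


def null_fwer(
    rng: np.random.Generator,
    n_trfs: int = 500,
    depth: int = 1_000_000,
    n_reps: int = 200,
    alpha: float = 0.05,
) -> float:
    """Family-wise error rate of the Bonferroni-corrected proportion test on
    fully null resamples (both groups share one abundance vector)."""
    rejections = 0
    for _ in range(n_reps):
        w = rng.lognormal(0.0, 1.0, n_trfs)
        probs = w / w.sum()
        x1 = rng.multinomial(depth, probs).astype(float)
        x2 = rng.multinomial(depth, probs).astype(float)
        _, p = kal_z_test(x1, depth, x2, depth)
        tested = (x1 > 0) | (x2 > 0)
        m = int(tested.sum())
        rejections += bool(np.any(p[tested] * m < alpha))
    return rejections / n_reps
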