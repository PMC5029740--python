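"""Differential tRF expression between pooled count libraries.

Counts are normalized to parts per million of the library's total mapped
reads. Each tRF is tested with the pooled two-proportion Z-test (Kal's test
for comparing a tag's relative frequency between two SAGE-style count
libraries), two-sided, followed by Bonferroni correction over all tRFs in
the comparison. Fold changes use a baseline of 1 ppm for unexpressed tRFs so
that appearance/disappearance events stay finite, and a |fold| >= 4 flag
marks the strong changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_NONE = "none"


def normalize_ppm(count: float, library_total: float):
    """Parts-per-million normalization: count / total x 1e6."""
    total = np.asarray(library_total, dtype=float)
    if np.any(total <= 0):
        raise ValueError("library_total must be positive")
    return np.asarray(count, dtype=float) / total * 1e6


def kal_z_test(x1, N1, x2, N2) -> tuple:
    """Pooled two-proportion Z-test on tag counts (vectorized).

    z = (p1 - p2) / sqrt(p0 (1 - p0) (1/N1 + 1/N2)) with p0 the pooled
    proportion; two-sided p from the standard normal. Degenerate cases
    (both proportions 0, or pooled proportion 0/1) return (0, 1).
    Fractional counts from multi-mapper weight splitting are accepted.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    if np.any(N1 <= 0) or np.any(N2 <= 0):
        raise ValueError("library totals must be positive")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > N1) or np.any(x2 > N2):
        raise ValueError("counts must satisfy 0 <= x <= N")
    p1 = x1 / N1
    p2 = x2 / N2
    p0 = (x1 + x2) / (N1 + N2)
    var = p0 * (1.0 - p0) * (1.0 / N1 + 1.0 / N2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.minimum(p, 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Family-wise correction: p_adj = min(1, p x m)."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]


def fold_change(ppm_control: float, ppm_case: float) -> float:
    """case/control ppm ratio with a baseline of 1 substituted for zeros."""
    if ppm_control < 0 or ppm_case < 0:
        raise ValueError("ppm values must be non-negative")
    control = ppm_control if ppm_control > 0 else 1.0
    case = ppm_case if ppm_case > 0 else 1.0
    return case / control


@dataclass
class Comparison:
    control: str
    case: str
    results: pd.DataFrame


def call_differential(
    counts: pd.DataFrame,
    library_totals: Mapping[str, float],
    groups: Mapping[str, str],
    control_group: str,
    case_group: str,
    alpha: float = 0.05,
    strong_fc: float = 4.0,
) -> pd.DataFrame:
    """Per-tRF differential expression between two groups of libraries.

    Counts and totals are pooled within each group before testing (each
    sequencing library is already a pool of samples, and the test compares
    one proportion per group). Bonferroni m = number of tRFs with nonzero
    pooled count in at least one of the two groups; all-zero tRFs are
    reported untested with p = 1.
    """
    for grp in (control_group, case_group):
        if grp not in set(groups.values()):
            raise ValueError(f"unknown group label {grp!r}")
    control_libs = sorted(l for l, g in groups.items() if g == control_group)
    case_libs = sorted(l for l, g in groups.items() if g == case_group)
    missing = [l for l in control_libs + case_libs if l not in counts.columns]
    if missing:
        raise ValueError(f"libraries missing from count matrix: {missing}")

    x1 = counts[control_libs].sum(axis=1).to_numpy(dtype=float)
    x2 = counts[case_libs].sum(axis=1).to_numpy(dtype=float)
    N1 = float(sum(library_totals[l] for l in control_libs))
    N2 = float(sum(library_totals[l] for l in case_libs))

    ppm1 = normalize_ppm(x1, N1)
    ppm2 = normalize_ppm(x2, N2)
    z, p_raw = kal_z_test(x1, N1, x2, N2)
    z = np.atleast_1d(z)
    p_raw = np.atleast_1d(p_raw)

    tested = (x1 > 0) | (x2 > 0)
    m = int(tested.sum())
    p_adj = np.ones_like(p_raw)
    p_adj[tested] = np.minimum(1.0, p_raw[tested] * m)

    fc = np.array([fold_change(a, b) for a, b in zip(ppm1, ppm2)])
    significant = tested & (p_adj < alpha)
    strong = (fc >= strong_fc) | (fc <= 1.0 / strong_fc)
    direction = np.where(fc > 1, DIRECTION_UP, np.where(fc < 1, DIRECTION_DOWN, DIRECTION_NONE))

    out = pd.DataFrame(
        {
            "trf_id": counts.index,
            "ppm_control": ppm1,
            "ppm_case": ppm2,
            "fold_change": fc,
            "z": z,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "tested": tested,
            "significant": significant,
            "strong": strong,
            "direction": direction,
        }
    ).set_index("trf_id")
    return out


def common_de(results_by_group: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """tRFs significant in every comparison, categorized by direction agreement.

    Categories: consistent_up, consistent_down, mixed (significant everywhere
    but with discordant directions across groups).
    """
    if len(results_by_group) < 2:
        raise ValueError("common_de requires at least two comparisons")
    sig_sets = {
        grp: set(df.index[df["significant"]]) for grp, df in results_by_group.items()
    }
    shared = sorted(set.intersection(*sig_sets.values()))
    rows = []
    for trf in shared:
        directions = {grp: results_by_group[grp].loc[trf, "direction"] for grp in results_by_group}
        uniq = set(directions.values())
        if uniq == {DIRECTION_UP}:
            category = "consistent_up"
        elif uniq == {DIRECTION_DOWN}:
            category = "consistent_down"
        else:
            category = "mixed"
        row = {"trf_id": trf, "category": category}
        row.update({f"direction_{g}": d for g, d in directions.items()})
        rows.append(row)
    return pd.DataFrame(rows)
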