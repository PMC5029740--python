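"""qPCR relative quantification, the two-tRF expression ratio, and the
group/survival statistics around it.

Expression is quantified by the ddCT method: dCT = CT(target) - CT(reference
gene), calibrated against the mean dCT of the control group, and expressed as
2^-ddCT (amplification efficiency fixed at 2). The biomarker score is the
ratio of two relative expressions (an up-regulated over a down-regulated
fragment), group differences are assessed with the Mann-Whitney U test, and
progression-free survival between ratio-defined strata with the two-group
log-rank test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# ddCT relative expression
# ---------------------------------------------------------------------------

def delta_delta_ct(
    ct_target: float, ct_reference: float, calibrator_delta_ct: float
) -> tuple[float, float]:
    """Return (delta_ct, rel_expr) for one well.

    delta_ct = CT(target) - CT(reference gene); rel_expr = 2^-(dCT - calibrator).
    """
    for v in (ct_target, ct_reference, calibrator_delta_ct):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    delta_ct = ct_target - ct_reference
    return delta_ct, 2.0 ** -(delta_ct - calibrator_delta_ct)


def relative_expression(
    cohort: pd.DataFrame,
    targets: Sequence[str],
    reference_assay: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-sample ddCT relative expression for each target assay.

    ``cohort`` must carry one ``ct_<assay>`` column per assay including the
    reference gene. The calibrator for each target is the mean dCT of the
    control group. Samples without a reference-gene CT are dropped with a
    warning. Returns the cohort with added ``dct_<t>`` / ``rel_<t>`` columns.
    """
    ref_col = f"ct_{reference_assay}"
    if ref_col not in cohort.columns:
        raise ValueError(f"missing reference-gene column {ref_col!r}")
    usable = cohort[np.isfinite(cohort[ref_col].astype(float))].copy()
    dropped = len(cohort) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} samples without a reference-gene CT", stacklevel=2)
    if not (usable["group"] == control_group).any():
        raise ValueError(f"no samples in control group {control_group!r}")

    for target in targets:
        col = f"ct_{target}"
        if col not in usable.columns:
            raise ValueError(f"missing CT column {col!r}")
        dct = usable[col].astype(float) - usable[ref_col].astype(float)
        calibrator = dct[usable["group"] == control_group].mean()
        usable[f"dct_{target}"] = dct
        usable[f"rel_{target}"] = 2.0 ** -(dct - calibrator)
    return usable


def ratio_score(rel_a: float, rel_b: float) -> float:
    """Expression ratio of two relative expressions (e.g. up-tRF over down-tRF)."""
    if rel_a <= 0 or rel_b <= 0:
        raise ValueError("relative expressions must be positive")
    return rel_a / rel_b


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U1, U2) with midrank tie handling; U1 belongs to sample ``a``."""
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def mann_whitney(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 7
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U, p_two_sided) with U = min(U1, U2).

    When both groups have at most ``exact_max_n`` observations the p-value is
    exact: all C(n1+n2, n1) group labelings are enumerated and
    p = min(1, 2 x smaller tail count / total). Larger samples use the normal
    approximation with the tie correction (no continuity correction).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u1, u2 = _u_statistic(a, b)
    u = min(u1, u2)

    if n1 <= exact_max_n and n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        total = 0
        n_le = 0
        n_ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n1 + n2), n1):
            u_perm = ranks[list(combo)].sum() - offset
            total += 1
            if u_perm <= u1 + eps:
                n_le += 1
            if u_perm >= u1 - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u, p

    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    return u, min(1.0, 2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Survival: dichotomization and log-rank
# ---------------------------------------------------------------------------

def dichotomize(
    scores: pd.Series, policy: str = "median", cutoff: float | None = None
) -> pd.Series:
    """Split samples into 'high'/'low' strata by score.

    'median' splits at the cohort median with ties going to 'low';
    'fixed' uses the supplied cutoff (score > cutoff -> 'high').
    """
    values = scores.astype(float)
    if policy == "median":
        threshold = float(values.median())
    elif policy == "fixed":
        if cutoff is None:
            raise ValueError("fixed policy requires a cutoff")
        threshold = float(cutoff)
    else:
        raise ValueError(f"unknown cutoff policy {policy!r}")
    labels = pd.Series(
        np.where(values > threshold, "high", "low"), index=scores.index, name="stratum"
    )
    if (labels == "high").sum() < 2 or (labels == "low").sum() < 2:
        raise ValueError("degenerate dichotomization: fewer than 2 samples per stratum")
    return labels


def logrank(
    strata: Mapping[str, Sequence[tuple[float, int]]]
) -> tuple[float, float]:
    """Two-group log-rank test on (time, event) pairs.

    At each distinct event time the observed events in group 1 are compared
    with their hypergeometric expectation under the pooled risk set;
    chi-square = (sum O1 - sum E1)^2 / sum V with 1 df.
    """
    if len(strata) != 2:
        raise ValueError("logrank requires exactly 2 strata")
    (name1, data1), (name2, data2) = sorted(strata.items())
    if len(data1) == 0 or len(data2) == 0:
        raise ValueError("each stratum must contain at least one subject")

    times1 = np.asarray([t for t, _ in data1], dtype=float)
    events1 = np.asarray([e for _, e in data1], dtype=int)
    times2 = np.asarray([t for t, _ in data2], dtype=float)
    events2 = np.asarray([e for _, e in data2], dtype=int)

    event_times = np.unique(np.concatenate([times1[events1 == 1], times2[events2 == 1]]))
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        n1 = int((times1 >= t).sum())
        n2 = int((times2 >= t).sum())
        n = n1 + n2
        d1 = int(((times1 == t) & (events1 == 1)).sum())
        d2 = int(((times2 == t) & (events2 == 1)).sum())
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_coordinates(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier survival-curve coordinates for plotting/export."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    df = km.survival_function_.reset_index()
    df.columns = ["time", "survival"]
    return df


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerResult:
    expression: pd.DataFrame
    group_tests: pd.DataFrame
    survival: pd.DataFrame
    km: pd.DataFrame | None


def analyze_cohort(
    cohort: pd.DataFrame,
    target_up: str,
    target_down: str,
    reference_assay: str,
    control_group: str,
    cutoff_policy: str = "median",
    cutoff: float | None = None,
    with_km: bool = False,
) -> BiomarkerResult:
    """Full qPCR biomarker analysis.

    Computes ddCT relative expressions, the target_up/target_down ratio,
    pairwise Mann-Whitney tests of each target and the ratio between all
    group pairs, and the log-rank comparison of progression-free survival
    between ratio strata (median split by default, over samples with
    follow-up).
    """
    expr = relative_expression(cohort, [target_up, target_down], reference_assay, control_group)
    expr["ratio"] = expr[f"rel_{target_up}"] / expr[f"rel_{target_down}"]

    test_rows = []
    groups = sorted(expr["group"].unique())
    for metric in (f"rel_{target_up}", f"rel_{target_down}", "ratio"):
        for g1, g2 in itertools.combinations(groups, 2):
            v1 = expr.loc[expr["group"] == g1, metric].to_numpy()
            v2 = expr.loc[expr["group"] == g2, metric].to_numpy()
            u, p = mann_whitney(v1, v2)
            test_rows.append(
                {
                    "metric": metric,
                    "group_a": g1,
                    "group_b": g2,
                    "n_a": len(v1),
                    "n_b": len(v2),
                    "U": u,
                    "p": p,
                    "geomean_a": float(np.exp(np.mean(np.log(v1)))),
                    "geomean_b": float(np.exp(np.mean(np.log(v2)))),
                    "mean_a": float(np.mean(v1)),
                    "mean_b": float(np.mean(v2)),
                }
            )
    group_tests = pd.DataFrame(test_rows)

    followed = expr[expr["pfs_time"].notna() & expr["event"].notna()].copy()
    survival_rows = []
    km_df = None
    if len(followed) >= 4:
        labels = dichotomize(followed["ratio"], policy=cutoff_policy, cutoff=cutoff)
        followed["stratum"] = labels
        strata = {
            name: list(zip(sub["pfs_time"].astype(float), sub["event"].astype(int)))
            for name, sub in followed.groupby("stratum")
        }
        chi2, p = logrank(strata)
        survival_rows.append(
            {
                "n_high": int((labels == "high").sum()),
                "n_low": int((labels == "low").sum()),
                "events_high": int(followed.loc[labels == "high", "event"].sum()),
                "events_low": int(followed.loc[labels == "low", "event"].sum()),
                "chi_square": chi2,
                "p": p,
            }
        )
        if with_km:
            parts = []
            for name, sub in followed.groupby("stratum"):
                coords = km_coordinates(sub["pfs_time"], sub["event"].astype(int))
                coords.insert(0, "stratum", name)
                parts.append(coords)
            km_df = pd.concat(parts, ignore_index=True)
    survival = pd.DataFrame(survival_rows)
    return BiomarkerResult(expression=expr, group_tests=group_tests, survival=survival, km=km_df)
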