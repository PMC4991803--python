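"""Outlier-based criticality criteria over vulnerability tables.

A component is *critical* for a property when its vulnerability lies
more than ``multiplier`` standard deviations above the mean of all
attacks of its kind.  Neurons use a fixed multiplier of 3 SD.  For
synapses a data-driven multiplier is derived: vulnerabilities are
graded in integer SD units, a histogram of grades is built per
property, the first major slope change of the (log-scale) histogram is
located by an exhaustive two-segment linear fit, and the most
conservative (largest) change point across the three properties
governs all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CriticalSet",
    "sd_grade",
    "node_critical_set",
    "edge_critical_set",
    "sd_histogram",
    "changepoint",
    "edge_criterion",
    "group_comparison",
    "property_vulnerability_correlation",
]

PROPERTIES = ("C", "E", "B")


@dataclass
class CriticalSet:
    """Critical members of one property with the thresholding context.

    ``members`` maps target -> integer sigma grade; a target is a
    member iff its vulnerability exceeds ``mean + multiplier * sd``.
    """

    property: str
    mean: float
    sd: float
    multiplier: float
    members: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.mean + self.multiplier * self.sd

    def __len__(self) -> int:
        return len(self.members)


def _moments(values: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite vulnerability values")
    return float(values.mean()), float(values.std(ddof=ddof))


def sd_grade(
    values,
    *,
    mean: float | None = None,
    sd: float | None = None,
    ddof: int = 1,
    method: str = "floor",
):
    """Integer sigma grades: distance from the mean in whole SD units.

    ``grade = floor((v - mean) / sd)`` (or ``round`` when selected),
    clipped below at 0 for reporting.  Errors on a degenerate (sd = 0)
    distribution.
    """
    arr = np.asarray(values, dtype=float)
    if mean is None or sd is None:
        mean, sd = _moments(arr, ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate vulnerability distribution (sd = 0)")
    z = (arr - mean) / sd
    if method == "floor":
        grades = np.floor(z)
    elif method == "round":
        grades = np.round(z)
    else:
        raise ValueError(f"unknown grading method {method!r}")
    grades = np.clip(grades, 0, None).astype(int)
    if np.isscalar(values):
        return int(grades)
    return grades


def _critical_set(
    vuln: pd.Series,
    property: str,
    multiplier: float,
    ddof: int,
    grade_method: str,
) -> CriticalSet:
    values = vuln.to_numpy(dtype=float)
    finite = np.isfinite(values)
    mean, sd = _moments(values[finite], ddof=ddof)
    cs = CriticalSet(property=property, mean=mean, sd=sd, multiplier=multiplier)
    if sd == 0:
        return cs  # all-equal vulnerabilities: no outliers
    over = finite & (values > mean + multiplier * sd)
    if over.any():
        grades = sd_grade(values[over], mean=mean, sd=sd, method=grade_method)
        cs.members = dict(zip(vuln.index[over], (int(g) for g in grades)))
    return cs


def node_critical_set(
    vuln_table: pd.DataFrame,
    multiplier: float = 3.0,
    *,
    ddof: int = 1,
    grade_method: str = "floor",
) -> tuple[dict[str, CriticalSet], list]:
    """Per-property critical sets and their deduplicated union.

    ``vuln_table`` must carry columns V_C, V_E, V_B (one row per
    target, as produced by the attack sweeps).  Returns
    ``({property: CriticalSet}, union_targets)`` with the union in
    table order.
    """
    sets = {
        p: _critical_set(vuln_table[f"V_{p}"], p, multiplier, ddof, grade_method)
        for p in PROPERTIES
    }
    union = [
        t for t in vuln_table.index if any(t in sets[p].members for p in PROPERTIES)
    ]
    return sets, union


def edge_critical_set(
    vuln_table: pd.DataFrame,
    multiplier: float,
    *,
    ddof: int = 1,
    grade_method: str = "floor",
) -> tuple[dict[str, CriticalSet], list]:
    """Critical synapses at a given multiplier (same contract as for nodes)."""
    return node_critical_set(
        vuln_table, multiplier, ddof=ddof, grade_method=grade_method
    )


def sd_histogram(
    values, *, ddof: int = 1, grade_method: str = "floor"
) -> dict[int, int]:
    """Count of targets per integer SD bin, for bins k >= 1 up to the max grade.

    Interior empty bins are present with count 0 so the histogram spans
    a contiguous range.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    grades = sd_grade(arr, ddof=ddof, method=grade_method)
    top = int(grades.max()) if grades.size else 0
    if top < 1:
        return {}
    counts = {k: 0 for k in range(1, top + 1)}
    for g in grades:
        if g >= 1:
            counts[int(g)] += 1
    return counts


def changepoint(histogram: dict[int, int]) -> int:
    """First major slope change of an SD histogram.

    Operationalized as the best two-segment piecewise-linear fit of
    log10(count + 1) against the bin index: for every candidate split
    k, least-squares lines are fitted to the bins <= k and the bins
    > k (each side needs at least two bins), and the split minimizing
    the total squared residual wins; ties go to the smallest k.
    """
    if len(histogram) < 4:
        raise ValueError(
            f"change-point detection needs a histogram spanning >= 4 bins, "
            f"got {len(histogram)}"
        )
    bins = np.array(sorted(histogram), dtype=float)
    y = np.log10(np.array([histogram[int(k)] for k in bins], dtype=float) + 1.0)

    def sse(x: np.ndarray, yy: np.ndarray) -> float:
        coef, res, *_ = np.polyfit(x, yy, 1, full=True)
        return float(res[0]) if len(res) else 0.0

    best_k, best_sse = None, math.inf
    for split in range(1, len(bins) - 2):  # left: bins[:split+1], right: rest
        left = sse(bins[: split + 1], y[: split + 1])
        right = sse(bins[split + 1 :], y[split + 1 :])
        total = left + right
        if total < best_sse - 1e-12:
            best_sse, best_k = total, int(bins[split])
    assert best_k is not None
    return best_k


def edge_criterion(change_points: dict[str, int]) -> int:
    """Governing multiplier: the most conservative (largest) change point."""
    if not change_points:
        raise ValueError("no change points supplied")
    return max(change_points.values())


def group_comparison(values, critical_mask) -> dict:
    """Mann-Whitney U comparison of critical vs noncritical components.

    Returns the U statistic, two-sided p (tie-corrected), and the
    median/quartiles of both groups.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(critical_mask, dtype=bool)
    crit, noncrit = values[mask], values[~mask]
    crit = crit[np.isfinite(crit)]
    noncrit = noncrit[np.isfinite(noncrit)]
    if crit.size == 0 or noncrit.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(crit, noncrit, alternative="two-sided")
    q = lambda a: tuple(np.percentile(a, [25, 50, 75]))
    c25, c50, c75 = q(crit)
    n25, n50, n75 = q(noncrit)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "n_critical": int(crit.size),
        "n_noncritical": int(noncrit.size),
        "critical_q1": c25,
        "critical_median": c50,
        "critical_q3": c75,
        "noncritical_q1": n25,
        "noncritical_median": n50,
        "noncritical_q3": n75,
    }


def property_vulnerability_correlation(
    properties: pd.DataFrame,
    signed_vulnerabilities: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Rank correlation of every intact property with every signed vulnerability.

    Rows are property columns (e.g. D, Str, AW, C_i, E_i, B_i), columns
    are pairs ``(<vuln>, rho)`` and ``(<vuln>, p)``.  Signed values are
    used deliberately: the sign of a vulnerability carries information.
    Zero-variance inputs yield NaN (flagged missing).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    out: dict[tuple[str, str], dict[str, float]] = {}
    for vcol in signed_vulnerabilities.columns:
        v = signed_vulnerabilities[vcol].to_numpy(dtype=float)
        for pcol in properties.columns:
            x = properties[pcol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(v)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(v[ok]) == 0:
                rho, p = np.nan, np.nan
            else:
                r = corr(x[ok], v[ok])
                rho, p = float(r.statistic), float(r.pvalue)
            out.setdefault((vcol, "rho"), {})[pcol] = rho
            out.setdefault((vcol, "p"), {})[pcol] = p
    df = pd.DataFrame(out)
    df.index.name = "property"
    return df
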