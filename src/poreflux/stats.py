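"""Sub-trajectory windowing and the test-selection comparison scheme.

Trajectories are partitioned into fixed-length, non-overlapping analysis
windows (10 ns by default); each window×monomer is one statistical unit
(a 200 ns tetramer run thus yields 80 pooled units, a 250 ns run 25 per
chain).  Comparisons first record normality (Shapiro) and
homoscedasticity checks at α = 0.05, then branch deterministically:

* two groups  — both checks pass → Student t-test, else Mann–Whitney
  (exact null for n ≤ 8 per group without ties; normal approximation
  with tie correction otherwise);
* >2 groups — checks pass → one-way ANOVA with Tukey's HSD post hoc,
  else Kruskal–Wallis omnibus with pairwise Wilcoxon rank-sum tests
  under Bonferroni correction.

The chosen branch is a pure function of the recorded checks, so rerunning
with identical inputs reproduces the full result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .constants import PorefluxError

__all__ = ["WindowPlan", "ComparisonResult", "plan_windows",
           "windowed_event_counts", "compare"]


@dataclass
class WindowPlan:
    length_ns: float
    window_ns: float
    n_chains: int
    mode: str                  # "pooled" or "per-chain"
    n_windows: int             # windows per trajectory
    n_units: int               # statistical units per condition
    boundaries: list = field(default_factory=list)  # [(lo, hi), ...)
    dropped_ns: float = 0.0


@dataclass
class ComparisonResult:
    groups: int
    test: str
    statistic: float
    pvalue: float
    checks: dict               # recorded normality/homoscedasticity decisions
    pairwise: pd.DataFrame | None = None


def plan_windows(
    length_ns: float,
    window_ns: float = 10.0,
    n_chains: int = 1,
    mode: str = "pooled",
) -> WindowPlan:
    """Deterministic partition [0,w), [w,2w), ...; a trailing remainder
    shorter than one window is dropped (and reported in ``dropped_ns``).

    ``mode='pooled'`` treats every chain's windows as exchangeable units
    of one condition (units = windows × chains); ``mode='per-chain'``
    keeps chains separate (units = windows).
    """
    if mode not in ("pooled", "per-chain"):
        raise PorefluxError(f"unknown windowing mode {mode!r}")
    if window_ns <= 0:
        raise PorefluxError("window length must be positive")
    if window_ns > length_ns:
        raise PorefluxError("window longer than trajectory")
    n_windows = int(length_ns // window_ns)
    boundaries = [(i * window_ns, (i + 1) * window_ns) for i in range(n_windows)]
    return WindowPlan(
        length_ns=length_ns,
        window_ns=window_ns,
        n_chains=n_chains,
        mode=mode,
        n_windows=n_windows,
        n_units=n_windows * (n_chains if mode == "pooled" else 1),
        boundaries=boundaries,
        dropped_ns=length_ns - n_windows * window_ns,
    )


def windowed_event_counts(records, times, plan: WindowPlan, chains) -> pd.DataFrame:
    """Per-chain, per-window permeation-event counts (events dated by exit
    frame), including zero windows — tidy (chain, window, value)."""
    times = np.asarray(times)
    rows = []
    for chain in chains:
        exits = np.array(
            [times[r.exit_frame] for r in records if r.chain_id == chain]
        )
        for w, (lo, hi) in enumerate(plan.boundaries):
            rows.append(
                {
                    "chain": chain,
                    "window": w,
                    "value": int(np.sum((exits >= lo) & (exits < hi))),
                }
            )
    return pd.DataFrame(rows)


def _shapiro_p(x: np.ndarray) -> float:
    # a zero-variance sample is maximally non-normal for branching purposes
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def _variance_ratio_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test on the sample-variance ratio."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    p = sps.f.cdf(f, len(a) - 1, len(b) - 1)
    return float(2 * min(p, 1 - p))


def _mannwhitney(a: np.ndarray, b: np.ndarray):
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # fully tied samples: no evidence of a shift
        return float(len(a) * len(b) / 2.0), 1.0, "mann-whitney"
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), "mann-whitney"


def compare(groups, alpha: float = 0.05) -> ComparisonResult:
    """Compare ≥2 groups of per-window values with the test-selection
    scheme described in the module docstring."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise PorefluxError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) < 3:
            raise PorefluxError(f"group {i} has fewer than 3 values")

    checks = {"alpha": alpha}
    shapiro = [_shapiro_p(g) for g in groups]
    checks["shapiro_p"] = shapiro
    normal = all(p > alpha for p in shapiro)
    checks["normal"] = normal

    if len(groups) == 2:
        p_var = _variance_ratio_p(groups[0], groups[1])
        checks["variance_ratio_p"] = p_var
        homoscedastic = p_var > alpha
        checks["homoscedastic"] = homoscedastic
        if normal and homoscedastic:
            res = sps.ttest_ind(groups[0], groups[1], equal_var=True)
            return ComparisonResult(
                2, "t-test", float(res.statistic), float(res.pvalue), checks
            )
        stat, p, name = _mannwhitney(groups[0], groups[1])
        return ComparisonResult(2, name, stat, p, checks)

    p_var = float(sps.bartlett(*groups).pvalue)
    checks["bartlett_p"] = p_var
    homoscedastic = p_var > alpha
    checks["homoscedastic"] = homoscedastic
    k = len(groups)
    if normal and homoscedastic:
        res = sps.f_oneway(*groups)
        tuk = sps.tukey_hsd(*groups)
        rows = [
            {"group_a": i, "group_b": j, "pvalue": float(tuk.pvalue[i, j])}
            for i in range(k)
            for j in range(i + 1, k)
        ]
        return ComparisonResult(
            k, "anova+tukey", float(res.statistic), float(res.pvalue),
            checks, pd.DataFrame(rows),
        )
    omnibus = sps.kruskal(*groups)
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            _, p, _ = _mannwhitney(groups[i], groups[j])
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "pvalue": min(1.0, p * n_pairs),  # Bonferroni
                }
            )
    return ComparisonResult(
        k, "wilcoxon+bonferroni", float(omnibus.statistic),
        float(omnibus.pvalue), checks, pd.DataFrame(rows),
    )
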