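"""Ensemble statistics shared across assays.

Includes the pointwise two-sample test over a common time grid, the
time-of-divergence statistic (the first timepoint from which two
condition means stay significantly apart), experiment-level aggregation
(tests operate on means of independent experiments, not on pooled
cells), and the internalised/surface expression ratio normalised to a
wild-type reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import CurveEnsemble, CurveError


class CurveStatsError(ValueError):
    pass


@dataclass
class DivergenceResult:
    """Outcome of a time-of-divergence analysis.

    ``time_s`` is the first grid timepoint from which the groups remain
    significantly different under the persistence rule, or None.
    """

    time_s: float | None
    p_values: np.ndarray
    alpha: float
    rule: str
    grid: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise CurveStatsError("p-values outside [0, 1]")
        if self.time_s is not None and len(self.grid):
            if not np.any(np.isclose(self.grid, self.time_s)):
                raise CurveStatsError("divergence time is not a grid timepoint")

    @property
    def diverged(self) -> bool:
        return self.time_s is not None


def _check_grids(group_a: CurveEnsemble, group_b: CurveEnsemble) -> np.ndarray:
    if group_a.time.shape != group_b.time.shape or not np.allclose(
        group_a.time, group_b.time
    ):
        raise CurveError("group ensembles are not on a common time grid")
    return group_a.time


def pointwise_test(
    group_a: CurveEnsemble,
    group_b: CurveEnsemble,
    method: str = "welch",
) -> np.ndarray:
    """Two-tailed two-sample p-value at every timepoint.

    ``method="welch"`` (default) is the unequal-variance t-test;
    ``"mannwhitney"`` is the rank-based alternative.  No multiplicity
    correction is applied across timepoints.  Degenerate timepoints where
    both groups are constant get p = 1 for equal values and p = 0 for a
    deterministic difference.
    """
    t = _check_grids(group_a, group_b)
    p = np.empty(len(t))
    for i in range(len(t)):
        a, b = group_a.values[:, i], group_b.values[:, i]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            p[i] = 1.0 if a[0] == b[0] else 0.0
            continue
        if method == "welch":
            p[i] = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif method == "mannwhitney":
            p[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise CurveStatsError(f"unknown method {method!r}")
    return p


def divergence_time(
    group_a: CurveEnsemble,
    group_b: CurveEnsemble,
    alpha: float = 0.05,
    rule: str = "all_subsequent",
    k: int = 3,
    method: str = "welch",
) -> DivergenceResult:
    """First timepoint from which the two groups stay significantly apart.

    With the default ``all_subsequent`` rule, the divergence time is the
    earliest grid time t* with p(t) < alpha at t* and at every later
    timepoint; the ``k_consecutive`` rule instead requires only the next
    k timepoints (inclusive) to be significant.  Returns time None when
    no timepoint qualifies.
    """
    if not 0 < alpha < 1:
        raise CurveStatsError("alpha must be in (0, 1)")
    t = _check_grids(group_a, group_b)
    p = pointwise_test(group_a, group_b, method=method)
    sig = p < alpha
    t_star: float | None = None
    if rule == "all_subsequent":
        # latest run of consecutive significance reaching the end
        idx = None
        for i in range(len(sig) - 1, -1, -1):
            if sig[i]:
                idx = i
            else:
                break
        if idx is not None:
            t_star = float(t[idx])
    elif rule == "k_consecutive":
        if k < 1:
            raise CurveStatsError("k must be >= 1")
        for i in range(len(sig)):
            if np.all(sig[i : i + k]) and len(sig[i : i + k]) == k:
                t_star = float(t[i])
                break
    else:
        raise CurveStatsError(f"unknown persistence rule {rule!r}")
    return DivergenceResult(
        time_s=t_star, p_values=p, alpha=alpha, rule=rule, grid=t
    )


def aggregate_by_experiment(
    values: pd.DataFrame,
    value_col: str = "value",
    experiment_col: str = "experiment_id",
) -> dict:
    """Per-experiment means, grand mean and SEM over experiment means.

    Statistics and downstream tests operate on the means of independent
    experiments, not on pooled per-cell values.  With a single experiment
    the SEM is undefined and reported as NaN (flagged).
    """
    df = pd.DataFrame(values)
    if df.empty:
        raise CurveStatsError("no values to aggregate")
    per_exp = df.groupby(experiment_col)[value_col].mean()
    n = len(per_exp)
    sem = float(per_exp.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "experiment_means": per_exp.to_dict(),
        "grand_mean": float(per_exp.mean()),
        "sem": sem,
        "n_experiments": n,
        "sem_defined": n > 1,
        "groups": per_exp.to_numpy(),
    }


def internalisation_ratio(
    surface_mfi: float,
    internalised_mfi: float,
    wt_surface_mfi: float,
    wt_internalised_mfi: float,
) -> float:
    """Internalised/surface expression ratio as a percentage of wild type.

    ``100 * (internalised/surface) / (wt_internalised/wt_surface)``; the
    wild-type reference is 100% by construction.
    """
    vals = (surface_mfi, internalised_mfi, wt_surface_mfi, wt_internalised_mfi)
    if any(v <= 0 for v in vals):
        raise CurveStatsError(f"all MFI inputs must be positive, got {vals}")
    return 100.0 * (internalised_mfi / surface_mfi) / (
        wt_internalised_mfi / wt_surface_mfi
    )
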