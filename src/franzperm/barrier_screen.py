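"""Waterproofing-formulation screening on water-loss (TMWL) panels.

A formulation's barrier effect is the percent reduction of
transmembranal water loss relative to the untreated control membrane.
The synthetic-membrane surrogate is validated by regressing tissue TMWL
on surrogate TMWL across formulations; group differences in permeation
parameters are compared with the Kruskal–Wallis rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_data import CONTROL_LABEL, TMWLRecord, ValidationError


class DegenerateRegressionError(ValidationError):
    """The predictor has zero variance; a regression line is undefined."""


@dataclass(frozen=True)
class ReductionResult:
    """Percent TMWL reduction of one formulation on one membrane."""

    membrane: str
    formulation: str
    control_tmwl: float
    treated_tmwl: float
    reduction_pct: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS line of tissue TMWL on surrogate TMWL."""

    slope: float
    intercept: float
    pearson_r: float
    r2: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal–Wallis H test with midrank tie correction."""

    h_statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    tie_corrected: bool
    all_identical: bool = False


def percent_reduction(records: list[TMWLRecord], membrane: str) -> list[ReductionResult]:
    """Percent TMWL reduction vs the untreated control, per formulation.

    The control baseline is the mean over the membrane's control
    replicates; one result per non-control formulation (replicates of a
    formulation each yield a result, in input order).
    """
    mine = [r for r in records if r.membrane == membrane]
    controls = [r.tmwl for r in mine if r.is_control]
    if not controls:
        raise ValidationError(f"no {CONTROL_LABEL!r} row for membrane {membrane!r}")
    control = float(np.mean(controls))
    if control <= 0:
        raise ValidationError(f"control TMWL for {membrane!r} must be positive")
    return [
        ReductionResult(
            membrane=membrane,
            formulation=r.formulation,
            control_tmwl=control,
            treated_tmwl=r.tmwl,
            reduction_pct=(control - r.tmwl) / control * 100.0,
        )
        for r in mine
        if not r.is_control
    ]


def pair_by_formulation(
    records: list[TMWLRecord], surrogate: str, tissue: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pair mean TMWL per formulation across two membranes.

    Returns the shared non-control formulation labels (surrogate order)
    and the aligned surrogate/tissue mean-TMWL arrays.
    """
    def _means(membrane):
        out: dict[str, list[float]] = {}
        for r in records:
            if r.membrane == membrane and not r.is_control:
                out.setdefault(r.formulation, []).append(r.tmwl)
        return {k: float(np.mean(v)) for k, v in out.items()}

    s_means, t_means = _means(surrogate), _means(tissue)
    shared = [f for f in s_means if f in t_means]
    x = np.array([s_means[f] for f in shared])
    y = np.array([t_means[f] for f in shared])
    return shared, x, y


def cross_membrane_regression(pairs) -> RegressionResult:
    """OLS of tissue TMWL on surrogate TMWL across formulations.

    ``pairs`` is an iterable of (surrogate_tmwl, tissue_tmwl) or a pair
    of aligned arrays. R² = r² is reported at full precision.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim == 2 and arr.shape[0] == 2 and arr.shape[1] > 2:
        arr = arr.T  # given as (x_array, y_array)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (surrogate, tissue) tuples")
    if arr.shape[0] < 3:
        raise ValidationError("regression needs at least 3 formulation pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("surrogate TMWL values have zero variance")
    if np.ptp(y) == 0:
        # flat response: slope 0 line through the mean, no linear association
        return RegressionResult(0.0, float(np.mean(y)), 0.0, 0.0, int(x.size))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n=int(x.size),
    )


def _h_statistic(pooled_2d: np.ndarray, sizes: tuple[int, ...]) -> np.ndarray:
    """Kruskal–Wallis H with midranks and tie correction, row-wise.

    ``pooled_2d`` has one pooled sample per row, with the first
    ``sizes[0]`` columns forming group 1, the next ``sizes[1]`` group 2,
    etc. Used by the permutation engine; scipy computes the headline H.
    """
    n = pooled_2d.shape[1]
    ranks = stats.rankdata(pooled_2d, axis=1)
    h = np.zeros(pooled_2d.shape[0])
    start = 0
    for size in sizes:
        h += ranks[:, start:start + size].sum(axis=1) ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # the tie pattern of the pooled multiset is permutation-invariant
    _, counts = np.unique(pooled_2d[0], return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie_term if tie_term > 0 else np.zeros_like(h)


def kruskal_wallis(
    groups: list,
    exact: bool = False,
    n_permutations: int = 100_000,
    seed: int | None = None,
) -> GroupTestResult:
    """Kruskal–Wallis rank test across ≥ 2 groups.

    The default p-value uses the chi-square approximation with
    (k − 1) degrees of freedom; with ``exact=True`` a Monte-Carlo
    permutation p-value (label reshuffling, seeded) is returned instead
    — preferable at the very small group sizes typical of permeation
    studies. Groups with all observations identical return H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValidationError("need at least 3 observations in total")
    sizes = tuple(int(a.size) for a in arrays)
    ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return GroupTestResult(0.0, 1.0, sizes, tie_corrected=True, all_identical=True)

    h_obs, p_chi2 = stats.kruskal(*arrays)
    if not exact:
        return GroupTestResult(float(h_obs), float(p_chi2), sizes, tie_corrected=ties)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_permutations, 1)), axis=1)
    h_perm = _h_statistic(perms, sizes)
    count = int(np.sum(h_perm >= h_obs - 1e-12))
    p_perm = (count + 1) / (n_permutations + 1)
    return GroupTestResult(float(h_obs), float(p_perm), sizes, tie_corrected=ties)


def rank_formulations(
    results: list[ReductionResult], by_class=None
) -> list[ReductionResult]:
    """Order formulations by descending percent reduction (stable sort).

    ``by_class`` optionally maps a formulation label to a class; when
    given, results are grouped by class (classes in first-appearance
    order) and ranked within each class.
    """
    if by_class is None:
        return sorted(results, key=lambda r: -r.reduction_pct)
    classes: dict[str | None, list[ReductionResult]] = {}
    for r in results:
        classes.setdefault(by_class(r.formulation), []).append(r)
    out: list[ReductionResult] = []
    for members in classes.values():
        out.extend(sorted(members, key=lambda r: -r.reduction_pct))
    return out
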