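"""Permutation-based treatment inference.

The treatment effect on prey trajectories is tested in two stages: each
flask is reduced to a single summary statistic — the OLS slope of ln prey
concentration versus day — and the difference in mean slope between the
two treatment groups is compared against its permutation null built by
relabeling flasks. This tests the same scientific contrast a mixed-effects
model with a treatment-by-time interaction would (does grazing change the
prey's exponential trajectory?) without distributional assumptions, at the
cost of ignoring within-flask correlation structure, which the two-stage
reduction removes by design.

Pairwise comparisons among estimated rates use the same two-sample
permutation machinery with Holm step-down adjustment across pairs; Holm
is exact under permutation and needs no normality.

Permutation p-values use the add-one convention
``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_permutations)``, which is
never zero and is exactly valid under the null. Small designs are fully
enumerated, in which case the same formula is applied with the
enumeration's non-identity assignments as the permutation set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from grazerates.errors import UndefinedRateError, ValidationError
from grazerates.timeseries_io import CountSeries

#: full enumeration is used whenever the number of distinct relabelings
#: does not exceed this cap (and never exceeds the requested n_perm by
#: orders of magnitude in cost)
_EXACT_CAP = 200_000


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sample permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    comparison: str
    exact: bool = False
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def per_flask_slope(series: CountSeries) -> float:
    """OLS slope (day^-1, log scale) of ln prey concentration vs day.

    Zero counts are excluded from the fit; at least two positive counts
    are required.
    """
    usable = series.prey_conc > 0
    if usable.sum() < 2:
        raise UndefinedRateError(
            f"flask {series.flask_id!r}: fewer than two positive prey counts"
        )
    slope, *_ = stats.linregress(
        series.days[usable], np.log(series.prey_conc[usable])
    )
    return float(slope)


def _two_sample_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed: int | None,
    comparison: str,
    method: str = "auto",
) -> PermutationResult:
    pooled = np.concatenate([x, y])
    n, n0 = len(pooled), len(x)
    observed = float(np.mean(x) - np.mean(y))
    n_distinct = math.comb(n, n0)
    use_exact = method == "exact" or (
        method == "auto" and n_distinct <= min(n_perm + 1, _EXACT_CAP)
    )
    if use_exact:
        total = pooled.sum()
        count_ge = 0
        for idx in itertools.combinations(range(n), n0):
            s0 = pooled[list(idx)].sum()
            stat = s0 / n0 - (total - s0) / (n - n0)
            if abs(stat) >= abs(observed) - 1e-12 * max(abs(observed), 1.0):
                count_ge += 1
        # the observed assignment is one of the enumerated ones, so this is
        # the add-one formula with n_permutations = n_distinct - 1
        return PermutationResult(
            statistic=observed,
            p_value=count_ge / n_distinct,
            n_permutations=n_distinct - 1,
            seed=seed,
            comparison=comparison,
            exact=True,
        )
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    perm_stats = perms[:, :n0].mean(axis=1) - perms[:, n0:].mean(axis=1)
    count = int(
        np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12 * max(abs(observed), 1.0))
    )
    return PermutationResult(
        statistic=observed,
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        comparison=comparison,
        exact=False,
    )


def treatment_permutation_test(
    slopes: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = 0,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided permutation test for a difference in mean per-flask slope.

    ``labels`` must contain exactly two distinct treatment labels, each
    with at least two flasks. The statistic is the difference in group
    mean slope (first label minus second, in sorted label order); the null
    is built by relabeling flasks uniformly at random without replacement.
    ``method="auto"`` switches to full enumeration whenever all distinct
    relabelings fit within the permutation budget.
    """
    slopes = np.asarray(slopes, dtype=float)
    labels = np.asarray(labels)
    if slopes.shape != labels.shape:
        raise ValidationError("slopes and labels must have the same length")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValidationError(f"exactly two treatment labels required, got {uniq}")
    x = slopes[labels == uniq[0]]
    y = slopes[labels == uniq[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each treatment group needs at least two flasks")
    return _two_sample_permutation(
        x, y, n_perm, seed, comparison=f"{uniq[0]} vs {uniq[1]}", method=method
    )


def pairwise_rate_comparison(
    groups: Mapping[str, Sequence[float]],
    n_perm: int = 9999,
    seed: int | None = 0,
    method: str = "auto",
) -> tuple[PermutationResult, ...]:
    """All pairwise permutation tests on group mean differences, Holm-adjusted.

    Each group needs at least two values. Per-pair seeds are derived from
    ``seed`` so the full set of comparisons is reproducible; adjusted
    p-values (Holm step-down) are attached to each result.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("at least two groups required")
    for name in names:
        if len(groups[name]) < 2:
            raise ValidationError(f"group {name!r} needs at least two values")
    pairs = list(itertools.combinations(names, 2))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2**31)
    results = []
    for (a, b), s in zip(pairs, child_seeds):
        results.append(
            _two_sample_permutation(
                np.asarray(groups[a], dtype=float),
                np.asarray(groups[b], dtype=float),
                n_perm,
                int(s),
                comparison=f"{a} vs {b}",
                method=method,
            )
        )
    _, p_adj, _, _ = multipletests([r.p_value for r in results], method="holm")
    return tuple(
        PermutationResult(
            statistic=r.statistic,
            p_value=r.p_value,
            n_permutations=r.n_permutations,
            seed=r.seed,
            comparison=r.comparison,
            exact=r.exact,
            p_adjusted=float(p),
        )
        for r, p in zip(results, p_adj)
    )
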