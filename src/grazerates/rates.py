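"""Growth, clearance, and ingestion rate estimation.

The estimator follows the classic two-culture grazing design (after
Heinbokel): prey growth rate ``k`` is measured in a grazer-free
monoculture, apparent prey growth ``g`` under grazing, and the clearance
rate of the grazer is

    F = (k - g) / P          [mL predator^-1 day^-1]

with ``P`` the time-averaged predator concentration over the interval. The
ingestion rate is ``I = B_avg * F`` (prey cells predator^-1 day^-1) where
``B_avg`` is the logarithmic mean of the interval's prey endpoint
concentrations,

    B_avg = (B1 - B0) / (ln B1 - ln B0),

which is the exact time average of an exponentially changing
concentration. ``P`` is computed by the same logarithmic mean applied to
the predator endpoints; for an exponentially growing predator this makes
the clearance estimator exact, not just approximate.

Two growth-rate estimators are provided: the endpoint-pair estimator
``mu = (ln Nt - ln N0) / t`` and the regression estimator
``mu = e^slope - 1`` where ``slope`` is the OLS slope of ln concentration
versus time in days (the only reading under which exponentiating a slope
is dimensionally coherent).

Zero counts are excluded from log-based fits and flagged, never
pseudo-counted: a pseudo-count would silently bias rates near depletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from grazerates.errors import ConfigurationError, UndefinedRateError, ValidationError
from grazerates.timeseries_io import CountSeries, Experiment

FLAG_NEGATIVE_CLEARANCE = "negative_clearance"
FLAG_ZERO_COUNT = "zero_count_interval"
FLAG_OUTSIDE_WINDOW = "outside_decline_window"


@dataclass(frozen=True)
class RateEstimate:
    """A growth-rate estimate (day^-1) over a stated window."""

    value: float
    method: str  # "exponential" (endpoint pair) or "linear" (e^slope - 1)
    window: tuple[float, float]
    n_points: int
    fit_r2: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError("a rate estimate needs at least two points")
        if self.window[1] <= self.window[0]:
            raise ValidationError("window end must exceed window start")


@dataclass(frozen=True)
class GrazingRates:
    """Clearance and ingestion estimates for one sampling interval.

    Units: ``k``, ``g`` in day^-1; ``B_avg``, ``P`` in cells mL^-1; ``F``
    in mL predator^-1 day^-1; ``I`` in prey cells predator^-1 day^-1.
    ``flags`` collects quality annotations; flagged rows are excluded from
    summary means.
    """

    flask_id: str
    prey_strain: str
    predator_strain: str
    interval: tuple[float, float]
    k: float
    g: float
    B_avg: float
    P: float
    F: float
    I: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        if math.isfinite(self.I) and math.isfinite(self.B_avg) and math.isfinite(self.F):
            expected = self.B_avg * self.F
            scale = max(abs(expected), abs(self.I), 1e-300)
            if abs(self.I - expected) > 1e-9 * scale:
                raise ValidationError(
                    f"I must equal B_avg * F (got {self.I}, expected {expected})"
                )


def _slice_window(series: CountSeries, window: tuple[float, float] | None):
    if window is None:
        return series.days, slice(None)
    lo, hi = window
    mask = (series.days >= lo) & (series.days <= hi)
    return series.days[mask], mask


def _concentrations(series: CountSeries, which: str) -> np.ndarray:
    if which == "prey":
        return series.prey_conc
    if which == "predator":
        return series.predator_conc
    raise ValueError(f"which must be 'prey' or 'predator', got {which!r}")


def exponential_growth_rate(
    series: CountSeries,
    which: str = "prey",
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Endpoint growth rate ``mu = (ln Nt - ln N0) / t`` in day^-1.

    Uses only the first and last in-window samples; both endpoint
    concentrations must be positive.
    """
    conc = _concentrations(series, which)
    days, mask = _slice_window(series, window)
    conc = conc[mask]
    if len(days) < 2:
        raise UndefinedRateError("window contains fewer than two samples")
    n0, nt = conc[0], conc[-1]
    if n0 <= 0 or nt <= 0:
        raise UndefinedRateError(
            f"non-positive endpoint concentration ({n0}, {nt}): rate undefined"
        )
    t = days[-1] - days[0]
    value = (math.log(nt) - math.log(n0)) / t
    return RateEstimate(
        value=value,
        method="exponential",
        window=(float(days[0]), float(days[-1])),
        n_points=2,
    )


def linear_growth_rate(
    series: CountSeries,
    which: str = "prey",
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Regression growth rate ``mu = e^slope - 1`` in day^-1.

    ``slope`` is the OLS slope of ln concentration on time over all
    in-window points with positive counts; zero counts are dropped from
    the fit. R^2 of the log-linear fit is reported (``None`` when only two
    points enter, where R^2 is vacuously 1).
    """
    conc = _concentrations(series, which)
    days, mask = _slice_window(series, window)
    conc = conc[mask]
    usable = conc > 0
    if usable.sum() < 2:
        raise UndefinedRateError("fewer than two positive counts in window")
    x = days[usable]
    y = np.log(conc[usable])
    slope, _, r, _, _ = stats.linregress(x, y)
    value = math.exp(slope) - 1.0
    return RateEstimate(
        value=float(value),
        method="linear",
        window=(float(x[0]), float(x[-1])),
        n_points=int(usable.sum()),
        fit_r2=float(r**2) if len(x) > 2 else None,
    )


def log_mean_concentration(B0: float, B1: float) -> float:
    """Logarithmic mean ``(B1 - B0) / (ln B1 - ln B0)`` in cells mL^-1.

    The exact time average of an exponentially changing concentration.
    Continuous at ``B1 == B0`` (returns ``B0`` when the relative
    difference is below 1e-9); bounded by min and max of the endpoints.
    """
    if B0 <= 0 or B1 <= 0:
        raise UndefinedRateError("logarithmic mean needs positive endpoints")
    if abs(B1 - B0) < 1e-9 * max(B0, B1):
        return float(B0)
    return (B1 - B0) / (math.log(B1) - math.log(B0))


def clearance_rate(k: float, g: float, P: float) -> float:
    """Clearance ``F = (k - g) / P`` in mL predator^-1 day^-1.

    Negative values (apparent prey growth exceeding the monoculture rate)
    are returned unclamped; callers flag them.
    """
    if P <= 0:
        raise UndefinedRateError("average predator concentration must be positive")
    return (k - g) / P


def ingestion_rate(B_avg: float, F: float) -> float:
    """Ingestion ``I = B_avg * F`` in prey cells predator^-1 day^-1."""
    return B_avg * F


def detect_decline_window(
    series: CountSeries,
    r2_min: float = 0.90,
    min_points: int = 3,
) -> tuple[float, float] | None:
    """Find the longest log-linear decline phase of the prey series.

    Scans every contiguous run of at least ``min_points`` sampling points
    in which prey concentration is strictly decreasing and the OLS fit of
    ln prey on day has R^2 >= ``r2_min`` (runs containing zero counts are
    skipped, since the log fit is undefined there). Returns the
    ``(start_day, end_day)`` of the longest qualifying run — ties broken
    toward the earlier window — or ``None`` if no run qualifies.
    """
    n = series.n_points
    if n < min_points:
        return None
    days = series.days
    prey = series.prey_conc
    best: tuple[float, float] | None = None
    best_len = 0
    for i in range(n):
        for j in range(i + min_points - 1, n):
            seg = prey[i : j + 1]
            if np.any(seg <= 0) or np.any(np.diff(seg) >= 0):
                continue
            slope, _, r, _, _ = stats.linregress(days[i : j + 1], np.log(seg))
            if r**2 < r2_min:
                continue
            run_len = j - i + 1
            if run_len > best_len:
                best_len = run_len
                best = (float(days[i]), float(days[j]))
    return best


def _pair_controls(
    experiment: Experiment, grazed: Iterable[CountSeries]
) -> list[tuple[CountSeries, CountSeries]]:
    """Pair each grazed flask with a same-prey-strain control.

    Replicate controls are matched to grazed replicates in sorted flask-id
    order, cycling when the counts differ.
    """
    grouped: dict[str, list[CountSeries]] = {}
    for s in grazed:
        grouped.setdefault(s.prey_strain, []).append(s)
    pairs = []
    for strain, flasks in grouped.items():
        controls = sorted(experiment.controls(strain), key=lambda s: s.flask_id)
        if not controls:
            raise ConfigurationError(
                f"no control flask for prey strain {strain!r}"
            )
        for i, s in enumerate(sorted(flasks, key=lambda f: f.flask_id)):
            pairs.append((s, controls[i % len(controls)]))
    return pairs


def grazing_table(
    experiment: Experiment,
    predator_strain: str,
    mode: str = "per_interval",
    r2_min: float = 0.90,
    global_k: bool = False,
) -> tuple[GrazingRates, ...]:
    """Per-interval clearance and ingestion rates for one grazer strain.

    For every consecutive sampling pair of every grazed flask: ``k`` is the
    strain-matched control's endpoint rate over the same interval (or the
    control's whole-series rate when ``global_k``), ``g`` the grazed
    flask's endpoint rate, ``B_avg`` and ``P`` the logarithmic means of the
    grazed flask's prey and predator endpoints, and ``F`` and ``I`` follow.

    ``mode="decline_window"`` restricts the usable intervals to the
    detected prey decline phase intersected with intervals of positive
    predator growth; other intervals are emitted flagged
    ``outside_decline_window``. Intervals with a zero count at either
    endpoint are emitted with NaN rates and flagged
    ``zero_count_interval``. Flagged rows are excluded by
    :func:`summarize_rates`.
    """
    if mode not in ("per_interval", "decline_window"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    grazed = experiment.grazed(predator_strain)
    if not grazed:
        raise ConfigurationError(
            f"no grazed flasks with predator strain {predator_strain!r}"
        )
    rows: list[GrazingRates] = []
    for gz, ctrl in _pair_controls(experiment, grazed):
        window = (
            detect_decline_window(gz, r2_min=r2_min)
            if mode == "decline_window"
            else None
        )
        k_global = (
            exponential_growth_rate(ctrl, "prey").value if global_k else None
        )
        for a in range(gz.n_points - 1):
            t0, t1 = float(gz.days[a]), float(gz.days[a + 1])
            flags: set[str] = set()
            if mode == "decline_window":
                in_window = window is not None and window[0] <= t0 and t1 <= window[1]
                pred_ok = (
                    gz.predator_conc[a] > 0
                    and gz.predator_conc[a + 1] > gz.predator_conc[a]
                )
                if not (in_window and pred_ok):
                    flags.add(FLAG_OUTSIDE_WINDOW)
            b0, b1 = gz.prey_conc[a], gz.prey_conc[a + 1]
            c0, c1 = gz.predator_conc[a], gz.predator_conc[a + 1]
            ctrl_window = (t0, t1)
            try:
                if k_global is not None:
                    k = k_global
                else:
                    k = exponential_growth_rate(ctrl, "prey", ctrl_window).value
                g = exponential_growth_rate(gz, "prey", (t0, t1)).value
                B_avg = log_mean_concentration(b0, b1)
                P = log_mean_concentration(c0, c1)
                F = clearance_rate(k, g, P)
                I = ingestion_rate(B_avg, F)
                if F < 0:
                    flags.add(FLAG_NEGATIVE_CLEARANCE)
            except UndefinedRateError:
                flags.add(FLAG_ZERO_COUNT)
                k = g = B_avg = P = F = I = float("nan")
            rows.append(
                GrazingRates(
                    flask_id=gz.flask_id,
                    prey_strain=gz.prey_strain,
                    predator_strain=str(gz.predator_strain),
                    interval=(t0, t1),
                    k=k,
                    g=g,
                    B_avg=B_avg,
                    P=P,
                    F=F,
                    I=I,
                    flags=frozenset(flags),
                )
            )
    return tuple(rows)


def summarize_rates(
    rows: Iterable[GrazingRates],
    weighting: str = "per_interval",
    include_negative_clearance: bool = True,
) -> pd.Series:
    """Summary means of k, g, F, I across usable intervals.

    Rows flagged ``zero_count_interval`` or ``outside_decline_window`` are
    excluded. ``weighting="per_interval"`` averages all usable intervals
    pooled across flasks and prey strains; ``"per_strain"`` averages
    within each prey strain first, then across strains. Negative-clearance
    rows are kept by default so that averages stay unbiased.
    """
    if weighting not in ("per_interval", "per_strain"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    usable = [
        r
        for r in rows
        if FLAG_ZERO_COUNT not in r.flags
        and FLAG_OUTSIDE_WINDOW not in r.flags
        and (include_negative_clearance or FLAG_NEGATIVE_CLEARANCE not in r.flags)
    ]
    if not usable:
        return pd.Series(
            {c: float("nan") for c in ("mean_k", "mean_g", "mean_F", "mean_I")}
            | {"n_intervals": 0}
        )
    df = pd.DataFrame(
        {
            "prey_strain": [r.prey_strain for r in usable],
            "k": [r.k for r in usable],
            "g": [r.g for r in usable],
            "F": [r.F for r in usable],
            "I": [r.I for r in usable],
        }
    )
    if weighting == "per_strain":
        df = df.groupby("prey_strain").mean(numeric_only=True)
    return pd.Series(
        {
            "mean_k": float(df["k"].mean()),
            "mean_g": float(df["g"].mean()),
            "mean_F": float(df["F"].mean()),
            "mean_I": float(df["I"].mean()),
            "n_intervals": len(usable),
        }
    )
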