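"""Cell biovolume morphometry and between-strain comparison.

Ciliate cells are approximated as prolate ellipsoids and their volume is
computed as

    V = 4/3 * pi * length * width**2

with the *full* length and width in um, not the semi-axes. The semi-axis
ellipsoid volume would be one eighth of this; the convention here follows
the formula as applied in the source analysis and is kept verbatim so that
published per-cell volumes reproduce. Mean strain volume is the arithmetic
mean of per-cell volumes, never the volume of mean dimensions (Jensen's
inequality makes these differ for variable cells).

Strains are compared with a pooled-variance (Student) two-sample t-test,
the only variant consistent with df = n_a + n_b - 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grazerates.errors import ValidationError


@dataclass(frozen=True)
class CellMeasurement:
    """A single cell's length and width in micrometres.

    By the prolate convention length should be the larger dimension; inputs
    with length < width are accepted with a warning because measurement
    order can be ambiguous on near-spherical cells.
    """

    strain: str
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.length) and math.isfinite(self.width)):
            raise ValidationError("length and width must be finite")
        if self.length <= 0 or self.width <= 0:
            raise ValidationError("length and width must be positive")
        if self.length < self.width:
            warnings.warn(
                f"cell of strain {self.strain!r}: length ({self.length}) < "
                f"width ({self.width}); prolate convention expects length >= width",
                stacklevel=2,
            )

    @property
    def volume(self) -> float:
        """Prolate-ellipsoid biovolume in um^3."""
        return prolate_volume(self.length, self.width)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float


def prolate_volume(length: float, width: float) -> float:
    """Biovolume (um^3) of a prolate ellipsoid from full length and width.

    Returns ``4/3 * pi * length * width**2`` exactly as written; no
    halving to semi-axes is applied.

    >>> round(prolate_volume(16.9, 11.8), 1)
    9856.5
    """
    if length < 0 or width < 0:
        raise ValidationError("length and width must be non-negative")
    return (4.0 / 3.0) * math.pi * length * width * width


def volume_summary(measurements: Iterable[CellMeasurement]) -> pd.DataFrame:
    """Per-strain summary of cell dimensions and biovolume.

    Returns a DataFrame indexed by strain with columns ``n``,
    ``mean_length_um``, ``mean_width_um`` and ``mean_volume_um3``, where
    mean volume averages the per-cell prolate volumes.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValidationError("no measurements supplied")
    df = pd.DataFrame(
        {
            "strain": [m.strain for m in measurements],
            "length": [m.length for m in measurements],
            "width": [m.width for m in measurements],
            "volume": [m.volume for m in measurements],
        }
    )
    out = df.groupby("strain").agg(
        n=("volume", "size"),
        mean_length_um=("length", "mean"),
        mean_width_um=("width", "mean"),
        mean_volume_um3=("volume", "mean"),
    )
    return out


def pooled_t_test(
    volumes_a: Sequence[float], volumes_b: Sequence[float]
) -> TTestResult:
    """Student two-sample t-test with pooled variance.

    Degrees of freedom are ``n_a + n_b - 2``; the p-value is two-sided.
    Degenerate case: zero pooled variance with equal means gives
    ``t = 0, p = 1``; zero pooled variance with unequal means is an error.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two values")
    df = len(a) + len(b) - 2
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / df
    if pooled_var == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, df, 1.0, float(np.mean(a)), float(np.mean(b)))
        raise ValidationError(
            "zero pooled variance with unequal means: t is undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
    )


def read_measurements(path) -> tuple[CellMeasurement, ...]:
    """Read a ``strain, length_um, width_um`` CSV into cell measurements."""
    from grazerates.timeseries_io import _read_table

    df = _read_table(path, ("strain", "length_um", "width_um"), None)
    return tuple(
        CellMeasurement(
            strain=str(r["strain"]),
            length=float(r["length_um"]),
            width=float(r["width_um"]),
        )
        for _, r in df.iterrows()
    )
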