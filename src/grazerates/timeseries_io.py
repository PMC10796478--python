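"""Delimited-text I/O and the experiment data model.

The pipeline consumes two kinds of tables, both comma-separated with a
mandatory header row (lines starting with ``#`` are treated as provenance
comments and skipped):

* flask count series — columns ``flask_id, day, prey_per_ml,
  predator_per_ml, treatment, prey_strain, predator_strain``; one row per
  flask per sampling day. Days are real numbers counted from the addition
  of the ciliate (day 0).
* read-abundance records — columns ``lake, date, fraction, taxon, reads``
  with ``fraction`` one of ``small`` (0.2-10 um) or ``large`` (10-100 um).

Zero concentrations are retained on read; the rates module decides how
log-based estimators treat them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from grazerates.errors import FormatError, ValidationError

COUNT_COLUMNS = (
    "flask_id",
    "day",
    "prey_per_ml",
    "predator_per_ml",
    "treatment",
    "prey_strain",
    "predator_strain",
)

ABUNDANCE_COLUMNS = ("lake", "date", "fraction", "taxon", "reads")

FRACTIONS = ("small", "large")


@dataclass(frozen=True)
class CountSeries:
    """One flask's count time series.

    Parameters
    ----------
    flask_id : str
        Unique flask label.
    prey_strain : str
        Identifier of the algal strain in the flask.
    predator_strain : str or None
        Ciliate strain, or ``None`` for grazer-free monoculture controls.
    treatment : {"control", "grazed"}
    days : array of float
        Sampling times in days since ciliate addition, strictly increasing.
    prey_conc, predator_conc : array of float
        Concentrations in cells per mL, non-negative, same length as
        ``days``. ``predator_conc`` is all-zero for controls.
    """

    flask_id: str
    prey_strain: str
    predator_strain: str | None
    treatment: str
    days: np.ndarray
    prey_conc: np.ndarray
    predator_conc: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(self, "prey_conc", np.asarray(self.prey_conc, dtype=float))
        object.__setattr__(
            self, "predator_conc", np.asarray(self.predator_conc, dtype=float)
        )
        if self.treatment not in ("control", "grazed"):
            raise ValidationError(
                f"flask {self.flask_id!r}: treatment must be 'control' or "
                f"'grazed', got {self.treatment!r}"
            )
        if self.days.ndim != 1 or len(self.days) == 0:
            raise ValidationError(f"flask {self.flask_id!r}: empty series")
        if not (len(self.days) == len(self.prey_conc) == len(self.predator_conc)):
            raise ValidationError(
                f"flask {self.flask_id!r}: days, prey_conc and predator_conc "
                "must have equal length"
            )
        if np.any(np.diff(self.days) <= 0):
            raise ValidationError(
                f"flask {self.flask_id!r}: sampling days must be strictly increasing"
            )
        if np.any(self.days < 0):
            raise ValidationError(f"flask {self.flask_id!r}: negative sampling day")
        for name, arr in (("prey", self.prey_conc), ("predator", self.predator_conc)):
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(
                    f"flask {self.flask_id!r}: {name} concentrations must be "
                    "finite and non-negative"
                )
        is_control = self.treatment == "control"
        has_predator_strain = self.predator_strain is not None
        any_predators = bool(np.any(self.predator_conc > 0))
        if is_control and (has_predator_strain or any_predators):
            raise ValidationError(
                f"flask {self.flask_id!r}: control flask must have no predator "
                "strain and all-zero predator counts"
            )
        if not is_control and not has_predator_strain:
            raise ValidationError(
                f"flask {self.flask_id!r}: grazed flask needs a predator strain"
            )

    @property
    def n_points(self) -> int:
        return len(self.days)


@dataclass(frozen=True)
class Experiment:
    """A collection of count series plus the prey x predator design map."""

    series: tuple[CountSeries, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.flask_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate flask ids in experiment")
        control_strains = {s.prey_strain for s in self.series if s.treatment == "control"}
        for s in self.series:
            if s.treatment == "grazed" and s.prey_strain not in control_strains:
                raise ValidationError(
                    f"grazed flask {s.flask_id!r} (prey strain {s.prey_strain!r}) "
                    "has no same-strain control flask"
                )

    @property
    def design(self) -> dict[tuple[str, str | None], tuple[str, ...]]:
        """Mapping (prey_strain, predator_strain) -> flask ids."""
        out: dict[tuple[str, str | None], list[str]] = {}
        for s in self.series:
            out.setdefault((s.prey_strain, s.predator_strain), []).append(s.flask_id)
        return {key: tuple(v) for key, v in out.items()}

    def controls(self, prey_strain: str) -> tuple[CountSeries, ...]:
        return tuple(
            s
            for s in self.series
            if s.treatment == "control" and s.prey_strain == prey_strain
        )

    def grazed(self, predator_strain: str | None = None) -> tuple[CountSeries, ...]:
        return tuple(
            s
            for s in self.series
            if s.treatment == "grazed"
            and (predator_strain is None or s.predator_strain == predator_strain)
        )

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)


@dataclass(frozen=True)
class AbundanceRecord:
    """One taxon's read count in one size-fractionated lake sample."""

    lake: str
    date: _dt.date
    fraction: str
    taxon: str
    reads: int

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if not isinstance(self.reads, (int, np.integer)) or isinstance(
            self.reads, bool
        ):
            raise ValidationError(f"reads must be an integer, got {self.reads!r}")
        if self.reads < 0:
            raise ValidationError(f"reads must be non-negative, got {self.reads}")


def _read_table(path, required: Sequence[str], renames: Mapping[str, str] | None):
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if renames:
        df = df.rename(columns={v: k for k, v in renames.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_counts(path, dialect: Mapping[str, str] | None = None) -> Experiment:
    """Read a flask-count CSV into a validated :class:`Experiment`.

    ``dialect`` optionally maps canonical column names to the names used in
    the file, e.g. ``{"prey_per_ml": "algae"}``. Rows are grouped by
    ``flask_id`` and sorted by ``day``; every series invariant is checked.
    """
    df = _read_table(path, COUNT_COLUMNS, dialect)
    dup = df.duplicated(subset=["flask_id", "day"])
    if dup.any():
        rows = df.loc[dup, ["flask_id", "day"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicated (flask_id, day) pair "
            f"({rows['flask_id']!r}, {rows['day']})"
        )
    for col in ("prey_per_ml", "predator_per_ml"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce") < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative {col} in data row {int(bad[0]) + 1}"
            )
    series = []
    for flask_id, grp in df.groupby("flask_id", sort=True):
        grp = grp.sort_values("day")
        predator_strain = grp["predator_strain"].iloc[0]
        if pd.isna(predator_strain) or str(predator_strain).strip() == "":
            predator_strain = None
        series.append(
            CountSeries(
                flask_id=str(flask_id),
                prey_strain=str(grp["prey_strain"].iloc[0]),
                predator_strain=(
                    None if predator_strain is None else str(predator_strain)
                ),
                treatment=str(grp["treatment"].iloc[0]),
                days=grp["day"].to_numpy(dtype=float),
                prey_conc=grp["prey_per_ml"].to_numpy(dtype=float),
                predator_conc=grp["predator_per_ml"].to_numpy(dtype=float),
            )
        )
    return Experiment(series=tuple(series))


def write_counts(experiment: Experiment, path, header_comment: str | None = None) -> None:
    """Write an :class:`Experiment` back to the canonical counts CSV."""
    rows = []
    for s in experiment:
        for d, b, c in zip(s.days, s.prey_conc, s.predator_conc):
            rows.append(
                {
                    "flask_id": s.flask_id,
                    "day": d,
                    "prey_per_ml": b,
                    "predator_per_ml": c,
                    "treatment": s.treatment,
                    "prey_strain": s.prey_strain,
                    "predator_strain": "" if s.predator_strain is None else s.predator_strain,
                }
            )
    df = pd.DataFrame(rows, columns=list(COUNT_COLUMNS))
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_abundance(path, dialect: Mapping[str, str] | None = None) -> tuple[AbundanceRecord, ...]:
    """Read a lake/date/fraction/taxon/reads CSV into validated records."""
    df = _read_table(path, ABUNDANCE_COLUMNS, dialect)
    records = []
    for idx, row in df.iterrows():
        reads_raw = row["reads"]
        reads_f = float(reads_raw)
        if reads_f != int(reads_f):
            raise ValidationError(
                f"{path}: non-integer reads {reads_raw!r} in data row {idx + 1}"
            )
        try:
            date = pd.Timestamp(row["date"]).date()
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{path}: unparseable date {row['date']!r} in data row {idx + 1}"
            ) from exc
        records.append(
            AbundanceRecord(
                lake=str(row["lake"]),
                date=date,
                fraction=str(row["fraction"]),
                taxon=str(row["taxon"]),
                reads=int(reads_f),
            )
        )
    return tuple(records)


RATES_COLUMNS = (
    "flask_id",
    "prey_strain",
    "predator_strain",
    "t_start",
    "t_end",
    "k",
    "g",
    "B_avg",
    "P",
    "F",
    "I",
    "flags",
)


def write_rates_table(rates: Iterable, path, header_comment: str | None = None) -> None:
    """Write per-interval grazing-rate rows to CSV.

    Accepts any iterable of :class:`grazerates.rates.GrazingRates`. Numeric
    columns are printed with 12 significant digits so a read-back
    round-trips within 1e-9 relative.
    """
    rows = []
    for r in rates:
        rows.append(
            {
                "flask_id": r.flask_id,
                "prey_strain": r.prey_strain,
                "predator_strain": r.predator_strain,
                "t_start": r.interval[0],
                "t_end": r.interval[1],
                "k": r.k,
                "g": r.g,
                "B_avg": r.B_avg,
                "P": r.P,
                "F": r.F,
                "I": r.I,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    df = pd.DataFrame(rows, columns=list(RATES_COLUMNS))
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_rates_table(path) -> tuple:
    """Read a grazing-rate CSV written by :func:`write_rates_table`."""
    from grazerates.rates import GrazingRates  # local import: avoids a cycle

    df = _read_table(path, RATES_COLUMNS, None)
    out = []
    for _, row in df.iterrows():
        flags = frozenset(
            f for f in str(row["flags"]).split(";") if f and f != "nan"
        )
        out.append(
            GrazingRates(
                flask_id=str(row["flask_id"]),
                prey_strain=str(row["prey_strain"]),
                predator_strain=str(row["predator_strain"]),
                interval=(float(row["t_start"]), float(row["t_end"])),
                k=float(row["k"]),
                g=float(row["g"]),
                B_avg=float(row["B_avg"]),
                P=float(row["P"]),
                F=float(row["F"]),
                I=float(row["I"]),
                flags=flags,
            )
        )
    return tuple(out)
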