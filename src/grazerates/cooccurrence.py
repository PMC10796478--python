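"""High/low co-occurrence screening of amplicon read abundances.

Each (lake, date) sample yields one read count for the prey taxon (taken
from the large, 10-100 um size fraction, where the alga occurs) and one
for the grazer taxon (small, 0.2-10 um fraction). Counts are classified
with strict thresholds — prey "high" above 20,000 reads, grazer "low"
below 5,000 reads by default — and tallied into four quadrants. Because
the two fractions are sequenced as separate samples, raw read numbers are
not cross-sample proportional; the summary is deliberately descriptive
and no association statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from grazerates.errors import ValidationError
from grazerates.timeseries_io import AbundanceRecord

QUADRANTS = (
    "prey_high_grazer_high",
    "prey_high_grazer_low",
    "prey_low_grazer_high",
    "prey_low_grazer_low",
)


@dataclass(frozen=True)
class Thresholds:
    """Read-count thresholds; comparisons are strict on both sides."""

    prey_high_min: int = 20_000
    grazer_low_max: int = 5_000


@dataclass(frozen=True)
class CooccurrenceSummary:
    quadrant_counts: dict[str, int]
    thresholds: Thresholds
    n_samples: int
    scatter: pd.DataFrame  # lake, date, prey_reads, grazer_reads, quadrant

    def __post_init__(self) -> None:
        if sum(self.quadrant_counts.values()) != self.n_samples:
            raise ValidationError("quadrant counts must sum to n_samples")


def classify_sample(
    prey_reads: int, grazer_reads: int, thresholds: Thresholds = Thresholds()
) -> str:
    """Quadrant label for one sample's prey and grazer read counts.

    Prey is high iff strictly above ``prey_high_min``; grazer is low iff
    strictly below ``grazer_low_max``. Boundary values therefore fall in
    the prey-low / grazer-high classes.
    """
    if prey_reads < 0 or grazer_reads < 0:
        raise ValidationError("read counts must be non-negative")
    prey = "prey_high" if prey_reads > thresholds.prey_high_min else "prey_low"
    grazer = "grazer_low" if grazer_reads < thresholds.grazer_low_max else "grazer_high"
    return f"{prey}_{grazer}"


def summarize(
    records: Iterable[AbundanceRecord],
    prey_taxon: str,
    grazer_taxon: str,
    thresholds: Thresholds = Thresholds(),
    prey_fraction: str = "large",
    grazer_fraction: str = "small",
) -> CooccurrenceSummary:
    """Tally quadrant membership across (lake, date) samples.

    For each (lake, date): the prey's reads are taken from
    ``prey_fraction`` and the grazer's from ``grazer_fraction``; a taxon
    missing from a sample counts as 0 reads. At least one of the two taxa
    must appear somewhere in the records.
    """
    records = list(records)
    relevant = [r for r in records if r.taxon in (prey_taxon, grazer_taxon)]
    if not relevant:
        raise ValidationError(
            f"neither {prey_taxon!r} nor {grazer_taxon!r} found in the records"
        )
    samples = sorted({(r.lake, r.date) for r in relevant})
    lookup: dict[tuple[str, object, str, str], int] = {}
    for r in relevant:
        key = (r.lake, r.date, r.fraction, r.taxon)
        lookup[key] = lookup.get(key, 0) + r.reads
    rows = []
    counts = {q: 0 for q in QUADRANTS}
    for lake, date in samples:
        prey_reads = lookup.get((lake, date, prey_fraction, prey_taxon), 0)
        grazer_reads = lookup.get((lake, date, grazer_fraction, grazer_taxon), 0)
        quadrant = classify_sample(prey_reads, grazer_reads, thresholds)
        counts[quadrant] += 1
        rows.append(
            {
                "lake": lake,
                "date": date,
                "prey_reads": prey_reads,
                "grazer_reads": grazer_reads,
                "quadrant": quadrant,
            }
        )
    scatter = pd.DataFrame(
        rows, columns=["lake", "date", "prey_reads", "grazer_reads", "quadrant"]
    )
    return CooccurrenceSummary(
        quadrant_counts=counts,
        thresholds=thresholds,
        n_samples=len(samples),
        scatter=scatter,
    )
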