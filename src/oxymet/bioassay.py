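"""Encoding of DPPH antioxidant and disk-diffusion antibiotic assays.

The DPPH radical-scavenging test is read at 517 nm: extracts that bleach
the radical lower the absorbance relative to the DPPH-only negative
control.  The assay as performed is colorimetric/qualitative (pink vs
yellow); the quantitative operationalization here — scavenging fraction
1 - A_sample/A_control called "+" at a configurable 20% threshold — is
this package's own, chosen so that clearly bleached wells call positive
while instrument noise does not.

Disk diffusion uses 6 mm disks; any inhibition halo beyond the disk
diameter (zone > 6 mm) is a positive antibiotic call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import SampleMeta

__all__ = [
    "DpphMeasurement",
    "ActivityCall",
    "DiskZone",
    "call_dpph",
    "call_zone",
    "activity_table",
    "parse_activity_table",
    "DEFAULT_SCAVENGING_THRESHOLD",
    "DISK_DIAMETER_MM",
]

#: Scavenging fraction at/above which a DPPH well calls "+".
DEFAULT_SCAVENGING_THRESHOLD = 0.2
#: Paper-disk diameter (mm); zones beyond this call "+".
DISK_DIAMETER_MM = 6.0
#: Measurement wavelength (nm), fixed by the assay.
DPPH_WAVELENGTH_NM = 517


@dataclass(frozen=True)
class DpphMeasurement:
    """One well: extract absorbance vs the DPPH-only negative control."""

    sample: SampleMeta
    absorbance_517: float
    negative_control_absorbance: float

    def __post_init__(self) -> None:
        if self.absorbance_517 < 0:
            raise ValueError("absorbance must be >= 0")
        if self.negative_control_absorbance < 0:
            raise ValueError("control absorbance must be >= 0")


@dataclass(frozen=True)
class ActivityCall:
    """A thresholded +/- call with its underlying quantitative value."""

    sample: SampleMeta
    call: str  # "+" or "-"
    value: float  # scavenging fraction, or zone diameter in mm


@dataclass(frozen=True)
class DiskZone:
    """One disk-diffusion measurement (zone diameter includes the disk)."""

    sample: SampleMeta
    test_organism: str
    zone_mm: float

    def __post_init__(self) -> None:
        if self.zone_mm < 0:
            raise ValueError("zone diameter must be >= 0")


def call_dpph(
    measurement: DpphMeasurement,
    threshold: float = DEFAULT_SCAVENGING_THRESHOLD,
) -> ActivityCall:
    """Call antioxidant activity from a DPPH well.

    scavenging = 1 - A_sample / A_control; "+" iff scavenging >= threshold.
    Monotone: lowering the sample absorbance never flips "+" to "-".
    """
    if measurement.negative_control_absorbance <= 0:
        raise ValueError("negative control absorbance must be positive")
    scavenging = 1.0 - measurement.absorbance_517 / measurement.negative_control_absorbance
    return ActivityCall(
        sample=measurement.sample,
        call="+" if scavenging >= threshold else "-",
        value=scavenging,
    )


def call_zone(zone: DiskZone, disk_mm: float = DISK_DIAMETER_MM) -> ActivityCall:
    """Call antibiotic activity: "+" iff the zone extends beyond the disk."""
    return ActivityCall(
        sample=zone.sample,
        call="+" if zone.zone_mm > disk_mm else "-",
        value=zone.zone_mm,
    )


def activity_table(calls: list[ActivityCall]) -> pd.DataFrame:
    """Arrange calls as a (condition, fraction) x week grid of {+, -, NA}.

    Missing cells are "NA", never "-": absence of a measurement is not
    negativity.  Duplicate (condition, week, fraction) cells are an error.
    """
    if not calls:
        return pd.DataFrame()
    cells: dict[tuple[str, str], dict[int, str]] = {}
    seen = set()
    for c in calls:
        key = (c.sample.condition, c.sample.week, c.sample.fraction)
        if key in seen:
            raise ValueError(f"duplicate activity cell {key}")
        seen.add(key)
        cells.setdefault((c.sample.condition, c.sample.fraction), {})[c.sample.week] = c.call
    weeks = sorted({w for row in cells.values() for w in row})
    rows = sorted(cells)
    grid = pd.DataFrame(
        [[cells[r].get(w, "NA") for w in weeks] for r in rows],
        index=pd.MultiIndex.from_tuples(rows, names=["condition", "fraction"]),
        columns=pd.Index(weeks, name="week"),
    )
    return grid


def parse_activity_table(grid: pd.DataFrame, strain: str = "") -> list[tuple[SampleMeta, str]]:
    """Inverse of :func:`activity_table`: (sample, call) pairs, NA cells skipped."""
    out = []
    for (condition, fraction), row in grid.iterrows():
        for week, call in row.items():
            if call == "NA":
                continue
            out.append(
                (SampleMeta(strain, condition, int(week), fraction), str(call))
            )
    return out
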