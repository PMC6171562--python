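"""CSV interchange: chromatograms, channel-intensity tables and exports.

All interchange is plain CSV with explicit headers.  Chromatograms travel in
long format (``transition_id, time_min, intensity``); labeling data as one
row per channel (``analyte, time, k, j, area``).  Row numbers are reported
in validation errors (header is row 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .peaks import Chromatogram

__all__ = [
    "IntensityRecord",
    "read_intensity_table",
    "write_intensity_table",
    "read_chromatograms",
    "write_chromatograms",
]

CHROM_COLUMNS = ["transition_id", "time_min", "intensity"]
INTENSITY_COLUMNS = ["analyte", "time", "k", "j", "area"]


class TableFormatError(ValueError):
    """A CSV table violates the declared schema."""


@dataclass(frozen=True)
class IntensityRecord:
    """One labeled-channel measurement at one time point."""

    analyte: str
    time: float
    k: int
    j: int
    area: float
    row: int  # 1-based CSV line (header = 1), for error reporting


def read_intensity_table(path: str | Path) -> list[IntensityRecord]:
    """Read and validate a channel-area table.

    Raises :class:`TableFormatError` naming the offending column or row on a
    missing column, a negative area, or a duplicate (analyte, time, k, j).
    """
    df = pd.read_csv(path)
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[IntensityRecord] = []
    seen: dict[tuple, int] = {}
    for i, row in df.iterrows():
        line = int(i) + 2
        area = float(row["area"])
        if area < 0:
            raise TableFormatError(f"{path}: negative intensity at row {line}")
        key = (str(row["analyte"]), float(row["time"]), int(row["k"]), int(row["j"]))
        if key in seen:
            raise TableFormatError(
                f"{path}: duplicate channel {key} at rows {seen[key]} and {line}"
            )
        seen[key] = line
        records.append(IntensityRecord(*key, area=area, row=line))
    return records


def write_intensity_table(records: Iterable[IntensityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"analyte": r.analyte, "time": r.time, "k": r.k, "j": r.j, "area": r.area}
            for r in records
        ],
        columns=INTENSITY_COLUMNS,
    ).to_csv(path, index=False)


def read_chromatograms(path: str | Path) -> dict[str, Chromatogram]:
    """Read long-format chromatograms, one :class:`Chromatogram` per transition."""
    df = pd.read_csv(path)
    missing = [c for c in CHROM_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    out: dict[str, Chromatogram] = {}
    for tid, group in df.groupby("transition_id", sort=False):
        g = group.sort_values("time_min")
        out[str(tid)] = Chromatogram(
            str(tid),
            g["time_min"].to_numpy(dtype=float),
            g["intensity"].to_numpy(dtype=float),
        )
    return out


def write_chromatograms(chroms: dict[str, Chromatogram], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "transition_id": c.transition_id,
                "time_min": c.time,
                "intensity": c.intensity,
            }
        )
        for c in chroms.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
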