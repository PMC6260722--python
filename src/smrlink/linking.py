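"""Join mass trajectories to expression profiles through the collection log.

Detection of a cell at the final cantilever triggers the collection stage,
which deposits the cell into a well and appends (release time, well) to the
collection log. Because final-cantilever peak times and log release times
come from the same clock, each trajectory can be matched to the nearest log
record and thence -- by well identity -- to one column of the expression
matrix. Wells that attract zero or two-plus trajectories (failed captures
and co-release multiplets) are excluded and reported, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .qc import ExpressionMatrix
from .smr import CellTrajectory

__all__ = ["CollectionRecord", "CollectionLog", "LinkedCell", "link", "linked_table"]


@dataclass(frozen=True)
class CollectionRecord:
    release_time: float
    well_id: str
    flags: str = ""


@dataclass
class CollectionLog:
    """The motor-position log: one record per release event."""

    records: list[CollectionRecord]

    def __post_init__(self) -> None:
        times = [r.release_time for r in self.records]
        if times != sorted(times):
            raise InputError("release times must be non-decreasing")
        wells = [r.well_id for r in self.records if r.well_id != "waste"]
        if len(wells) != len(set(wells)):
            raise InputError("well_id must be unique except 'waste'")

    @classmethod
    def from_records(cls, records) -> "CollectionLog":
        return cls([CollectionRecord(float(t), str(w), str(f)) for t, w, f in records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.release_time, r.well_id, r.flags) for r in self.records],
            columns=["release_time", "well_id", "flags"],
        )

    @property
    def non_waste(self) -> list[CollectionRecord]:
        return [r for r in self.records if r.well_id != "waste"]


@dataclass
class LinkedCell:
    """A well-identified join of one trajectory with one expression column."""

    well_id: str
    trajectory: CellTrajectory
    expression_column: str


def link(
    trajectories: list[CellTrajectory],
    log: CollectionLog,
    matrix: ExpressionMatrix | None = None,
    tolerance: float | None = None,
) -> tuple[list[LinkedCell], pd.DataFrame]:
    """Match trajectories to wells and wells to expression columns.

    Each QC-clean trajectory is assigned to the log record whose release
    time is nearest its final peak time, within ``tolerance`` (default: half
    the median release spacing, i.e. 15 s for the standard 30 s cell
    spacing). Wells with zero or with two or more matched trajectories are
    excluded, as are wells absent from the expression matrix; all exclusions
    are returned as a report with reasons.

    Returns ``(linked_cells, exclusion_report)``; the report has columns
    ``well_id`` and ``reason`` (one row per excluded well, plus one row per
    flagged trajectory excluded before matching).
    """
    if tolerance is not None and tolerance < 0:
        raise InputError("tolerance must be non-negative")
    records = log.non_waste
    if tolerance is None:
        times = np.array([r.release_time for r in records])
        spacing = np.median(np.diff(times)) if times.size > 1 else 30.0
        tolerance = spacing / 2.0

    report_rows: list[dict] = []
    clean = []
    for t in trajectories:
        if t.is_clean:
            clean.append(t)
        else:
            report_rows.append(
                {"well_id": "", "reason": f"trajectory_flagged:{';'.join(sorted(t.qc_flags))}"}
            )

    rec_times = np.array([r.release_time for r in records])
    by_well: dict[str, list[CellTrajectory]] = {r.well_id: [] for r in records}
    for t in clean:
        final_time = t.peaks[-1].time
        if rec_times.size == 0:
            report_rows.append({"well_id": "", "reason": "no_collection_record"})
            continue
        k = int(np.argmin(np.abs(rec_times - final_time)))
        if abs(rec_times[k] - final_time) > tolerance:
            report_rows.append({"well_id": "", "reason": "no_collection_record"})
            continue
        by_well[records[k].well_id].append(t)

    linked: list[LinkedCell] = []
    columns = set(matrix.values.columns) if matrix is not None else None
    for rec in records:
        matched = by_well[rec.well_id]
        if len(matched) == 0:
            report_rows.append({"well_id": rec.well_id, "reason": "no_trajectory"})
        elif len(matched) >= 2:
            report_rows.append({"well_id": rec.well_id, "reason": "multiplet"})
        elif columns is not None and rec.well_id not in columns:
            report_rows.append({"well_id": rec.well_id, "reason": "missing_expression"})
        else:
            linked.append(
                LinkedCell(
                    well_id=rec.well_id,
                    trajectory=matched[0],
                    expression_column=rec.well_id,
                )
            )
    report = pd.DataFrame(report_rows, columns=["well_id", "reason"])
    return linked, report


def linked_table(linked: list[LinkedCell]) -> pd.DataFrame:
    """Flatten linked cells into the per-well biophysical covariate table."""
    rows = [
        {
            "well_id": lc.well_id,
            "mass": lc.trajectory.final_mass,
            "mar": lc.trajectory.mar,
            "growth_efficiency": lc.trajectory.growth_efficiency,
            "expression_column": lc.expression_column,
        }
        for lc in linked
    ]
    return pd.DataFrame(rows, columns=["well_id", "mass", "mar", "growth_efficiency", "expression_column"])
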