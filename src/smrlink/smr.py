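"""From resonant-frequency traces to mass trajectories and growth rates.

A cell transiting a suspended-microchannel-resonator cantilever depresses its
resonant frequency in proportion to the cell's buoyant mass. This module
turns per-cantilever frequency traces into per-cell records:

* :func:`detect_peaks` -- threshold detection of below-baseline excursions,
  converting peak depth (Hz) to buoyant mass (pg) through the calibration
  factor;
* :func:`match_trajectories` -- greedy in-order association of peaks across
  consecutive cantilevers into single-cell mass trajectories, flagging
  ambiguous (doublet-suspect) and broken (failed-match) chains;
* :func:`fit_mar` -- ordinary-least-squares slope of mass vs time, the mass
  accumulation rate (MAR, pg/h), together with its standard error and the
  mass-normalized MAR (growth efficiency, 1/h).

Cells carrying ``doublet_suspect`` or ``failed_match`` flags are excluded
from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InputError

__all__ = [
    "FrequencyTrace",
    "MassPeak",
    "CellTrajectory",
    "detect_peaks",
    "match_trajectories",
    "fit_mar",
    "unflagged",
    "trajectories_to_frame",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class FrequencyTrace:
    """One cantilever's resonant-frequency samples over time.

    Frequencies may be baseline-relative (peak detection subtracts the trace
    median, so any constant offset is immaterial). ``calibration`` converts
    Hz of peak depth into pg of buoyant mass.
    """

    cantilever_index: int
    times: np.ndarray
    frequencies: np.ndarray
    calibration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.times.shape != self.frequencies.shape:
            raise InputError("times and frequencies must have equal length")
        if self.calibration <= 0:
            raise InputError("calibration must be > 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")


@dataclass(frozen=True)
class MassPeak:
    """A single buoyant-mass measurement: peak apex time and mass (pg)."""

    cantilever_index: int
    time: float
    mass: float


@dataclass
class CellTrajectory:
    """An ordered series of mass peaks for one cell, with its fitted MAR."""

    cell_id: str
    peaks: list[MassPeak]
    mar: float | None = None
    mar_stderr: float | None = None
    final_mass: float | None = None
    growth_efficiency: float | None = None
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        times = [p.time for p in self.peaks]
        if times != sorted(times):
            raise InputError("trajectory peaks must be time-ordered")

    @property
    def is_clean(self) -> bool:
        return not (self.qc_flags & {"doublet_suspect", "failed_match", "too_few_points"})


def detect_peaks(trace: FrequencyTrace, threshold: float) -> list[MassPeak]:
    """Detect mass peaks as below-baseline excursions deeper than ``threshold``.

    The baseline is the per-trace median (cell transits are sparse relative
    to trace length, so the median sits on the baseline). Each contiguous run
    of samples whose depth below baseline exceeds ``threshold`` yields one
    peak at the sample of maximal depth, with
    ``mass = calibration * maximal depth``.
    """
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    if trace.times.size == 0:
        return []
    baseline = float(np.median(trace.frequencies))
    depth = baseline - trace.frequencies
    above = depth > threshold
    if not above.any():
        return []
    # contiguous runs of supra-threshold depth
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    peaks = []
    for s, e in zip(starts, ends):
        apex = s + int(np.argmax(depth[s:e]))
        peaks.append(
            MassPeak(
                cantilever_index=trace.cantilever_index,
                time=float(trace.times[apex]),
                mass=float(trace.calibration * depth[apex]),
            )
        )
    return peaks


def match_trajectories(
    peaks_by_cantilever: list[list[MassPeak]],
    expected_transit: float,
    tolerance: float,
) -> list[CellTrajectory]:
    """Chain peaks across cantilevers into per-cell trajectories.

    Greedy and in-order: a trajectory whose last peak is at time *t* accepts
    the earliest unclaimed peak on the next cantilever lying within
    ``t + expected_transit +/- tolerance``. If the earliest *candidate* in a
    trajectory's window is already claimed by another trajectory, both
    trajectories are flagged ``doublet_suspect`` (two cells competing for one
    slot); the earlier claimant keeps the peak. A trajectory that finds no
    peak in its window is flagged ``failed_match`` and stops growing. Every
    input peak joins at most one trajectory.
    """
    if tolerance < 0:
        raise InputError("tolerance must be non-negative")
    for lst in peaks_by_cantilever:
        if [p.time for p in lst] != sorted(p.time for p in lst):
            raise InputError("per-cantilever peak lists must be time-sorted")
    if not peaks_by_cantilever:
        return []

    trajectories = [
        CellTrajectory(cell_id="", peaks=[p]) for p in peaks_by_cantilever[0]
    ]
    for nxt in peaks_by_cantilever[1:]:
        claimed: dict[int, CellTrajectory] = {}
        # trajectories are processed in order of their last peak time
        for traj in sorted(
            (t for t in trajectories if "failed_match" not in t.qc_flags),
            key=lambda t: t.peaks[-1].time,
        ):
            center = traj.peaks[-1].time + expected_transit
            window = [
                k
                for k, p in enumerate(nxt)
                if center - tolerance <= p.time <= center + tolerance
            ]
            if not window:
                traj.qc_flags.add("failed_match")
                continue
            first = window[0]
            if first in claimed:
                # competition: earliest candidate already taken
                traj.qc_flags.add("doublet_suspect")
                claimed[first].qc_flags.add("doublet_suspect")
            free = [k for k in window if k not in claimed]
            if not free:
                traj.qc_flags.add("failed_match")
                continue
            k = free[0]
            claimed[k] = traj
            traj.peaks.append(nxt[k])

    trajectories.sort(key=lambda t: t.peaks[0].time)
    width = max(4, len(str(max(len(trajectories) - 1, 0))))
    for i, traj in enumerate(trajectories):
        traj.cell_id = f"traj_{i:0{width}d}"
    return trajectories


def fit_mar(trajectory: CellTrajectory) -> CellTrajectory:
    """Fit the mass accumulation rate by OLS of mass (pg) on time (h).

    Populates ``mar`` (pg/h), ``mar_stderr``, ``final_mass`` (last peak's
    mass) and ``growth_efficiency`` (MAR / final mass, 1/h) in place and
    returns the trajectory. Trajectories with fewer than two peaks are
    flagged ``too_few_points`` and left unfitted.
    """
    peaks = trajectory.peaks
    if len(peaks) < 2:
        trajectory.qc_flags.add("too_few_points")
        return trajectory
    t_h = np.array([p.time for p in peaks]) / SECONDS_PER_HOUR
    mass = np.array([p.mass for p in peaks])
    if np.ptp(t_h) == 0:
        raise InputError("degenerate fit: all peaks share one timestamp")
    fit = sps.linregress(t_h, mass)
    trajectory.mar = float(fit.slope)
    trajectory.mar_stderr = float(fit.stderr)
    trajectory.final_mass = float(mass[-1])
    trajectory.growth_efficiency = (
        trajectory.mar / trajectory.final_mass if trajectory.final_mass > 0 else np.nan
    )
    return trajectory


def unflagged(trajectories: list[CellTrajectory]) -> list[CellTrajectory]:
    """Trajectories free of doublet/failed-match/too-few-points flags."""
    return [t for t in trajectories if t.is_clean]


def trajectories_to_frame(trajectories: list[CellTrajectory]) -> pd.DataFrame:
    """Serialize trajectories to a flat table (one row per cell).

    Per-cantilever mass/time pairs appear as ``mass_<i>`` / ``time_<i>``
    columns; flags are semicolon-joined.
    """
    rows = []
    for t in trajectories:
        row: dict = {
            "cell_id": t.cell_id,
            "mar": t.mar,
            "mar_stderr": t.mar_stderr,
            "final_mass": t.final_mass,
            "growth_efficiency": t.growth_efficiency,
            "flags": ";".join(sorted(t.qc_flags)),
        }
        for p in t.peaks:
            row[f"time_{p.cantilever_index}"] = p.time
            row[f"mass_{p.cantilever_index}"] = p.mass
        rows.append(row)
    return pd.DataFrame(rows)
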