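"""Synthetic linked single-cell data: device signals and expression matrices.

This module emulates the two halves of a linked biophysical/transcriptomic
experiment so that every downstream stage has a known-answer input:

* a population of cells traversing the cell cycle, each with a ground-truth
  buoyant mass (pg) and mass accumulation rate (MAR, pg/h) tied together by a
  linear mass--growth relationship;
* the serial-SMR device signal: one resonant-frequency trace per cantilever
  with a rectangular frequency dip per cell transit, plus the collection log
  written when each cell is detected at the final cantilever and dispensed
  into a well;
* a counts matrix in which phase-specific gene panels (G1/S, G2/M, mitosis)
  are modulated along the cycle -- hence correlated with mass -- on top of a
  gamma-Poisson (negative binomial) noise model with Bernoulli dropout and
  log-normal library-size variation.

All randomness flows from ``SimConfig.seed`` through independent child
streams, so identical configurations give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError
from .linking import CollectionLog
from .qc import ExpressionMatrix
from .smr import FrequencyTrace

__all__ = [
    "SimCell",
    "SimConfig",
    "simulate_population",
    "simulate_expression",
    "simulate_device_run",
    "well_expression",
    "ground_truth_frame",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class SimCell:
    """One simulated cell with its ground-truth biophysical state.

    ``true_mass`` is the buoyant mass (pg) when the cell enters the first
    cantilever; the instantaneous mass at any later time follows the cell's
    MAR. ``phase_position`` is the fraction of the cell cycle elapsed, in
    [0, 1). ``well_id`` is filled in by :func:`simulate_device_run` and is
    ``"waste"`` until then.
    """

    cell_id: str
    phase_position: float
    true_mass: float
    true_mar: float
    entry_time: float
    well_id: str = "waste"

    def __post_init__(self) -> None:
        if not (0.0 <= self.phase_position < 1.0):
            raise ConfigurationError(
                f"phase_position must be in [0, 1), got {self.phase_position}"
            )
        if self.true_mass <= 0:
            raise ConfigurationError(f"true_mass must be > 0, got {self.true_mass}")

    def mass_at(self, time: float) -> float:
        """Instantaneous buoyant mass (pg) at absolute time ``time`` (s)."""
        return self.true_mass + self.true_mar * (time - self.entry_time) / SECONDS_PER_HOUR


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated experiment.

    Units: masses in pg, times in s, MAR in pg/h, rates as probabilities.

    Parameters
    ----------
    n_cells
        Number of cells released through the device.
    n_cantilevers
        Number of serial mass sensors; must be >= 2 (a growth-rate fit needs
        at least two mass measurements).
    transit_time_mean, transit_time_sd
        Truncated-normal serpentine transit time between consecutive
        cantilevers (s).
    cell_spacing
        Interval between successive cell releases into the array (s); the
        device loads one cell approximately every 30 s.
    mass_growth_coupling, mar_intercept, mar_noise_sd
        The linear mass--growth relationship: MAR = coupling * mass +
        intercept + N(0, mar_noise_sd).
    birth_mass_mean, birth_mass_cv
        Log-normal birth mass; a cell's mass is birth mass times 2**phase.
    noise_sd_mass
        White noise on the frequency traces, expressed as its pg equivalent
        through the calibration factor.
    calibration
        pg of buoyant mass per Hz of frequency-peak depth.
    sample_rate, peak_width
        Trace sampling rate (Hz) and rectangular transit-dip duration (s).
    n_genes, panel_sizes
        Total gene count and sizes of the (G1/S, G2/M, mitosis) panels.
    phase_effect
        Log-scale amplitude of phase modulation of panel genes over one full
        cycle (default 2.0 ~ 7-fold, at the strong end of the 2--10x dynamic
        range typical of cycle-regulated transcripts such as cyclins and
        histones).
    nb_dispersion
        Gamma-Poisson dispersion alpha (variance = mu + alpha * mu**2).
    count_noise
        When False, counts equal their expected values (no gamma-Poisson
        sampling) -- the noise-free regime for exact-construction checks.
    dropout_rate
        Bernoulli zeroing probability applied after count generation.
    libsize_lognorm_params
        (location, scale) of the log-normal per-cell library size.
    doublet_rate
        Probability that a cell co-releases with its successor, sharing one
        collection well.
    peak_loss_rate
        Probability that an intermediate-cantilever peak is lost (failed
        match upstream of the final sensor).
    seed
        Master seed for all random streams.
    """

    n_cells: int = 200
    n_cantilevers: int = 10
    transit_time_mean: float = 20.0
    transit_time_sd: float = 0.5
    cell_spacing: float = 30.0
    mass_growth_coupling: float = 0.05
    mar_intercept: float = 0.0
    mar_noise_sd: float = 0.6
    birth_mass_mean: float = 40.0
    birth_mass_cv: float = 0.12
    noise_sd_mass: float = 0.0
    calibration: float = 1.0
    sample_rate: float = 10.0
    peak_width: float = 0.5
    n_genes: int = 1000
    panel_sizes: tuple[int, int, int] = (43, 54, 29)
    phase_effect: float = 2.0
    nb_dispersion: float = 0.3
    count_noise: bool = True
    dropout_rate: float = 0.2
    libsize_lognorm_params: tuple[float, float] = (np.log(5.0e4), 0.3)
    doublet_rate: float = 0.02
    peak_loss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        if self.n_cantilevers < 2:
            raise ConfigurationError("n_cantilevers must be >= 2")
        if self.cell_spacing <= 0:
            raise ConfigurationError("cell_spacing must be > 0")
        for name in ("dropout_rate", "doublet_rate", "peak_loss_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.transit_time_mean <= 0 or self.transit_time_sd < 0:
            raise ConfigurationError("transit times must be positive")
        if self.calibration <= 0:
            raise ConfigurationError("calibration must be > 0")
        if self.birth_mass_mean <= 0:
            raise ConfigurationError("birth_mass_mean must be > 0")
        if sum(self.panel_sizes) > self.n_genes:
            raise ConfigurationError(
                f"panel sizes {self.panel_sizes} exceed n_genes={self.n_genes}"
            )

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Child generator ``stream`` of the config's master seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(16)[stream])


def simulate_population(config: SimConfig) -> list[SimCell]:
    """Draw a population of cells spread along the cell cycle.

    Mass is birth mass times ``2**phase`` (exponential doubling over the
    cycle) and MAR follows the configured linear coupling to mass with
    Gaussian scatter. Cells enter the device at fixed ``cell_spacing``
    intervals in release order.
    """
    rng = _rng(config, 0)
    n = config.n_cells
    phase = rng.uniform(0.0, 1.0, size=n)
    cv = config.birth_mass_cv
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(config.birth_mass_mean) - 0.5 * sigma**2
    birth_mass = rng.lognormal(mean=mu, sigma=sigma, size=n)
    mass = birth_mass * np.exp2(phase)
    mar = (
        config.mass_growth_coupling * mass
        + config.mar_intercept
        + rng.normal(0.0, config.mar_noise_sd, size=n)
    )
    width = max(4, len(str(max(n - 1, 0))))
    return [
        SimCell(
            cell_id=f"cell_{i:0{width}d}",
            phase_position=float(phase[i]),
            true_mass=float(mass[i]),
            true_mar=float(mar[i]),
            entry_time=float(i * config.cell_spacing),
        )
        for i in range(n)
    ]


def _panel_gene_names(config: SimConfig) -> dict[str, list[str]]:
    n_g1s, n_g2m, n_mit = config.panel_sizes
    width = max(4, len(str(config.n_genes - 1)))
    names = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    return {
        "G1/S": names[:n_g1s],
        "G2/M": names[n_g1s : n_g1s + n_g2m],
        "mitosis": names[n_g1s + n_g2m : n_g1s + n_g2m + n_mit],
        "_all": names,
    }


def simulate_expression(
    cells: Sequence[SimCell], config: SimConfig
) -> tuple[ExpressionMatrix, dict[str, list[str]], pd.DataFrame]:
    """Generate a counts matrix with phase-modulated gene panels.

    G2/M-panel genes increase in rate with phase position (hence with mass),
    G1/S-panel genes decrease, mitosis-panel genes rise sharply late in the
    cycle, and background genes are phase-independent. Counts are
    gamma-Poisson around library-size-scaled rates, then thinned by Bernoulli
    dropout.

    Returns
    -------
    matrix
        ``ExpressionMatrix`` (counts layer), genes x cells, columns labelled
        by ``cell_id``.
    panels
        Mapping of panel name (``G1/S``, ``G2/M``, ``mitosis``) to gene lists.
    truth
        Per-gene ground truth: panel membership and expected correlation
        sign with mass (``+``, ``-`` or ``0``).
    """
    if len(cells) == 0:
        raise ConfigurationError("cell list must be non-empty")
    rng = _rng(config, 1)
    names = _panel_gene_names(config)
    all_genes = names["_all"]
    n_genes, n_cells = config.n_genes, len(cells)
    n_g1s, n_g2m, n_mit = config.panel_sizes
    n_panel = n_g1s + n_g2m + n_mit

    # Cell-cycle programs are moderately-to-highly expressed; background
    # spans the full dynamic range.
    base_log = np.empty(n_genes)
    base_log[:n_panel] = rng.normal(0.5, 0.5, size=n_panel)
    base_log[n_panel:] = rng.normal(0.0, 1.0, size=n_genes - n_panel)

    coef = rng.uniform(0.8, 1.2, size=n_panel) * config.phase_effect
    phase = np.array([c.phase_position for c in cells])
    mod = np.zeros((n_genes, n_cells))
    mod[:n_g1s] = -coef[:n_g1s, None] * phase[None, :]
    mod[n_g1s : n_g1s + n_g2m] = coef[n_g1s : n_g1s + n_g2m, None] * phase[None, :]
    # mitosis genes peak just before division: quadratic rise, still monotone
    mod[n_g1s + n_g2m : n_panel] = coef[n_g1s + n_g2m :, None] * phase[None, :] ** 2

    rates = np.exp(base_log[:, None] + mod)
    proportions = rates / rates.sum(axis=0, keepdims=True)
    loc, scale = config.libsize_lognorm_params
    libsize = rng.lognormal(mean=loc, sigma=scale, size=n_cells)
    mean = proportions * libsize[None, :]

    if not config.count_noise:
        counts = mean.copy()
    else:
        alpha = config.nb_dispersion
        if alpha > 0:
            lam = rng.gamma(1.0 / alpha, mean * alpha)
        else:
            lam = mean
        counts = rng.poisson(lam).astype(float)
    if config.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= config.dropout_rate

    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=all_genes, columns=[c.cell_id for c in cells]),
        layer="counts",
    )
    panels = {k: v for k, v in names.items() if k != "_all"}
    sign = np.array(["-"] * n_g1s + ["+"] * (n_g2m + n_mit) + ["0"] * (n_genes - n_panel))
    panel_label = np.array(
        ["G1/S"] * n_g1s + ["G2/M"] * n_g2m + ["mitosis"] * n_mit
        + ["background"] * (n_genes - n_panel)
    )
    truth = pd.DataFrame(
        {"gene": all_genes, "panel": panel_label, "mass_corr_sign": sign}
    ).set_index("gene")
    return matrix, panels, truth


def simulate_device_run(
    cells: Sequence[SimCell], config: SimConfig
) -> tuple[list[FrequencyTrace], CollectionLog]:
    """Render the device signal for a population and write the collection log.

    Each cell produces one rectangular frequency dip per cantilever, of depth
    ``instantaneous mass / calibration`` Hz, at times set by its entry time
    plus truncated-normal serpentine transit delays. Detection at the final
    cantilever appends a record to the collection log (release time, well).

    With probability ``doublet_rate`` a cell co-releases with its successor:
    the pair shares transit-delay draws (they travel together, 2 s apart)
    and a single collection-log record flagged ``co_release``, so the shared
    well ends up holding two cells. Intermediate peaks may be lost with
    probability ``peak_loss_rate`` (flagged ``peak_lost`` in the log).
    Overlapping dips on one cantilever are flagged ``overlap``, never
    silently dropped.

    Side effect: assigns ``well_id`` on the input cells.
    """
    cells = list(cells)
    if any(c.entry_time < 0 for c in cells):
        raise ConfigurationError("entry times must be non-negative")
    if sorted(c.entry_time for c in cells) != [c.entry_time for c in cells]:
        raise ConfigurationError("cells must be ordered by entry_time")

    rng = _rng(config, 2)
    n_cant = config.n_cantilevers
    n = len(cells)

    # co-release pairing: cell i drags cell i+1 along
    co_release_with_next = np.zeros(n, dtype=bool)
    draws = rng.random(n)
    i = 0
    while i < n - 1:
        if draws[i] < config.doublet_rate:
            co_release_with_next[i] = True
            i += 2
        else:
            i += 1

    def draw_delays() -> np.ndarray:
        d = rng.normal(config.transit_time_mean, config.transit_time_sd, size=n_cant - 1)
        return np.clip(d, 0.2 * config.transit_time_mean, None)

    transit_times = np.zeros((n, n_cant))
    i = 0
    while i < n:
        delays = draw_delays()
        t0 = cells[i].entry_time
        transit_times[i] = t0 + np.concatenate(([0.0], np.cumsum(delays)))
        if co_release_with_next[i]:
            # partner rides the same serpentine flow, trailing by 2 s; its
            # entry time moves up so its mass trajectory starts where it
            # actually first transits
            transit_times[i + 1] = transit_times[i] + 2.0
            cells[i + 1].entry_time = float(transit_times[i + 1, 0])
            i += 2
        else:
            i += 1

    lost = (
        rng.random((n, n_cant - 1)) < config.peak_loss_rate
        if config.peak_loss_rate > 0
        else np.zeros((n, n_cant - 1), dtype=bool)
    )

    t_end = transit_times.max() + config.peak_width + 5.0 if n else 10.0
    n_samples = int(np.ceil(t_end * config.sample_rate)) + 1
    grid = np.arange(n_samples) / config.sample_rate
    noise_hz = config.noise_sd_mass / config.calibration

    traces: list[FrequencyTrace] = []
    overlap_cells: set[str] = set()
    for j in range(n_cant):
        freq = np.zeros(n_samples)
        intervals = []
        for i, cell in enumerate(cells):
            if j > 0 and j < n_cant and j - 1 < lost.shape[1] and lost[i, j - 1]:
                continue
            t = transit_times[i, j]
            sel = (grid >= t) & (grid < t + config.peak_width)
            # dip tracks the instantaneous mass sample by sample, so the
            # detected apex depth is exactly the mass at the apex time
            freq[sel] -= cell.mass_at(grid[sel]) / config.calibration
            intervals.append((t, t + config.peak_width, cell.cell_id))
        intervals.sort()
        for (s0, e0, c0), (s1, e1, c1) in zip(intervals, intervals[1:]):
            if s1 < e0:
                overlap_cells.update((c0, c1))
        if noise_hz > 0:
            freq = freq + rng.normal(0.0, noise_hz, size=n_samples)
        traces.append(
            FrequencyTrace(
                cantilever_index=j,
                times=grid.copy(),
                frequencies=freq,
                calibration=config.calibration,
            )
        )

    # collection log: one record per release event (a co-released pair is one
    # trigger and one well)
    records = []
    well_counter = 0
    i = 0
    while i < n:
        well_counter += 1
        well = f"W{well_counter:04d}"
        members = [cells[i]]
        flags = []
        if co_release_with_next[i]:
            members.append(cells[i + 1])
            flags.append("co_release")
        for m in members:
            m.well_id = well
            if m.cell_id in overlap_cells:
                flags.append("overlap")
        release_time = float(transit_times[i, -1])
        records.append((release_time, well, ";".join(sorted(set(flags)))))
        i += len(members)
    if config.peak_loss_rate > 0 and lost.any():
        # annotate affected wells
        lost_ids = {cells[i].cell_id for i in np.nonzero(lost.any(axis=1))[0]}
        records = [
            (t, w, ";".join(sorted(set(filter(None, f.split(";"))) | {"peak_lost"}))
             if any(c.well_id == w and c.cell_id in lost_ids for c in cells) else f)
            for t, w, f in records
        ]
    log = CollectionLog.from_records(records)
    return traces, log


def well_expression(matrix: ExpressionMatrix, cells: Sequence[SimCell]) -> ExpressionMatrix:
    """Re-index a per-cell counts matrix by collection well.

    Cells sharing a well (co-release) contribute the *sum* of their counts,
    which is what a sequenced doublet well would yield. Cells routed to
    ``"waste"`` are dropped.
    """
    by_well: dict[str, np.ndarray] = {}
    for cell in cells:
        if cell.well_id == "waste":
            continue
        col = matrix.values[cell.cell_id].to_numpy()
        by_well[cell.well_id] = by_well.get(cell.well_id, 0) + col
    values = pd.DataFrame(by_well, index=matrix.values.index)
    return ExpressionMatrix(values=values, layer=matrix.layer)


def ground_truth_frame(cells: Sequence[SimCell], log: CollectionLog | None = None) -> pd.DataFrame:
    """Tabulate per-cell ground truth, keyed by cell_id."""
    co_wells: set[str] = set()
    if log is not None:
        co_wells = {
            r.well_id for r in log.records if "co_release" in r.flags
        }
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "well_id": c.well_id,
                "phase_position": c.phase_position,
                "true_mass": c.true_mass,
                "true_mar": c.true_mar,
                "true_growth_efficiency": c.true_mar / c.true_mass,
                "entry_time": c.entry_time,
                "is_doublet": c.well_id in co_wells,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")
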