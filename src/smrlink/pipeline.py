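"""End-to-end convenience: simulated run -> linked statistics.

Chains the full workflow on synthetic data: population -> device traces and
collection log -> peak detection -> trajectory matching and MAR fitting ->
well linking -> QC / ln(TPM+1) -> per-well covariate table. Used by the
command-line interface, the examples and the acceptance script; each stage
remains individually accessible through its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import linking, qc, smr, synthdata

__all__ = ["LinkedRun", "run_synthetic_pipeline"]


@dataclass
class LinkedRun:
    """All artifacts of one simulated linked experiment."""

    config: synthdata.SimConfig
    cells: list
    traces: list
    log: linking.CollectionLog
    trajectories: list
    linked: list
    exclusions: pd.DataFrame
    matrix: qc.ExpressionMatrix  # logTPM, QC-filtered, linked wells only
    covariates: pd.DataFrame  # well_id-indexed mass / mar / growth_efficiency
    panels: dict
    gene_truth: pd.DataFrame  # per-gene panel membership / expected sign
    cell_truth: pd.DataFrame  # per-cell ground truth keyed by cell_id

    @property
    def mass(self) -> np.ndarray:
        return self.covariates["mass"].to_numpy()

    @property
    def growth_efficiency(self) -> np.ndarray:
        return self.covariates["growth_efficiency"].to_numpy()


def run_synthetic_pipeline(
    config: synthdata.SimConfig,
    detect_threshold: float | None = None,
    complexity_threshold: int = 0,
    gene_min_fraction: float = 0.05,
) -> LinkedRun:
    """Run the whole simulated experiment and return every artifact.

    ``detect_threshold`` defaults to half the smallest plausible peak depth
    (a quarter of the mean birth mass in Hz). ``complexity_threshold``
    defaults to 0 because synthetic cells detect most genes; pass the
    dataset profiles from :mod:`smrlink.qc` for realistic filtering.
    """
    cells = synthdata.simulate_population(config)
    traces, log = synthdata.simulate_device_run(cells, config)
    counts_by_cell, panels, gene_truth = synthdata.simulate_expression(cells, config)
    counts = synthdata.well_expression(counts_by_cell, cells)

    if detect_threshold is None:
        detect_threshold = 0.25 * config.birth_mass_mean / config.calibration
    peaks = [smr.detect_peaks(t, threshold=detect_threshold) for t in traces]
    trajectories = smr.match_trajectories(
        peaks,
        expected_transit=config.transit_time_mean,
        tolerance=max(4.0 * config.transit_time_sd, 3.0) + config.peak_width,
    )
    for traj in trajectories:
        if len(traj.peaks) >= 2:
            smr.fit_mar(traj)
        else:
            traj.qc_flags.add("too_few_points")

    linked, exclusions = linking.link(trajectories, log, counts)

    wells = [lc.well_id for lc in linked]
    sub = qc.ExpressionMatrix(values=counts.values.loc[:, wells], layer="counts")
    filtered, _ = qc.filter_cells(sub, complexity_threshold)
    filtered = qc.filter_genes(filtered, gene_min_fraction)
    logtpm = qc.log_transform(qc.to_tpm(filtered))

    keep_wells = list(logtpm.values.columns)
    keep = {lc.well_id: lc for lc in linked}
    covariates = linking.linked_table([keep[w] for w in keep_wells]).set_index("well_id")

    cell_truth = synthdata.ground_truth_frame(cells, log)
    return LinkedRun(
        config=config,
        cells=cells,
        traces=traces,
        log=log,
        trajectories=trajectories,
        linked=linked,
        exclusions=exclusions,
        matrix=logtpm,
        covariates=covariates,
        panels=panels,
        gene_truth=gene_truth,
        cell_truth=cell_truth,
    )
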