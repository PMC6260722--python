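"""Shared fixtures: small synthetic runs and the 20-seed default-condition panel."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import smrlink as sl
from smrlink.scoring import GenePanel, panel_score, preranked_enrichment
from smrlink.stats import correlate_genes, flag_significant, shuffle_null, spearman

N_PANEL_SEEDS = 20


@pytest.fixture(scope="session")
def small_config() -> sl.SimConfig:
    return sl.SimConfig(n_cells=60, n_genes=400, panel_sizes=(20, 25, 15), seed=7)


@pytest.fixture(scope="session")
def small_run(small_config) -> sl.LinkedRun:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sl.run_synthetic_pipeline(small_config)


@pytest.fixture(scope="session")
def plant_panel():
    """Per-seed summary statistics of the full pipeline at default settings.

    For each of 20 seeds: the significance-flagged ranked gene list against
    measured mass, per-gene ground truth, the G2/M panel-score correlation
    with true mass, the fitted-MAR vs final-mass correlation, and the
    preranked enrichment of the planted G2/M panel. Shared by the
    plant-recovery and sign-recovery tests so the simulations run once.
    """
    results = []
    for seed in range(N_PANEL_SEEDS):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = sl.run_synthetic_pipeline(sl.SimConfig(seed=seed))
            mass = run.covariates["mass"].to_numpy()
            ranked = correlate_genes(run.matrix, mass)
            null = shuffle_null(run.matrix, mass, n_iterations=10_000, seed=seed)
            flagged = flag_significant(ranked, null).entries

            g2m = GenePanel.from_list("G2/M", run.panels["G2/M"])
            scores = panel_score(run.matrix, g2m)
            truth_by_well = run.cell_truth.reset_index().set_index("well_id")
            true_mass = truth_by_well.loc[scores.index, "true_mass"].to_numpy()
            score_rho = spearman(scores["score"].to_numpy(), true_mass)

            clean = [t for t in run.trajectories if t.is_clean and t.mar is not None]
            mar_mass_rho = spearman(
                np.array([t.mar for t in clean]), np.array([t.final_mass for t in clean])
            )

            enrichment = preranked_enrichment(
                flag_significant(ranked, null), [g2m], p=1.0, n_perm=1000, seed=seed
            )
        results.append(
            {
                "seed": seed,
                "flagged": flagged,
                "gene_truth": run.gene_truth.reindex(flagged.index),
                "null": null,
                "score_rho": score_rho,
                "mar_mass_rho": mar_mass_rho,
                "enrichment": enrichment,
                "n_cells": run.matrix.shape[1],
            }
        )
    return results
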