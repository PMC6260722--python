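"""Diagnostic plots for linked biophysical / expression data."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_mass_vs_mar", "plot_score_vs_mass"]


def plot_mass_vs_mar(covariates: pd.DataFrame, ax=None):
    """Scatter of MAR (pg/h) against buoyant mass (pg) across cells."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(covariates["mass"], covariates["mar"], s=12, alpha=0.7)
    ax.set_xlabel("buoyant mass (pg)")
    ax.set_ylabel("MAR (pg/h)")
    return ax


def plot_score_vs_mass(scores: pd.DataFrame, covariates: pd.DataFrame, ax=None):
    """Panel score against buoyant mass for the cells common to both."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    common = scores.index.intersection(covariates.index)
    ax.scatter(covariates.loc[common, "mass"], scores.loc[common, "score"], s=12, alpha=0.7)
    ax.set_xlabel("buoyant mass (pg)")
    ax.set_ylabel(f"{scores['panel'].iloc[0]} score (mean z)")
    return ax
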