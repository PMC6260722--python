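"""Expression-matrix preprocessing: TPM, complexity and detection filters.

The analysis operates on ln(TPM+1)-transformed expression. Quality control
follows the linked-experiment workflow: cells must *exceed* a per-dataset
complexity threshold (number of detected genes: 4000 for L1210/FL5.12-like
lymphoblasts, 2000 for CD8+ T cells, 1000 for glioblastoma PDCL cells), and
genes must be detected in strictly more than 5% of the remaining cells.
Filters are applied cells-then-genes (cell QC precedes gene inclusion) and
are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InputError

__all__ = [
    "ExpressionMatrix",
    "to_tpm",
    "filter_cells",
    "filter_genes",
    "log_transform",
    "COMPLEXITY_PROFILES",
]

# per-dataset complexity thresholds (cells must detect MORE genes than this)
COMPLEXITY_PROFILES: dict[str, int] = {
    "L1210": 4000,
    "FL5.12": 4000,
    "CD8_T": 2000,
    "BT159": 1000,
}

LAYERS = ("counts", "TPM", "logTPM")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with a layer tag.

    ``values`` is a DataFrame indexed by gene identifier with one column per
    cell (well). ``layer`` records what the numbers mean: raw ``counts``,
    ``TPM`` (columns sum to 1e6), or ``logTPM`` (ln(TPM+1)). ``flags`` holds
    QC annotations such as all-zero cells found during normalization.
    """

    values: pd.DataFrame
    layer: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if (self.values.to_numpy() < 0).any():
            raise InputError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (value > 0); layer-invariant since TPM and
        logTPM preserve the zero pattern of counts."""
        return self.values > 0


def to_tpm(matrix: ExpressionMatrix, gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    """Scale each cell to transcripts-per-million.

    With ``gene_lengths`` (kb or bp; only relative lengths matter) counts are
    length-normalized first, giving true TPM; without lengths this is
    CPM-as-TPM, appropriate for the synthetic generator whose counts carry no
    length bias. All-zero cells are left all-zero and recorded in
    ``flags["all_zero_cells"]``.
    """
    if matrix.layer != "counts":
        raise InputError(f"to_tpm expects a counts layer, got {matrix.layer!r}")
    values = matrix.values.astype(float)
    if gene_lengths is not None:
        lengths = gene_lengths.reindex(values.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()[:5]
            raise InputError(f"gene_lengths missing for genes {missing} ...")
        values = values.div(lengths, axis=0)
    colsums = values.sum(axis=0)
    zero_cols = colsums.index[colsums == 0].tolist()
    if zero_cols:
        warnings.warn(f"{len(zero_cols)} all-zero cell(s) left unscaled", stacklevel=2)
    safe = colsums.replace(0, 1.0)
    tpm = values.div(safe, axis=1) * 1.0e6
    return ExpressionMatrix(values=tpm, layer="TPM", flags={**matrix.flags, "all_zero_cells": zero_cols})


def filter_cells(
    matrix: ExpressionMatrix, complexity_threshold: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove cells that do not *exceed* the complexity threshold.

    A cell is kept iff its number of detected genes is strictly greater than
    ``complexity_threshold`` (a cell detecting exactly the threshold count is
    removed). Returns the filtered matrix and a report of removed wells with
    their gene counts.
    """
    if complexity_threshold < 0:
        raise InputError("complexity_threshold must be >= 0")
    n_detected = matrix.detected().sum(axis=0)
    keep = n_detected > complexity_threshold
    report = pd.DataFrame(
        {"well_id": n_detected.index[~keep], "genes_detected": n_detected[~keep].to_numpy()}
    ).reset_index(drop=True)
    out = ExpressionMatrix(
        values=matrix.values.loc[:, keep], layer=matrix.layer, flags=dict(matrix.flags)
    )
    return out, report


def filter_genes(matrix: ExpressionMatrix, min_fraction: float = 0.05) -> ExpressionMatrix:
    """Keep genes detected in strictly more than ``min_fraction`` of cells."""
    if not (0.0 <= min_fraction < 1.0):
        raise InputError("min_fraction must be in [0, 1)")
    frac = matrix.detected().mean(axis=1)
    keep = frac > min_fraction
    return ExpressionMatrix(
        values=matrix.values.loc[keep], layer=matrix.layer, flags=dict(matrix.flags)
    )


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ln(TPM + 1)."""
    if matrix.layer != "TPM":
        raise InputError(f"log_transform expects a TPM layer, got {matrix.layer!r}")
    return ExpressionMatrix(
        values=np.log1p(matrix.values), layer="logTPM", flags=dict(matrix.flags)
    )
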