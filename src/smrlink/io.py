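"""Readers and writers for the package's plain-text interchange formats.

Traces are two-column TSV (time_s, frequency_hz) per cantilever; collection
logs and trajectory tables are CSV; expression matrices are dense TSV or
MatrixMarket MTX with genes.tsv / barcodes.tsv sidecars; gene sets are GMT;
simulation configs are YAML.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from ._exceptions import InputError
from .linking import CollectionLog
from .qc import ExpressionMatrix
from .scoring import GenePanel
from .smr import FrequencyTrace

__all__ = [
    "write_trace_tsv",
    "read_trace_tsv",
    "write_collection_log",
    "read_collection_log",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_expression_mtx",
    "read_expression_mtx",
    "read_gmt",
    "write_gmt",
    "load_sim_config",
    "save_sim_config",
]


def write_trace_tsv(trace: FrequencyTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "frequency_hz": trace.frequencies})
    with open(path, "w") as fh:
        fh.write(f"# cantilever_index={trace.cantilever_index}\n")
        fh.write(f"# calibration_pg_per_hz={trace.calibration}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trace_tsv(path) -> FrequencyTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    if not {"time_s", "frequency_hz"} <= set(df.columns):
        raise InputError(f"{path}: expected time_s and frequency_hz columns")
    return FrequencyTrace(
        cantilever_index=int(meta.get("cantilever_index", 0)),
        times=df["time_s"].to_numpy(),
        frequencies=df["frequency_hz"].to_numpy(),
        calibration=float(meta.get("calibration_pg_per_hz", 1.0)),
    )


def write_collection_log(log: CollectionLog, path) -> None:
    log.to_frame().to_csv(path, index=False)


def read_collection_log(path) -> CollectionLog:
    df = pd.read_csv(path, keep_default_na=False)
    return CollectionLog.from_records(
        list(zip(df["release_time"], df["well_id"], df.get("flags", [""] * len(df))))
    )


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, layer: str = "counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(values=df, layer=layer)


def write_expression_mtx(matrix: ExpressionMatrix, directory) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = csr_matrix(matrix.values.to_numpy())
    mmwrite(os.fspath(directory / "matrix.mtx"), sparse)
    pd.Series(matrix.values.index).to_csv(
        directory / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(matrix.values.columns).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_expression_mtx(directory, layer: str = "counts") -> ExpressionMatrix:
    directory = Path(directory)
    sparse = mmread(os.fspath(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    values = pd.DataFrame(np.asarray(sparse.todense()), index=genes, columns=cells)
    return ExpressionMatrix(values=values, layer=layer)


def read_gmt(path) -> list[GenePanel]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    panels = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{line_no}: GMT line needs name, description, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            panels.append(GenePanel.from_list(name, genes))
    return panels


def write_gmt(panels: list[GenePanel], path, description: str = "smrlink") -> None:
    with open(path, "w") as fh:
        for panel in panels:
            fh.write("\t".join([panel.name, description, *panel.genes]) + "\n")


def _plain(value):
    """Coerce numpy scalars/sequences to YAML-representable builtins."""
    if isinstance(value, (tuple, list)):
        return [_plain(v) for v in value]
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    return value


def save_sim_config(config, path) -> None:
    from dataclasses import asdict

    data = {k: _plain(v) for k, v in asdict(config).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_sim_config(path):
    from .synthdata import SimConfig

    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("panel_sizes", "libsize_lognorm_params"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(**data)
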