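"""Reading and writing the three study tables as TSV.

The on-disk contract: a sample table (one row per injection), a compound
table (one row per reconstructed compound) and an abundance matrix with
sample_id rows and compound_id columns; missing measurements are empty cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceMatrix,
    SAMPLE_COLUMNS,
    validate_compound_table,
    validate_sample_table,
)
from .exceptions import DataError

_FLOAT_FMT = "%.10g"


def read_tables(sample_path, compound_path, matrix_path):
    """Read and cross-validate the sample/compound/matrix triple.

    Returns ``(samples, compounds, matrix)``; the matrix axes are reordered
    to match the tables exactly. Raises :class:`DataError` naming the first
    offending identifier on any mismatch.
    """
    samples = pd.read_csv(sample_path, sep="\t", dtype={"sample_id": str, "batch": str})
    compounds = pd.read_csv(compound_path, sep="\t", dtype={"compound_id": str})
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = "sample_id"
    raw.columns.name = "compound_id"

    for col in ("variety", "cultivation"):
        samples[col] = samples[col].fillna("")
    for col in ("harvest_week_index", "calendar_week", "replicate"):
        samples[col] = samples[col].astype("Int64")
    samples["is_qc"] = samples["is_qc"].astype(bool)
    compounds["annotation"] = compounds["annotation"].fillna("")
    compounds["flavour_flag"] = compounds["flavour_flag"].astype(bool)
    validate_sample_table(samples)
    validate_compound_table(compounds)

    unmatched_cols = [c for c in raw.columns if c not in set(compounds["compound_id"])]
    if unmatched_cols:
        raise DataError(f"matrix column {unmatched_cols[0]!r} absent from compound table")
    unmatched_rows = [r for r in raw.index if r not in set(samples["sample_id"])]
    if unmatched_rows:
        raise DataError(f"matrix row {unmatched_rows[0]!r} absent from sample table")
    missing_samples = [s for s in samples["sample_id"] if s not in raw.index]
    if missing_samples:
        raise DataError(f"sample {missing_samples[0]!r} has no matrix row")
    missing_compounds = [c for c in compounds["compound_id"] if c not in raw.columns]
    if missing_compounds:
        raise DataError(f"compound {missing_compounds[0]!r} has no matrix column")

    raw = raw.loc[samples["sample_id"].tolist(), compounds["compound_id"].tolist()]
    vals = raw.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        bad = raw.columns[(raw < 0).any(axis=0)][0]
        raise DataError(f"negative raw intensity in compound {bad!r}")
    matrix = AbundanceMatrix(raw, scale="raw")
    return samples, compounds, matrix


def write_tables(out_dir, samples=None, compounds=None, matrix=None, prefix=""):
    """Write any of the three tables to ``out_dir`` as TSV; returns the paths.

    Float cells use a 10-significant-digit round-trippable format so that
    repeated runs with the same seed produce bit-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if samples is not None:
        p = out_dir / f"{prefix}samples.tsv"
        samples.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths["samples"] = p
    if compounds is not None:
        p = out_dir / f"{prefix}compounds.tsv"
        compounds.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        paths["compounds"] = p
    if matrix is not None:
        name = f"{prefix}matrix_{matrix.scale}.tsv"
        p = out_dir / name
        matrix.data.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        paths["matrix"] = p
    return paths


def write_frame(path, frame: pd.DataFrame, index: bool = False) -> Path:
    """TSV writer with the package-wide deterministic float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path
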