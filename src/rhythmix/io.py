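"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and flag matrices are TSV (rows = transcript IDs,
columns = sample IDs); sample metadata and melatonin series are CSV/TSV;
results tables are TSV with floats at 10 significant digits; provenance
records are JSON. Readers validate duplicate IDs, ragged rows and
non-numeric cells with line numbers, and record NA cells as flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, MelatoninPanel

__all__ = [
    "load_gem", "write_gem", "load_meta", "write_meta",
    "load_melatonin", "write_melatonin", "write_table", "write_json",
]

FLOAT_FMT = "%.10g"


def _check_rectangular(path: Path, sep: str = "\t"):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            ncol = line.rstrip("\n").count(sep) + 1
            if ncol != width:
                raise ValueError(
                    f"{path}: line {lineno} has {ncol} fields, expected {width}"
                )


def load_gem(path) -> ExpressionMatrix:
    """Load a TSV expression matrix; NA cells become per-cell flags."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate transcript IDs {dup[:5]}")
    bad_cells = []
    for j, c in enumerate(df.columns):
        col = pd.to_numeric(df[c], errors="coerce")
        newly_bad = col.isna() & df[c].notna()
        if newly_bad.any():
            for i in np.flatnonzero(newly_bad.to_numpy())[:5]:
                bad_cells.append((df.index[i], c, int(i + 2)))
        df[c] = col
    if bad_cells:
        raise ValueError(f"{path}: non-numeric cells (id, sample, line): {bad_cells}")
    flags = df.isna()
    values = df.fillna(0.0) if flags.to_numpy().any() else df
    return ExpressionMatrix(values.astype(float), flags)


def write_gem(matrix: ExpressionMatrix, path, flags_path=None):
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                         index_label="transcript_id")
    if flags_path is not None:
        matrix.flags.astype(int).to_csv(flags_path, sep="\t",
                                        index_label="transcript_id")


def load_meta(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_meta(meta: pd.DataFrame, path):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def load_melatonin(path) -> MelatoninPanel:
    df = pd.read_csv(path)
    need = {"participant", "session", "clock_time", "concentration"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: melatonin panel lacks columns {sorted(missing)}")
    return MelatoninPanel(df)


def write_melatonin(panel: MelatoninPanel, path, truth_path=None):
    panel.samples.to_csv(path, index=False, float_format=FLOAT_FMT)
    if truth_path is not None and panel.truth is not None:
        panel.truth.to_csv(truth_path, index=False, float_format=FLOAT_FMT)


def write_table(df: pd.DataFrame, path, index: bool = False):
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
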