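"""Core in-memory containers shared across the pipeline.

Expression data live in a :class:`ExpressionMatrix` — a log2 intensity table
(transcripts × samples) with an aligned boolean flag matrix marking
per-cell QC failures. Sample annotations (participant, sampling session,
clock time, group, leg, per-sample QC metrics) travel as a plain
:class:`pandas.DataFrame` with well-known column names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: canonical SampleMeta columns
META_COLUMNS = ["sample_id", "participant", "session", "clock_time", "group", "leg"]
#: per-sample QC metric columns (may ride along in SampleMeta)
QC_COLUMNS = ["median_cv_pct", "flagged_pct", "rin"]


@dataclass
class ExpressionMatrix:
    """Log2 expression values (transcripts × samples) plus per-cell QC flags."""

    values: pd.DataFrame
    flags: Optional[pd.DataFrame] = None

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript IDs: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dup[:5]}")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=v.index, columns=v.columns, dtype=bool
            )
        else:
            if not (
                self.flags.index.equals(v.index) and self.flags.columns.equals(v.columns)
            ):
                raise ValueError("flag matrix must be aligned with the value matrix")
            self.flags = self.flags.astype(bool)
        unflagged = ~self.flags.to_numpy()
        vals = v.to_numpy(dtype=float)
        if not np.isfinite(vals[unflagged]).all():
            bad = np.argwhere(~np.isfinite(vals) & unflagged)
            cells = [(v.index[i], v.columns[j]) for i, j in bad[:5]]
            raise ValueError(f"non-finite unflagged values at cells {cells}")

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, transcripts=None, samples=None) -> "ExpressionMatrix":
        v, f = self.values, self.flags
        if transcripts is not None:
            v, f = v.loc[transcripts], f.loc[transcripts]
        if samples is not None:
            v, f = v[samples], f[samples]
        return ExpressionMatrix(v.copy(), f.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.flags.equals(other.flags)
        )


@dataclass
class MelatoninPanel:
    """Hourly salivary melatonin series per participant × session.

    ``samples`` is long-format (participant, session, clock_time,
    concentration); ``truth`` (present for synthetic panels) carries the
    generative offset per participant × session.
    """

    samples: pd.DataFrame
    truth: Optional[pd.DataFrame] = None

    def series(self, participant, session) -> pd.DataFrame:
        m = (self.samples["participant"] == participant) & (
            self.samples["session"] == session
        )
        return self.samples[m].sort_values("clock_time")


def validate_meta(meta: pd.DataFrame, require_qc: bool = False) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns {missing}")
    if require_qc:
        missing = [c for c in QC_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"sample metadata lacks QC columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    return meta
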