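"""Sample QC filtering, quantile normalization, probe retention and
centering transforms for log2 expression matrices.

The QC rules mirror a standard two-color-array workflow: samples are kept
when the median replicate-probe coefficient of variation is below 10%,
fewer than 35% of probes are flagged by any QC variable, and RIN exceeds
6 (all strict inequalities); transcripts are kept when flagged in fewer
than 20% of the retained samples. Batch adjustment here is per-transcript
batch-mean alignment — a deliberately simple, fully specified stand-in for
empirical-Bayes batch correction — and is applied only to the matrix used
for component analysis; rhythm and differential-expression models run on
quantile-normalized data without it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "sample_qc_filter", "quantile_normalize", "probe_filter",
    "batch_adjust", "participant_center",
]

log = logging.getLogger(__name__)

CV_MAX = 10.0        # median CV of replicated non-control probes, percent
FLAGGED_MAX = 35.0   # percent of probes flagged by any QC variable
RIN_MIN = 6.0


def sample_qc_filter(matrix: ExpressionMatrix, qc: pd.DataFrame):
    """Retain samples passing all three QC rules.

    ``qc`` is indexed by sample_id (or carries a ``sample_id`` column) with
    ``median_cv_pct``, ``flagged_pct`` and ``rin``. Samples without a QC
    row are excluded and logged, never silently kept. Returns
    ``(retained_ids, report)`` with per-criterion exclusion counts.
    """
    if "sample_id" in qc.columns:
        qc = qc.set_index("sample_id")
    retained = []
    report = {"cv": 0, "flagged": 0, "rin": 0, "missing_qc": 0,
              "n_in": len(matrix.samples)}
    for s in matrix.samples:
        if s not in qc.index:
            report["missing_qc"] += 1
            log.warning("sample %s has no QC metrics; excluded", s)
            continue
        row = qc.loc[s]
        ok = True
        if not row["median_cv_pct"] < CV_MAX:
            report["cv"] += 1
            ok = False
        if not row["flagged_pct"] < FLAGGED_MAX:
            report["flagged"] += 1
            ok = False
        if not row["rin"] > RIN_MIN:
            report["rin"] += 1
            ok = False
        if ok:
            retained.append(s)
    report["n_retained"] = len(retained)
    return retained, report


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean quantile distribution.

    After normalization each column's sorted values equal the mean of the
    per-column sorted values; ties within a column receive the mean of the
    quantile values they span.
    """
    V = matrix.values.to_numpy(dtype=float)
    n, m = V.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(V).all():
        bad = np.argwhere(~np.isfinite(V))
        cells = [(matrix.values.index[i], matrix.values.columns[j])
                 for i, j in bad[:5]]
        raise ValueError(f"non-finite values at cells {cells}")
    ref = np.sort(V, axis=0).mean(axis=1)
    out = np.empty_like(V)
    for j in range(m):
        col = V[:, j]
        order = np.argsort(col, kind="stable")
        ref_by_pos = np.empty(n)
        ref_by_pos[order] = ref
        # ties receive the mean of the reference quantiles they span
        _, inv, cnt = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.zeros(cnt.size)
        np.add.at(sums, inv, ref_by_pos)
        out[:, j] = sums[inv] / cnt[inv]
    vdf = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(vdf, matrix.flags.copy())


def probe_filter(matrix: ExpressionMatrix, max_flag_frac: float = 0.20):
    """Transcripts flagged in fewer than ``max_flag_frac`` of samples (strict)."""
    frac = matrix.flags.to_numpy().mean(axis=1)
    keep = frac < max_flag_frac
    return list(matrix.transcripts[keep])


def batch_adjust(matrix: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Shift each batch's per-transcript mean to the transcript grand mean."""
    batches = pd.Series(np.asarray(batches), index=matrix.samples)
    V = matrix.values
    grand = V.mean(axis=1)
    out = V.copy()
    for b, cols in batches.groupby(batches).groups.items():
        if len(cols) == 1:
            log.warning("batch %r has a single sample; mean shift only", b)
        shift = grand - V[cols].mean(axis=1)
        out[cols] = V[cols].add(shift, axis=0)
    return ExpressionMatrix(out, matrix.flags.copy())


def participant_center(matrix: ExpressionMatrix, meta: pd.DataFrame) -> ExpressionMatrix:
    """Zero-center each transcript within each participant's samples."""
    mapping = meta.set_index("sample_id")["participant"]
    unmapped = [s for s in matrix.samples if s not in mapping.index]
    if unmapped:
        raise ValueError(f"samples without participant mapping: {unmapped[:5]}")
    V = matrix.values
    out = V.copy()
    parts = pd.Series([mapping[s] for s in V.columns], index=V.columns)
    for _, cols in parts.groupby(parts).groups.items():
        out[cols] = V[cols].sub(V[cols].mean(axis=1), axis=0)
    return ExpressionMatrix(out, matrix.flags.copy())
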