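"""Participant-centered PCA with varimax-rotated components.

The expression matrix is zero-centered within participant (individual
baselines removed), samples are treated as observations and transcripts as
variables, and a covariance PCA (no variable scaling) is computed. The
first ``k`` (default 4) components are varimax-rotated — the orthonormal
rotation matrix obtained from the loadings is applied to both loadings and
scores, yielding rotated principal component (RPC) scores whose session /
time structure is then modelled with the shared mixed-ANOVA and cosinor
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .anova import MixedAnova, mixed_anova
from .cosinor import BootstrapSettings, fit_session

__all__ = ["PcaResult", "pca", "varimax_rotate", "score_anova",
           "score_rhythm", "top_loading_transcripts"]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # sample-covariance eigenvalues
    pct_variance: np.ndarray
    scores: pd.DataFrame             # samples × components
    loadings: pd.DataFrame           # transcripts × components
    k: int = 4
    rotation: np.ndarray | None = None
    rotated_loadings: pd.DataFrame | None = None
    rotated_scores: pd.DataFrame | None = None
    rotated_pct_variance: np.ndarray | None = None


def pca(centered: pd.DataFrame) -> PcaResult:
    """Covariance PCA of a participant-centered matrix (transcripts × samples).

    Columns are observations. The component sign is fixed by making the
    largest-magnitude loading of each component positive.
    """
    if centered.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = centered.to_numpy(dtype=float).T          # samples × transcripts
    X = X - X.mean(axis=0, keepdims=True)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = U * s
    loadings = Vt.T
    # sign convention
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{j + 1}" for j in range(len(eig))]
    return PcaResult(
        eigenvalues=eig,
        pct_variance=100.0 * eig / eig.sum(),
        scores=pd.DataFrame(scores, index=centered.columns, columns=names),
        loadings=pd.DataFrame(loadings, index=centered.index, columns=names),
    )


def varimax_rotate(result: PcaResult, k: int = 4,
                   normalize: bool = True) -> PcaResult:
    """Varimax-rotate the first ``k`` components in place (returns result).

    The rotation matrix is found on (optionally Kaiser row-normalized)
    loadings, then applied to the *raw* loadings and to the scores.
    """
    if k > result.loadings.shape[1]:
        raise ValueError("k exceeds the number of components")
    L = result.loadings.iloc[:, :k].to_numpy()
    if k == 1:
        R = np.eye(1)
    else:
        Lw = L
        if normalize:
            h = np.sqrt((L**2).sum(axis=1))
            h = np.where(h > 0, h, 1.0)
            Lw = L / h[:, None]
        _, R = rotate_factors(Lw, "varimax")
    Lrot = L @ R
    names = [f"RPC{j + 1}" for j in range(k)]
    S = result.scores.iloc[:, :k].to_numpy() @ R
    var_rot = S.var(axis=0, ddof=1)
    total = result.eigenvalues.sum()
    result.k = k
    result.rotation = R
    result.rotated_loadings = pd.DataFrame(
        Lrot, index=result.loadings.index, columns=names
    )
    result.rotated_scores = pd.DataFrame(
        S, index=result.scores.index, columns=names
    )
    result.rotated_pct_variance = 100.0 * var_rot / total
    return result


def score_anova(scores: pd.DataFrame, meta: pd.DataFrame,
                levels: dict | None = None) -> dict[str, MixedAnova]:
    """Mixed ANOVA 'score ~ session + time + session:time + (1|participant)'
    for each component column of ``scores`` (indexed by sample_id)."""
    from .diffexpr import _with_time_point

    meta = _with_time_point(meta).set_index("sample_id")
    out = {}
    for comp in scores.columns:
        d = meta.loc[scores.index].copy()
        d["_score"] = scores[comp].to_numpy(dtype=float)
        out[comp] = mixed_anova(
            d, "_score", ["session", "time_point"], "participant",
            interactions=[("session", "time_point")], levels=levels,
        )
    return out


def score_rhythm(
    scores: pd.DataFrame,
    meta_aligned: pd.DataFrame,
    tau: float = 24.0,
    bootstrap: BootstrapSettings | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-session random-slopes cosinor fits of each component's scores.

    Returns ``{"results": per session × component table,
    "per_participant": participant-level amplitude/acrophase estimates}``
    suitable for the session-comparison operations.
    """
    gem_like = scores.T                            # components × samples
    res_rows, part_rows = [], []
    for sess, grp in meta_aligned.groupby("session", sort=False):
        res, per_part = fit_session(
            gem_like[grp["sample_id"]], grp, tau=tau, variant="slopes",
            bootstrap=bootstrap,
        )
        res = res.reset_index().rename(columns={"transcript_id": "component"})
        res.insert(0, "session", sess)
        per_part = per_part.rename(columns={"transcript_id": "component"})
        per_part.insert(0, "session", sess)
        res_rows.append(res)
        part_rows.append(per_part)
    return {
        "results": pd.concat(res_rows, ignore_index=True),
        "per_participant": pd.concat(part_rows, ignore_index=True),
    }


def top_loading_transcripts(rotated_loadings: pd.DataFrame, n: int) -> dict:
    """Top-|loading|, top-positive and top-negative transcripts per component.

    Ties break deterministically by transcript ID.
    """
    if n > len(rotated_loadings):
        raise ValueError("n exceeds the transcript count")
    out = {}
    for comp in rotated_loadings.columns:
        v = rotated_loadings[comp]
        df = pd.DataFrame({"id": v.index, "loading": v.to_numpy()})
        df["abs"] = df["loading"].abs()
        top_abs = df.sort_values(["abs", "id"], ascending=[False, True])["id"]
        top_pos = df.sort_values(["loading", "id"], ascending=[False, True])["id"]
        top_neg = df.sort_values(["loading", "id"], ascending=[True, True])["id"]
        out[comp] = {
            "top_abs": top_abs.head(n).tolist(),
            "top_positive": top_pos.head(n).tolist(),
            "top_negative": top_neg.head(n).tolist(),
        }
    return out
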