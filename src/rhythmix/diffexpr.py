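"""Repeated-measures differential expression across sessions and time points.

Each transcript's log2 expression is modelled as
``expression ~ session + time + group + leg + session:time + (1|participant)``
with Type-III-style F-tests (Satterthwaite df). Main-effect p-values are
BH-corrected across transcripts; pairwise session contrasts of LS means are
BH-corrected within each transcript. A transcript is called
differentially expressed in a session pair when both the session
main-effect FDR and that pair's contrast FDR fall below 0.01, with the
direction given by the sign of the LS-mean difference (a log2 fold change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .anova import MixedAnova, mixed_anova
from .designs import build_design
from .lmm import MixedModel

__all__ = ["DiffExprResult", "fit_de_model", "fit_de_batch", "ls_means",
           "de_classify", "volcano_summary"]

DE_ALPHA = 0.01
DE_FACTORS = ["session", "time_point", "group", "leg"]
DE_INTERACTIONS = [("session", "time_point")]


@dataclass
class DiffExprResult:
    """Per-transcript ANOVA table, session LS means and pairwise contrasts."""

    anova: pd.DataFrame          # index transcript; p_/fdr_ per term
    lsmeans: pd.DataFrame        # long: transcript, session, lsmean, se
    contrasts: pd.DataFrame      # long: transcript, pair, estimate, p, fdr
    alpha: float = DE_ALPHA
    calls: pd.DataFrame | None = None


def _with_time_point(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    if "time_point" not in meta.columns:
        # categorical clock-time label, e.g. 15.0 -> "15:00"
        meta["time_point"] = meta["clock_time"].map(
            lambda h: f"{int(h) % 24:02d}:{int(round((h % 1) * 60)):02d}"
        )
    return meta


def fit_de_model(y, meta: pd.DataFrame, levels: dict | None = None) -> MixedAnova:
    """Single-response version (used for component scores and spot checks)."""
    meta = _with_time_point(meta)
    d = meta.copy()
    d["_y"] = np.asarray(y, dtype=float)
    return mixed_anova(d, "_y", DE_FACTORS, "participant",
                       interactions=DE_INTERACTIONS, levels=levels)


def ls_means(anova_fit: MixedAnova, factor: str) -> pd.DataFrame:
    """Least-squares means ± SE for one factor of a fitted model."""
    return anova_fit.ls_means(factor)


def fit_de_batch(
    gem_values: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = DE_ALPHA,
    levels: dict | None = None,
) -> DiffExprResult:
    """Fit the differential-expression model to every transcript.

    All transcripts share one fixed-effect design, so the REML fits, term
    F-tests and contrast inference run as a single vectorized batch.
    """
    meta = _with_time_point(meta)
    sample_ids = meta["sample_id"].to_numpy()
    Y = gem_values[sample_ids].to_numpy(dtype=float).T
    design = build_design(meta, DE_FACTORS, interactions=DE_INTERACTIONS,
                          levels=levels)
    groups = meta["participant"].to_numpy()
    model = MixedModel(Y, design.X, groups)
    fit = model.fit(df_method="wald")  # coefficient-level t df unused here
    W = model._vcov_varpar(fit.theta, fit.sigma2, np.arange(fit.n_cols))

    tbl = {"transcript_id": gem_values.index}
    for term in design.terms:
        L = design.contrast_block(term)
        F, num_df, den_df, p = model.ftest(fit, L, W=W)
        tbl[f"F_{term}"] = F
        tbl[f"p_{term}"] = p
        ok = np.isfinite(p)
        fdr = np.full_like(p, np.nan)
        if ok.any():
            fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
        tbl[f"fdr_{term}"] = fdr
    anova = pd.DataFrame(tbl).set_index("transcript_id")

    # session LS means per transcript
    cells, rows = design.lsmean_rows("session")
    lsm = rows @ fit.beta.T                       # (S, T)
    lsm_se = np.sqrt(
        np.einsum("ip,tpq,iq->it", rows, fit.cov_beta, rows)
    )                                             # (S, T)
    lsmeans = pd.DataFrame({
        "transcript_id": np.repeat(gem_values.index, len(cells)),
        "session": np.tile(cells["session"].to_numpy(), len(gem_values)),
        "lsmean": lsm.T.ravel(),
        "se": lsm_se.T.ravel(),
    })

    # pairwise session contrasts, BH within transcript
    sess = cells["session"].tolist()
    cons, pairs = [], []
    for i in range(len(sess)):
        for j in range(i + 1, len(sess)):
            cons.append(rows[i] - rows[j])
            pairs.append((sess[i], sess[j]))
    cons = np.asarray(cons)                       # (k, p)
    est = cons @ fit.beta.T                       # (k, T)
    se = np.sqrt(np.einsum("kp,tpq,kq->kt", cons, fit.cov_beta, cons))
    df = model.contrast_df(fit.theta, fit.sigma2, cons, W=W).T  # (k, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    fdr = np.empty_like(pval)
    for t in range(pval.shape[1]):               # BH across the 15 contrasts
        fdr[:, t] = multipletests(pval[:, t], method="fdr_bh")[1]
    contrasts = pd.DataFrame({
        "transcript_id": np.repeat(gem_values.index, len(pairs)),
        "session_a": np.tile([a for a, _ in pairs], len(gem_values)),
        "session_b": np.tile([b for _, b in pairs], len(gem_values)),
        "estimate": est.T.ravel(),
        "se": se.T.ravel(),
        "p": pval.T.ravel(),
        "fdr": fdr.T.ravel(),
    })
    res = DiffExprResult(anova=anova, lsmeans=lsmeans, contrasts=contrasts,
                         alpha=alpha)
    res.calls = de_classify(res)
    return res


def de_classify(results: DiffExprResult) -> pd.DataFrame:
    """Up/down/ns call per transcript × session pair under the dual BH rule."""
    alpha = results.alpha
    main_fdr = results.anova["fdr_session"]
    c = results.contrasts.merge(
        main_fdr.rename("main_fdr"), left_on="transcript_id", right_index=True
    )
    sig = (c["main_fdr"] < alpha) & (c["fdr"] < alpha)
    call = np.where(~sig, "ns", np.where(c["estimate"] > 0, "up", "down"))
    out = c[["transcript_id", "session_a", "session_b", "estimate", "p", "fdr"]].copy()
    out["call"] = call
    return out


def volcano_summary(results: DiffExprResult, pair: tuple) -> dict:
    """Counts and the fold-change/p table for one session pair."""
    a, b = pair
    calls = results.calls if results.calls is not None else de_classify(results)
    m = (calls["session_a"] == a) & (calls["session_b"] == b)
    flipped = (calls["session_a"] == b) & (calls["session_b"] == a)
    sub = calls[m].copy()
    if not m.any() and flipped.any():
        sub = calls[flipped].copy()
        sub["estimate"] = -sub["estimate"]
        sub["call"] = sub["call"].map({"up": "down", "down": "up", "ns": "ns"})
    n_up = int((sub["call"] == "up").sum())
    n_down = int((sub["call"] == "down").sum())
    n = len(sub)
    return {
        "pair": (a, b),
        "n_up": n_up,
        "n_down": n_down,
        "pct_significant": 100.0 * (n_up + n_down) / n if n else 0.0,
        "table": sub[["transcript_id", "estimate", "p", "fdr", "call"]],
    }
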