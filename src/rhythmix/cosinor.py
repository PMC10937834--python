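"""Mixed-effects cosinor rhythmometry.

A 24-h cosinor ``y = MESOR + amp·sin(2π(t − φ)/τ)`` is linearized as
``y = mes + β1·cos(2πt/τ) + β2·sin(2πt/τ)`` and fitted per transcript and
sampling session as a linear mixed model in one of two variants:

* ``slopes`` — zero fixed intercept with participant-specific rhythm
  slopes, ``y ~ 0 + x1 + x2 + (0 + x1 + x2 | participant)``, on data
  z-scored within participant (× session);
* ``intercept`` — participant random intercepts on raw data,
  ``y ~ x1 + x2 + (1 | participant)``.

Amplitude and peak time (acrophase) derive from the fixed slopes; a
transcript is classified rhythmic in a session when the smaller of the two
Benjamini–Hochberg FDR values of β1 and β2 (corrected across transcripts
within the session) falls below 0.05. Uncertainty comes from a
participant-cluster bootstrap, with a circular standard deviation for the
acrophase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import MixedFit, MixedModel

__all__ = [
    "CosinorDesign", "BootstrapSettings", "cosinor_design", "zscore_within",
    "fit_cosinor_slopes", "fit_cosinor_intercept", "derive_rhythm_params",
    "classify_rhythmic", "bootstrap_se", "conditional_r2", "fit_session",
]

RHYTHM_FDR = 0.05


@dataclass
class CosinorDesign:
    """Linearized cosinor regressors at fixed period ``tau`` (hours)."""

    t: np.ndarray
    x1: np.ndarray           # cos(2π t / τ)
    x2: np.ndarray           # sin(2π t / τ)
    tau: float
    participants: Optional[np.ndarray] = None

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.x1, self.x2])


@dataclass
class BootstrapSettings:
    replicates: int = 200
    unit: str = "participant"    # cluster bootstrap by default
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if self.unit not in ("participant", "row"):
            raise ValueError("resampling unit must be 'participant' or 'row'")


def cosinor_design(times, tau: float = 24.0, participants=None) -> CosinorDesign:
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(times, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite sampling times")
    ang = 2.0 * np.pi * t / tau
    return CosinorDesign(
        t=t, x1=np.cos(ang), x2=np.sin(ang), tau=float(tau),
        participants=None if participants is None else np.asarray(participants),
    )


def zscore_within(Y: np.ndarray, groups, ddof: int = 1):
    """Standardize each group's series to mean 0, SD 1 (sample SD).

    Returns ``(Z, degenerate)`` where ``degenerate[g, j]`` marks
    group × column series that were constant (these become all-zero).
    ``Y`` is (n,) or (n, T); groups are row labels.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    Z = np.empty_like(Y)
    degenerate = np.zeros((len(labels), Y.shape[1]), dtype=bool)
    for g in range(len(labels)):
        m = codes == g
        if m.sum() < 2:
            raise ValueError(
                f"group {labels[g]!r} has fewer than 2 observations to z-score"
            )
        mu = Y[m].mean(axis=0)
        sd = Y[m].std(axis=0, ddof=ddof)
        const = sd <= 1e-12 * np.maximum(1.0, np.abs(mu))
        degenerate[g] = const
        sd = np.where(const, 1.0, sd)
        Z[m] = (Y[m] - mu) / sd
        Z[np.ix_(m, const)] = 0.0
    if squeeze:
        return Z[:, 0], degenerate
    return Z, degenerate


def fit_cosinor_slopes(Y, design: CosinorDesign, groups=None,
                       df_method: str = "satterthwaite") -> MixedFit:
    """Random rhythm-slopes variant (expects z-scored responses)."""
    groups = design.participants if groups is None else groups
    if groups is None:
        raise ValueError("participant labels required")
    return MixedModel(Y, design.X, groups, Z=design.X).fit(df_method=df_method)


def fit_cosinor_intercept(Y, design: CosinorDesign, groups=None,
                          df_method: str = "satterthwaite") -> MixedFit:
    """Random-intercept variant on raw (non-standardized) responses."""
    groups = design.participants if groups is None else groups
    if groups is None:
        raise ValueError("participant labels required")
    n = len(design.t)
    X = np.column_stack([np.ones(n), design.x1, design.x2])
    return MixedModel(Y, X, groups, Z=np.ones((n, 1))).fit(df_method=df_method)


def derive_rhythm_params(beta1, beta2, tau: float = 24.0):
    """Amplitude, phase and acrophase from the linearized slopes.

    ``amp = sqrt(β1² + β2²)``; ``φ = (τ/2π)·atan2(β1, β2) mod τ`` — the
    two-argument arctangent reproduces the quadrant-corrected arctangent on
    all non-degenerate quadrants and stays defined on the axes; the
    acrophase (peak time) is ``(τ − φ + τ/4) mod τ``, which equals the
    argmax over t of ``β1·cos(2πt/τ) + β2·sin(2πt/τ)``. Both slopes zero
    gives amp 0 and undefined (NaN) phase/acrophase.
    """
    b1 = np.asarray(beta1, dtype=float)
    b2 = np.asarray(beta2, dtype=float)
    amp = np.hypot(b1, b2)
    with np.errstate(invalid="ignore"):
        phi = (tau / (2.0 * np.pi)) * np.arctan2(b1, b2) % tau
        phi = np.where(phi >= tau, 0.0, phi)   # guard the float mod boundary
    acro = (tau - phi + tau / 4.0) % tau
    acro = np.where(acro >= tau, 0.0, acro)
    undefined = amp == 0.0
    phi = np.where(undefined, np.nan, phi)
    acro = np.where(undefined, np.nan, acro)
    if np.ndim(beta1) == 0:
        return float(amp), float(phi), float(acro)
    return amp, phi, acro


def classify_rhythmic(p_b1, p_b2, alpha: float = RHYTHM_FDR):
    """BH-FDR per coefficient across transcripts; rhythmic iff min FDR < alpha.

    NA p-values are excluded from the correction and flagged non-rhythmic.
    Returns ``(rhythmic, fdr_b1, fdr_b2)``.
    """
    out_fdr = []
    for p in (np.asarray(p_b1, float), np.asarray(p_b2, float)):
        fdr = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out_fdr.append(fdr)
    fdr1, fdr2 = out_fdr
    with np.errstate(invalid="ignore"):
        minfdr = np.fmin(fdr1, fdr2)
    rhythmic = np.where(np.isnan(minfdr), False, minfdr < alpha)
    return rhythmic.astype(bool), fdr1, fdr2


def conditional_r2(fit: MixedFit, X_fixed: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Nakagawa–Schielzeth conditional R² (Johnson extension for slopes).

    ``(var_fixed + var_random) / (var_fixed + var_random + var_residual)``,
    with var_random the mean over observations of ``z_i' G z_i``.
    """
    pred = X_fixed @ fit.beta.T                      # (n, T)
    var_f = pred.var(axis=0)
    quad = np.einsum("ni,tij,nj->tn", Z, fit.cov_re, Z)
    var_r = quad.mean(axis=1)
    denom = var_f + var_r + fit.sigma2
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (var_f + var_r) / denom, 0.0)


def bootstrap_se(
    y: np.ndarray,
    design: CosinorDesign,
    variant: str = "slopes",
    settings: BootstrapSettings | None = None,
    groups=None,
) -> dict:
    """Bootstrap SEs of MESOR, amplitude and acrophase for one response.

    Participants are resampled with replacement (cluster bootstrap) by
    default, implemented as group-multiplicity weights so replicates reuse
    the sufficient statistics; ``unit='row'`` resamples rows instead.
    Linear SEs are the SD of replicate estimates; the acrophase SE is the
    circular standard deviation of the replicate acrophases in hours.
    """
    settings = settings or BootstrapSettings()
    groups = design.participants if groups is None else np.asarray(groups)
    rng = np.random.default_rng(settings.seed)
    R = settings.replicates
    y = np.asarray(y, dtype=float)
    tau = design.tau

    if variant == "slopes":
        X, Z, i_mes = design.X, design.X, None
    elif variant == "intercept":
        X = np.column_stack([np.ones(len(y)), design.x1, design.x2])
        Z, i_mes = np.ones((len(y), 1)), 0
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if settings.unit == "participant":
        labels = np.unique(groups)
        G = len(labels)
        draws = rng.integers(0, G, size=(R, G))
        weights = np.zeros((R, G))
        for r in range(R):
            np.add.at(weights[r], draws[r], 1.0)
        Yrep = np.repeat(y[:, None], R, axis=1)
        fit = MixedModel(Yrep, X, groups, Z=Z, group_weights=weights).fit(
            df_method="wald"
        )
        ok = np.isfinite(fit.beta).all(axis=1) & fit.converged
    else:
        n = len(y)
        beta_list, ok_list = [], []
        for r in range(R):
            ridx = rng.integers(0, n, size=n)
            try:
                frep = MixedModel(
                    y[ridx], X[ridx], groups[ridx], Z=Z[ridx]
                ).fit(df_method="wald")
                beta_list.append(frep.beta[0])
                ok_list.append(bool(frep.converged[0]))
            except Exception:
                beta_list.append(np.full(X.shape[1], np.nan))
                ok_list.append(False)
        fit = None
        beta_arr = np.asarray(beta_list)
        ok = np.asarray(ok_list) & np.isfinite(beta_arr).all(axis=1)

    beta = fit.beta if fit is not None else beta_arr
    j1, j2 = (0, 1) if variant == "slopes" else (1, 2)
    amp, _, acro = derive_rhythm_params(beta[ok, j1], beta[ok, j2], tau)
    mes = beta[ok, i_mes] if i_mes is not None else np.zeros(ok.sum())
    unreliable = ok.mean() < 0.5
    acro_ok = acro[np.isfinite(acro)]
    se_acro = (
        float(stats.circstd(acro_ok, high=tau, low=0.0)) if acro_ok.size else np.nan
    )
    return {
        "se_mes": float(np.std(mes, ddof=1)) if ok.sum() > 1 else np.nan,
        "se_amp": float(np.std(amp, ddof=1)) if ok.sum() > 1 else np.nan,
        "se_acro_circ": se_acro,
        "n_ok": int(ok.sum()),
        "unreliable": bool(unreliable),
    }


def fit_session(
    gem_values: pd.DataFrame,
    meta: pd.DataFrame,
    tau: float = 24.0,
    variant: str = "slopes",
    alpha: float = RHYTHM_FDR,
    df_method: str = "satterthwaite",
    bootstrap: BootstrapSettings | None = None,
    bootstrap_transcripts=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every transcript of one session's melatonin-aligned samples.

    ``gem_values`` is transcripts × samples; ``meta`` must carry
    ``sample_id``, ``participant`` and ``aligned_time`` for the session's
    samples. Returns ``(results, per_participant)``: the per-transcript
    table (slopes, amplitude, acrophase, p/FDR, rhythmic flag, conditional
    R², optional bootstrap SEs) and the participant-level amplitude /
    acrophase estimates (fixed effects + conditional modes) used for
    session comparisons.
    """
    meta = meta.dropna(subset=["aligned_time"])
    # participants need >=2 samples to be z-scored / contribute to slopes
    counts = meta.groupby("participant")["sample_id"].count()
    keep = meta["participant"].isin(counts[counts >= 2].index)
    meta = meta.loc[keep]
    if meta["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants in a session fit")
    sample_ids = meta["sample_id"].to_numpy()
    Y = gem_values[sample_ids].to_numpy(dtype=float).T       # (n, T)
    groups = meta["participant"].to_numpy()
    design = cosinor_design(
        meta["aligned_time"].to_numpy(dtype=float), tau, participants=groups
    )

    if variant == "slopes":
        Yfit, _ = zscore_within(Y, groups)
        fit = fit_cosinor_slopes(Yfit, design, df_method=df_method)
        j1, j2 = 0, 1
        mes = np.zeros(fit.n_cols)
        X_fixed, Z = design.X, design.X
    elif variant == "intercept":
        Yfit = Y
        fit = fit_cosinor_intercept(Yfit, design, df_method=df_method)
        j1, j2 = 1, 2
        mes = fit.beta[:, 0]
        X_fixed = np.column_stack([np.ones(len(design.t)), design.x1, design.x2])
        Z = np.ones((len(design.t), 1))
    else:
        raise ValueError(f"unknown variant {variant!r}")

    b1, b2 = fit.beta[:, j1], fit.beta[:, j2]
    amp, phi, acro = derive_rhythm_params(b1, b2, tau)
    p1 = np.where(fit.converged, fit.pvalues[:, j1], np.nan)
    p2 = np.where(fit.converged, fit.pvalues[:, j2], np.nan)
    rhythmic, fdr1, fdr2 = classify_rhythmic(p1, p2, alpha=alpha)
    r2c = conditional_r2(fit, X_fixed, Z)

    res = pd.DataFrame({
        "transcript_id": gem_values.index,
        "variant": variant,
        "mes": mes, "beta1": b1, "beta2": b2,
        "amp": amp, "phi": phi, "acrophase": acro,
        "p_b1": p1, "p_b2": p2, "fdr_b1": fdr1, "fdr_b2": fdr2,
        "rhythmic": rhythmic, "r2c": r2c,
        "se_mes": np.nan, "se_amp": np.nan, "se_acro_circ": np.nan,
        "converged": fit.converged,
    }).set_index("transcript_id")

    if bootstrap is not None:
        targets = (
            list(bootstrap_transcripts)
            if bootstrap_transcripts is not None
            else list(gem_values.index)
        )
        for k, tid in enumerate(targets):
            yk = Yfit[:, gem_values.index.get_loc(tid)]
            bs = bootstrap_se(
                yk, design, variant=variant,
                settings=BootstrapSettings(
                    bootstrap.replicates, bootstrap.unit, bootstrap.seed + k
                ),
            )
            res.loc[tid, ["se_mes", "se_amp", "se_acro_circ"]] = (
                bs["se_mes"], bs["se_amp"], bs["se_acro_circ"]
            )

    # participant-level parameters: fixed effects + conditional modes
    if variant == "slopes":
        bi = fit.beta[:, None, :] + fit.ranef            # (T, G, 2)
        amp_i, _, acro_i = derive_rhythm_params(bi[..., 0], bi[..., 1], tau)
        recs = []
        for g, part in enumerate(fit.group_labels):
            recs.append(pd.DataFrame({
                "transcript_id": gem_values.index,
                "participant": part,
                "beta1_i": bi[:, g, 0], "beta2_i": bi[:, g, 1],
                "amp_i": amp_i[:, g], "acrophase_i": acro_i[:, g],
            }))
        per_part = pd.concat(recs, ignore_index=True)
    else:
        per_part = pd.DataFrame(
            columns=["transcript_id", "participant", "beta1_i", "beta2_i",
                     "amp_i", "acrophase_i"]
        )
    return res, per_part
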