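"""Synthetic cohort generator with ground truth.

Emulates the statistical structure of a 90-day head-down-tilt bed-rest
transcriptome study: 20 participants sampled in 6 sessions (two baseline,
three bed-rest, one recovery), 6 clock times per 24-h session at 4-h
spacing, a bimodal (day/night) distribution of peak times, session-specific
MESOR/amplitude/phase perturbations, participant-specific random intercepts
and rhythm slopes, Gaussian residual noise, and occasional missing samples
or undetectable melatonin profiles. Ground truth for every transcript ×
session is returned for parameter-recovery and error-rate studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, MelatoninPanel

__all__ = ["SimConfig", "generate_cohort", "generate_melatonin_profiles", "truth_summary"]

SESSIONS = ["BDC1", "BDC2", "HDT1", "HDT2", "HDT3", "R"]
CLOCK_TIMES = [15.0, 19.0, 23.0, 3.0, 7.0, 11.0]

#: per-session (MESOR shift, amplitude scale, phase shift in hours);
#: defaults follow the qualitative protocol trajectory — amplitudes highest
#: in late baseline, an earlier night peak entering bed rest, a deep
#: amplitude trough mid bed rest and no recovery of amplitude afterwards.
DEFAULT_SESSION_EFFECTS = {
    "BDC1": (0.0, 1.00, 0.0),
    "BDC2": (0.0, 1.10, 0.0),
    "HDT1": (-0.10, 1.00, -2.0),
    "HDT2": (-0.10, 0.45, 0.0),
    "HDT3": (-0.05, 0.80, 1.0),
    "R": (0.0, 0.35, 0.0),
}

#: (von Mises mean hour, concentration, weight): night- and day-peaking modes
DEFAULT_ACROPHASE_MIXTURE = [(3.0, 3.0, 0.55), (14.0, 3.0, 0.45)]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults are the study design."""

    n_participants: int = 20
    n_transcripts: int = 2000
    sessions: tuple = tuple(SESSIONS)
    clock_times: tuple = tuple(CLOCK_TIMES)
    tau: float = 24.0
    frac_rhythmic: float = 0.25
    amp_dist: tuple = (np.log(0.4), 0.5)        # lognormal (log-mean, log-sd), log2 units
    acrophase_mixture: list = field(default_factory=lambda: list(DEFAULT_ACROPHASE_MIXTURE))
    session_effects: dict = field(default_factory=lambda: dict(DEFAULT_SESSION_EFFECTS))
    mesor_dist: tuple = (8.0, 1.5)              # Normal(mean, sd) of baseline MESOR
    re_cov: np.ndarray = field(default_factory=lambda: np.diag([0.01, 0.01]))
    re_intercept_sd: float = 0.5
    noise_sd: float = 0.35
    missing_rate: float = 0.09                  # the study lost 64/701 samples
    frac_de: float = 0.0                        # transcripts with session DE offsets
    de_effect: float = 1.0                      # log2 shift magnitude for DE transcripts
    melatonin_offset_mean: float = 8.0
    melatonin_offset_sd: float = 0.6
    melatonin_undetectable_rate: float = 0.02
    flag_rate: float = 0.0                      # per-cell QC flag probability
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("frac_rhythmic", "missing_rate", "frac_de",
                     "melatonin_undetectable_rate", "flag_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        w = sum(m[2] for m in self.acrophase_mixture)
        if abs(w - 1.0) > 1e-8:
            raise ValueError(f"acrophase_mixture weights must sum to 1, got {w}")
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("re_cov must be positive semi-definite")
        self.re_cov = cov
        missing = [s for s in self.sessions if s not in self.session_effects]
        if missing:
            raise ValueError(f"session_effects missing entries for {missing}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["re_cov"] = np.asarray(self.re_cov).tolist()
        d["sessions"] = list(self.sessions)
        d["clock_times"] = list(self.clock_times)
        return d


def unwrap_clock_times(clock_times) -> np.ndarray:
    """Cumulative sampling times in hours from the first draw.

    Clock times that wrap past midnight continue on the next day, so
    consecutive samples keep their true spacing (4 h in the study design).
    """
    ct = np.asarray(clock_times, dtype=float)
    out = np.empty_like(ct)
    out[0] = ct[0]
    for i in range(1, len(ct)):
        out[i] = out[i - 1] + (ct[i] - ct[i - 1]) % 24.0
    return out


def _sample_acrophases(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw peak times (hours, mod tau) from the von Mises mixture."""
    mix = config.acrophase_mixture
    weights = np.array([m[2] for m in mix])
    comp = rng.choice(len(mix), size=n, p=weights)
    hours = np.empty(n)
    scale = 2.0 * np.pi / config.tau
    for k, (mu_h, kappa, _) in enumerate(mix):
        m = comp == k
        ang = rng.vonmises(mu_h * scale, kappa, size=m.sum())
        hours[m] = (ang / scale) % config.tau
    return hours


def _sample_offsets(config: SimConfig, rng: np.random.Generator):
    """True melatonin offsets (hours-of-day) per participant × session."""
    P, S = config.n_participants, len(config.sessions)
    offs = rng.normal(config.melatonin_offset_mean, config.melatonin_offset_sd, (P, S))
    # keep the morning crossing inside the sampling window and clear of the
    # midday baseline segment used for the threshold
    offs = np.clip(offs, 7.6, 10.9)
    detectable = rng.random((P, S)) >= config.melatonin_undetectable_rate
    return offs, detectable


def generate_melatonin_profiles(config: SimConfig, rng=None, offsets=None,
                                detectable=None) -> MelatoninPanel:
    """Hourly (07:00–23:00) melatonin series per participant × session.

    Each detectable profile has a low daytime baseline, a nocturnal rise
    from 21:00, and an elevated early-morning segment declining linearly
    through the baseline-derived threshold (mean + 2·SD of the designated
    midday baseline samples) *exactly* at the true offset: the two hourly
    samples bracketing the offset lie on one line through (offset,
    threshold), so linear interpolation recovers the offset to float
    precision. Undetectable profiles stay at baseline throughout.
    """
    from .melatonin import designate_baseline  # local import; no cycle at call time

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if offsets is None:
        offsets, detectable = _sample_offsets(config, rng)
    P, S = offsets.shape
    hours = np.arange(7.0, 24.0)  # 07:00 .. 23:00
    rows, truth_rows = [], []
    participants = [f"P{i + 1:02d}" for i in range(P)]
    for i, part in enumerate(participants):
        for j, sess in enumerate(config.sessions):
            base = 2.0 + rng.uniform(0.0, 1.0)
            conc = base + rng.uniform(-0.1, 0.1, size=hours.size)
            if detectable[i, j]:
                off = offsets[i, j]
                # threshold exactly as the offset detector will compute it
                bidx = designate_baseline(hours, conc)
                thr = conc[bidx].mean() + 2.0 * conc[bidx].std(ddof=1)
                # morning decline of 0.9·thr per hour passes through
                # (off, thr) and stays positive at the next hourly sample
                slope = 0.9 * thr
                line = thr + slope * (off - hours)
                morning = hours <= np.ceil(off)
                conc[morning] = line[morning]
                # daytime samples outside the designated baseline stay
                # safely below the threshold until the evening rise
                day = ~morning & (hours < 21.0)
                day[bidx] = False
                conc[day] = np.minimum(conc[day], thr - 0.05)
                evening = hours >= 21.0
                conc[evening] += (hours[evening] - 20.5) * 8.0
            rows.extend(
                {"participant": part, "session": sess, "clock_time": h, "concentration": c}
                for h, c in zip(hours, conc)
            )
            truth_rows.append(
                {"participant": part, "session": sess,
                 "true_offset": offsets[i, j] if detectable[i, j] else np.nan,
                 "detectable": bool(detectable[i, j])}
            )
    return MelatoninPanel(pd.DataFrame(rows), pd.DataFrame(truth_rows))


def generate_cohort(config: SimConfig):
    """Simulate a full cohort.

    Returns ``(gem, meta, melatonin, truth)``: the log2 expression matrix
    with QC flags, the sample sheet (with per-sample QC metrics), the
    melatonin panel, and the ground-truth table per transcript × session.

    Each transcript's expression is
    ``MESOR + session offset + amp · sin(2π(t − φ)/τ)`` evaluated at times
    aligned to the participant's melatonin offset, plus participant random
    intercepts, participant rhythm-slope deviations (rhythmic transcripts
    only) and Gaussian noise. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    P, T = config.n_participants, config.n_transcripts
    sessions = list(config.sessions)
    S = len(sessions)
    tau = config.tau
    scale = 2.0 * np.pi / tau

    transcripts = [f"T{k + 1:05d}" for k in range(T)]
    participants = [f"P{i + 1:02d}" for i in range(P)]

    rhythmic = rng.random(T) < config.frac_rhythmic
    mesor = rng.normal(*config.mesor_dist, size=T)
    amp = np.where(rhythmic, rng.lognormal(*config.amp_dist, size=T), 0.0)
    acro = _sample_acrophases(config, T, rng)

    is_de = rng.random(T) < config.frac_de
    de_offsets = np.zeros((T, S))
    if is_de.any():
        pattern = rng.choice([0.0, 1.0, -1.0], size=(int(is_de.sum()), S),
                             p=[0.5, 0.25, 0.25])
        de_offsets[is_de] = pattern * config.de_effect

    # participant random effects (shared across sessions)
    intercept_re = rng.normal(0.0, config.re_intercept_sd, size=(T, P))
    slope_re = rng.multivariate_normal(np.zeros(2), config.re_cov, size=(T, P))
    slope_re[~rhythmic] = 0.0

    offsets, detectable = _sample_offsets(config, rng)
    melatonin = generate_melatonin_profiles(config, rng=rng, offsets=offsets,
                                            detectable=detectable)

    unwrapped = unwrap_clock_times(config.clock_times)
    n_tp = len(config.clock_times)

    # per-session truth
    truth_rows = []
    beta1 = np.empty((T, S))
    beta2 = np.empty((T, S))
    mes_ts = np.empty((T, S))
    for j, sess in enumerate(sessions):
        shift, amp_scale, phase_shift = config.session_effects[sess]
        amp_s = amp * amp_scale
        acro_s = (acro + phase_shift) % tau
        mes_s = mesor + shift + de_offsets[:, j]
        beta1[:, j] = amp_s * np.cos(scale * acro_s)
        beta2[:, j] = amp_s * np.sin(scale * acro_s)
        mes_ts[:, j] = mes_s
        truth_rows.append(pd.DataFrame({
            "transcript_id": transcripts,
            "session": sess,
            "mesor": mes_s,
            "amplitude": amp_s,
            "acrophase": np.where(rhythmic, acro_s, np.nan),
            "rhythmic": rhythmic,
            "mesor_offset": de_offsets[:, j],
        }))
    truth = pd.concat(truth_rows, ignore_index=True)

    # assemble samples
    meta_rows = []
    values = np.empty((T, P * S * n_tp))
    col = 0
    sample_ids = []
    group = np.array(["control", "cocktail"])[np.arange(P) % 2]
    leg = np.array(["leg1", "leg2"])[(np.arange(P) >= P / 2).astype(int)]
    for i, part in enumerate(participants):
        for j, sess in enumerate(sessions):
            t_aligned = unwrapped - offsets[i, j]
            x1 = np.cos(scale * t_aligned)
            x2 = np.sin(scale * t_aligned)
            sig = (
                mes_ts[:, j:j + 1]
                + intercept_re[:, i:i + 1]
                + np.outer(beta1[:, j] + slope_re[:, i, 0], x1)
                + np.outer(beta2[:, j] + slope_re[:, i, 1], x2)
            )
            if config.noise_sd > 0:
                sig = sig + rng.normal(0.0, config.noise_sd, size=sig.shape)
            values[:, col:col + n_tp] = sig
            for k, ct in enumerate(config.clock_times):
                sid = f"{part}_{sess}_TP{k + 1}"
                sample_ids.append(sid)
                meta_rows.append({
                    "sample_id": sid, "participant": part, "session": sess,
                    "clock_time": ct, "time_index": k,
                    "group": group[i], "leg": leg[i],
                })
            col += n_tp

    meta = pd.DataFrame(meta_rows)
    # plausible per-sample QC metrics (all passing by construction)
    n_samp = len(meta)
    meta["median_cv_pct"] = rng.uniform(3.0, 8.0, n_samp)
    meta["flagged_pct"] = rng.uniform(5.0, 20.0, n_samp)
    meta["rin"] = rng.uniform(7.0, 9.8, n_samp)

    keep = rng.random(n_samp) >= config.missing_rate
    values = values[:, keep]
    meta = meta.loc[keep].reset_index(drop=True)
    sample_ids = [s for s, k in zip(sample_ids, keep) if k]

    vdf = pd.DataFrame(values, index=transcripts, columns=sample_ids)
    flags = None
    if config.flag_rate > 0:
        flags = pd.DataFrame(
            rng.random(vdf.shape) < config.flag_rate,
            index=vdf.index, columns=vdf.columns,
        )
    gem = ExpressionMatrix(vdf, flags)
    return gem, meta, melatonin, truth


def truth_summary(truth: pd.DataFrame, tau: float = 24.0):
    """Per-session rhythmic counts and a 24 × one-hour acrophase histogram."""
    counts = (
        truth.groupby("session", sort=False)["rhythmic"].sum().astype(int)
    )
    edges = np.arange(0.0, 25.0)
    hist = {}
    for sess, grp in truth.groupby("session", sort=False):
        a = grp.loc[grp["rhythmic"], "acrophase"].dropna() % tau
        hist[sess] = np.histogram(a, bins=edges)[0]
    hist = pd.DataFrame(hist).T
    hist.columns = [f"h{int(h):02d}" for h in edges[:-1]]
    return counts, hist
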