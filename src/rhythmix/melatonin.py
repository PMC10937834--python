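"""Melatonin offset phase markers and melatonin-aligned sample times.

The morning melatonin offset — the clock time at which salivary melatonin
falls back below a baseline-derived threshold (baseline mean + 2 SD, after
Voultsios' threshold method) — serves as the internal circadian phase
reference. Sampling times are re-expressed relative to it before any
rhythm modelling, and participant × session series without a usable offset
are excluded from aligned analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import MixedAnova, mixed_anova
from .synth import unwrap_clock_times

__all__ = [
    "MelatoninOffset", "designate_baseline", "melatonin_offset",
    "compute_offsets", "align_times", "offset_session_anova",
]

log = logging.getLogger(__name__)

#: radioimmunoassay detection limit (pg/ml); a profile whose maximum does not
#: clear the threshold by at least this margin has no usable morning decline
DETECTION_LIMIT = 0.85


@dataclass
class MelatoninOffset:
    participant: object
    session: object
    threshold: float
    offset_hours: float      # decimal clock hours; NaN when undetectable
    detectable: bool


def designate_baseline(hours: np.ndarray, conc: np.ndarray,
                       method: str = "midday") -> np.ndarray:
    """Indices of the three baseline samples used for the threshold.

    ``midday`` (default) designates the 12:00–14:00 samples — the low
    daytime plateau the threshold method assumes; ``first3`` uses the first
    three samples of the profile.
    """
    hours = np.asarray(hours, dtype=float)
    if method == "first3":
        return np.arange(3)
    if method == "midday":
        idx = np.flatnonzero((hours >= 12.0) & (hours <= 14.0))
        if idx.size < 3:  # irregular grid: fall back to 3 samples nearest 13:00
            idx = np.argsort(np.abs(hours - 13.0))[:3]
        return np.sort(idx[:3])
    raise ValueError(f"unknown baseline designation {method!r}")


def melatonin_offset(series: pd.DataFrame, participant=None, session=None,
                     baseline: str = "midday") -> MelatoninOffset:
    """Morning offset of one hourly melatonin profile.

    The threshold is mean + 2·SD of the three designated baseline samples;
    the offset is the linearly interpolated clock time of the first
    downward threshold crossing after the profile's pre-baseline maximum.
    ``detectable`` is False when the profile never clears the threshold by
    the assay detection limit or never crosses back below it.
    """
    s = series.dropna(subset=["concentration"]).sort_values("clock_time")
    if len(series) and s.empty:
        raise ValueError("all concentrations missing")
    if len(s) < 3:
        raise ValueError("need at least 3 melatonin samples")
    hours = s["clock_time"].to_numpy(dtype=float)
    conc = s["concentration"].to_numpy(dtype=float)
    if (conc < 0).any():
        raise ValueError("negative melatonin concentrations")

    bidx = designate_baseline(hours, conc, method=baseline)
    thr = float(conc[bidx].mean() + 2.0 * conc[bidx].std(ddof=1))

    # search the segment before the baseline window for the morning decline
    stop = bidx[0] if bidx[0] > 0 else len(conc)
    seg = conc[:stop + 1]
    if seg.size < 2 or seg.max() < thr + DETECTION_LIMIT:
        return MelatoninOffset(participant, session, thr, np.nan, False)
    k0 = int(np.argmax(seg))
    for k in range(k0, stop):
        if conc[k] >= thr > conc[k + 1]:
            frac = (conc[k] - thr) / (conc[k] - conc[k + 1])
            off = hours[k] + frac * (hours[k + 1] - hours[k])
            return MelatoninOffset(participant, session, thr, float(off), True)
    return MelatoninOffset(participant, session, thr, np.nan, False)


def compute_offsets(panel, baseline: str = "midday") -> pd.DataFrame:
    """Offsets for every participant × session series of a melatonin panel."""
    samples = panel.samples if hasattr(panel, "samples") else panel
    recs = []
    for (part, sess), grp in samples.groupby(["participant", "session"], sort=False):
        o = melatonin_offset(grp, participant=part, session=sess, baseline=baseline)
        recs.append(vars(o))
    return pd.DataFrame(recs).rename(columns={"offset_hours": "offset_hours"})


def align_times(meta: pd.DataFrame, offsets: pd.DataFrame,
                per_participant_mean: bool = False) -> pd.DataFrame:
    """Append melatonin-aligned times to a sample sheet.

    ``aligned_time = unwrapped sampling time − melatonin offset`` in decimal
    hours, where clock times are unwrapped within each participant ×
    session series so consecutive samples keep their true spacing across
    midnight. Series whose offset is missing or undetectable are dropped
    (and logged). With ``per_participant_mean`` the participant's mean
    detectable offset is used for all of their sessions.
    """
    off = offsets[offsets["detectable"]].copy()
    if per_participant_mean:
        mean_off = off.groupby("participant")["offset_hours"].mean()
        key = lambda part, sess: mean_off.get(part, np.nan)  # noqa: E731
    else:
        tbl = off.set_index(["participant", "session"])["offset_hours"]
        key = lambda part, sess: tbl.get((part, sess), np.nan)  # noqa: E731

    sort_col = "time_index" if "time_index" in meta.columns else "clock_time"
    out = []
    n_dropped = 0
    for (part, sess), grp in meta.groupby(["participant", "session"], sort=False):
        o = key(part, sess)
        if not np.isfinite(o):
            n_dropped += 1
            log.info("dropping %s × %s: no usable melatonin offset", part, sess)
            continue
        grp = grp.sort_values(sort_col).copy()
        unwrapped = unwrap_clock_times(grp["clock_time"].to_numpy(dtype=float))
        grp["aligned_time"] = unwrapped - o
        out.append(grp)
    if not out:
        raise ValueError("no participant × session series with usable offsets")
    if n_dropped:
        log.info("align_times dropped %d participant-session series", n_dropped)
    return pd.concat(out).sort_index()


def offset_session_anova(offsets: pd.DataFrame) -> MixedAnova:
    """Mixed ANOVA 'offset ~ session + (1|participant)' on detectable offsets."""
    d = offsets[offsets["detectable"]].rename(columns={"offset_hours": "offset"})
    if d["session"].nunique() < 2:
        raise ValueError("need at least 2 sessions")
    return mixed_anova(d, "offset", ["session"], "participant")
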