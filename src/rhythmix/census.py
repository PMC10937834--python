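"""Census and comparison of rhythmicity across sampling sessions.

Counts of rhythmic transcripts per session are compared with a χ²
homogeneity test; rhythmic sets with pairwise overlap matrices (Jaccard
and column-conditional); amplitude / R² distributions with pairwise
two-sample Kolmogorov–Smirnov tests under BH correction; acrophase
distributions with χ² tests over 24 one-hour bins; session effects on
participant-level amplitudes with a mixed ANOVA; and session effects on
acrophase with participant-cluster bootstrap intervals of the circular
mean, declaring a pair different when the 95% intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .anova import MixedAnova, mixed_anova
from .cosinor import BootstrapSettings

__all__ = [
    "RhythmCensus", "rhythmic_counts_chisq", "overlap_matrices",
    "compare_distributions_ks", "acrophase_histogram", "acrophase_chisq",
    "amplitude_session_anova", "acrophase_session_compare",
    "classify_peak_window",
]

#: peak-window classes (half-open clock-hour intervals; boundary belongs to
#: the later window): day 11:00–18:00, evening 18:00–21:00,
#: night 21:00–07:00 (wrapping), morning 07:00–11:00
PEAK_WINDOWS = {
    "day": (11.0, 18.0),
    "evening": (18.0, 21.0),
    "night": (21.0, 7.0),
    "morning": (7.0, 11.0),
}


@dataclass
class RhythmCensus:
    counts: pd.Series              # rhythmic transcripts per session
    percentages: pd.Series
    jaccard: pd.DataFrame          # |A∩B| / |A∪B| × 100
    conditional: pd.DataFrame      # [i, j] = |A_i ∩ A_j| / |A_j| × 100
    always_rhythmic: list
    n_transcripts: int
    empty_sessions: list


def rhythmic_counts_chisq(flags: pd.DataFrame):
    """χ² homogeneity test on the sessions × (rhythmic, not) count table."""
    counts = flags.sum(axis=0).to_numpy(dtype=float)
    total = len(flags)
    table = np.column_stack([counts, total - counts])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        import warnings

        warnings.warn("expected cell count below 5; chi-square is approximate",
                      stacklevel=2)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def overlap_matrices(flags: pd.DataFrame) -> RhythmCensus:
    """Pairwise overlap of rhythmic sets across sessions.

    ``flags`` is a boolean transcripts × sessions table. The symmetric
    matrix is Jaccard overlap |A∩B|/|A∪B|; the column-conditional matrix
    scales the intersection by the column session's set size.
    """
    sessions = list(flags.columns)
    F = flags.to_numpy(dtype=bool)
    sizes = F.sum(axis=0)
    S = len(sessions)
    jac = np.zeros((S, S))
    cond = np.zeros((S, S))
    empty = [s for s, n in zip(sessions, sizes) if n == 0]
    for i in range(S):
        for j in range(S):
            inter = np.count_nonzero(F[:, i] & F[:, j])
            union = np.count_nonzero(F[:, i] | F[:, j])
            jac[i, j] = 100.0 * inter / union if union else 0.0
            cond[i, j] = 100.0 * inter / sizes[j] if sizes[j] else 0.0
    always = list(flags.index[F.all(axis=1)]) if S else []
    counts = pd.Series(sizes, index=sessions)
    return RhythmCensus(
        counts=counts,
        percentages=100.0 * counts / len(flags),
        jaccard=pd.DataFrame(jac, index=sessions, columns=sessions),
        conditional=pd.DataFrame(cond, index=sessions, columns=sessions),
        always_rhythmic=always,
        n_transcripts=len(flags),
        empty_sessions=empty,
    )


def compare_distributions_ks(values_by_session: dict, label: str = "value"):
    """All pairwise two-sample KS tests with BH correction over the family."""
    sessions = list(values_by_session)
    recs = []
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            a = np.asarray(values_by_session[sessions[i]], dtype=float)
            b = np.asarray(values_by_session[sessions[j]], dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if a.size < 2 or b.size < 2:
                raise ValueError("need at least 2 values per session for KS")
            ks = stats.ks_2samp(a, b)
            recs.append({
                "label": label, "session_a": sessions[i], "session_b": sessions[j],
                "D": float(ks.statistic), "p": float(ks.pvalue),
            })
    out = pd.DataFrame(recs)
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def acrophase_histogram(acrophases, tau: float = 24.0,
                        clock_offset: float = 0.0) -> np.ndarray:
    """Counts in 24 half-open one-hour bins anchored at clock hour 0.

    ``clock_offset`` (e.g. the session-mean melatonin offset) is added
    before binning so melatonin-aligned acrophases land in clock time.
    """
    a = np.asarray(acrophases, dtype=float)
    a = a[np.isfinite(a)]
    if ((a < 0) | (a >= tau)).any():
        raise ValueError("acrophases must lie in [0, tau)")
    h = (a + clock_offset) % 24.0
    return np.histogram(h, bins=np.arange(0.0, 25.0))[0]


def _pool_zero_expected(table: np.ndarray) -> np.ndarray:
    """Merge bins with zero column totals into their right neighbour."""
    keep_cols = []
    pending = np.zeros(table.shape[0])
    cols = []
    for j in range(table.shape[1]):
        col = table[:, j] + pending
        if col.sum() == 0:
            pending = col
            continue
        pending = np.zeros(table.shape[0])
        cols.append(col)
    if len(cols) == 0:
        raise ValueError("both histograms are empty")
    if pending.sum() > 0:
        cols[-1] = cols[-1] + pending
    return np.column_stack(cols)


def acrophase_chisq(hist_a: np.ndarray, hist_b: np.ndarray):
    """χ² homogeneity of two acrophase histograms (zero bins pooled)."""
    a = np.asarray(hist_a, dtype=float)
    b = np.asarray(hist_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must have equal bin counts")
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both histograms are empty")
    table = _pool_zero_expected(np.vstack([a, b]))
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def amplitude_session_anova(per_participant: pd.DataFrame,
                            value_col: str = "amp_i") -> MixedAnova:
    """Mixed ANOVA 'amplitude ~ session + (1|participant)'."""
    return mixed_anova(per_participant, value_col, ["session"], "participant")


def acrophase_session_compare(
    per_participant: pd.DataFrame,
    settings: BootstrapSettings | None = None,
    tau: float = 24.0,
    value_col: str = "acrophase_i",
    level: float = 0.95,
) -> pd.DataFrame:
    """Circular-mean acrophase per session with cluster-bootstrap intervals.

    Participants are resampled with replacement within each session; the
    percentile interval of the bootstrap circular means is expressed as
    (center − half-width, center + half-width) on the circle. Two sessions
    differ when their intervals do not overlap (circular interval
    arithmetic). Sessions with fewer than 3 participants are flagged
    unreliable.
    """
    settings = settings or BootstrapSettings()
    rng = np.random.default_rng(settings.seed)
    scale = 2.0 * np.pi / tau
    rows = {}
    for sess, grp in per_participant.groupby("session", sort=False):
        vals = grp.dropna(subset=[value_col])
        a = vals[value_col].to_numpy(dtype=float)
        parts = vals["participant"].to_numpy()
        labels = np.unique(parts)
        cm = stats.circmean(a * scale, high=2 * np.pi) / scale
        boots = np.empty(settings.replicates)
        for r in range(settings.replicates):
            pick = labels[rng.integers(0, len(labels), len(labels))]
            sel = np.concatenate([a[parts == p] for p in pick])
            boots[r] = stats.circmean(sel * scale, high=2 * np.pi) / scale
        # percentile interval around the circular mean (work in deviations)
        dev = (boots - cm + tau / 2) % tau - tau / 2
        lo, hi = np.quantile(dev, [(1 - level) / 2, 1 - (1 - level) / 2])
        rows[sess] = {
            "session": sess,
            "circ_mean": cm % tau,
            "lo": lo, "hi": hi,          # interval half-extents (hours)
            "n_participants": len(labels),
            "unreliable": len(labels) < 3,
        }
    out = pd.DataFrame(rows.values())

    # pairwise non-overlap on the circle
    recs = []
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            a_, b_ = out.iloc[i], out.iloc[j]
            d = (b_["circ_mean"] - a_["circ_mean"] + tau / 2) % tau - tau / 2
            # intervals [lo, hi] around each center; overlap iff the center
            # separation is covered by the two half-intervals
            overlap = (d >= a_["lo"] - b_["hi"]) and (d <= a_["hi"] - b_["lo"])
            recs.append({
                "session_a": a_["session"], "session_b": b_["session"],
                "circ_distance": abs(d), "different": not overlap,
            })
    pairs = pd.DataFrame(recs)
    return out, pairs


def classify_peak_window(hour: float) -> str:
    """Assign a clock-hour acrophase to day/evening/night/morning windows."""
    h = float(hour)
    if not 0.0 <= h < 24.0:
        raise ValueError(f"hour must be in [0, 24), got {hour}")
    if 11.0 <= h < 18.0:
        return "day"
    if 18.0 <= h < 21.0:
        return "evening"
    if 7.0 <= h < 11.0:
        return "morning"
    return "night"
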