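"""Repeated-measures (mixed-model) ANOVA with participant random intercepts.

One shared code path serves every "response ~ factors + (1|participant)"
model in the pipeline: melatonin offsets, transcript expression,
rhythm-parameter comparisons and component scores. Term F-tests use
Satterthwaite denominator degrees of freedom; least-squares means are
equal-weight marginal predictions over the factorial grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import Design, build_design
from .lmm import MixedFit, MixedModel

__all__ = ["MixedAnova", "mixed_anova"]

_BOUNDARY = -7.5  # log-scale variance parameter below this ≈ singular fit


@dataclass
class MixedAnova:
    """Fitted mixed ANOVA for a single response."""

    design: Design
    model: MixedModel
    fit: MixedFit
    anova_table: pd.DataFrame      # term, F, num_df, den_df, p
    singular: bool = False

    def ls_means(self, by) -> pd.DataFrame:
        """LS means ± SE (and Satterthwaite df) for factor level(s) ``by``."""
        cells, rows = self.design.lsmean_rows(by)
        est = rows @ self.fit.beta[0]
        se = np.sqrt(np.einsum("ip,pq,iq->i", rows, self.fit.cov_beta[0], rows))
        df = self.model.contrast_df(self.fit.theta, self.fit.sigma2, rows)[0]
        out = cells.copy()
        out["lsmean"], out["se"], out["df"] = est, se, df
        return out

    def pairwise(self, factor: str) -> pd.DataFrame:
        """All pairwise LS-mean differences for one factor, with t-test p."""
        cells, rows = self.design.lsmean_rows(factor)
        levels = cells[factor].tolist()
        recs, cons = [], []
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                cons.append(rows[i] - rows[j])
                recs.append((levels[i], levels[j]))
        cons = np.asarray(cons)
        est = cons @ self.fit.beta[0]
        se = np.sqrt(np.einsum("ip,pq,iq->i", cons, self.fit.cov_beta[0], cons))
        df = self.model.contrast_df(self.fit.theta, self.fit.sigma2, cons)[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, est / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(tval), df)
        return pd.DataFrame({
            "level_a": [r[0] for r in recs], "level_b": [r[1] for r in recs],
            "estimate": est, "se": se, "df": df, "t": tval, "p": p,
        })


def mixed_anova(
    df: pd.DataFrame,
    response: str,
    factors: list,
    group_col: str,
    interactions: list | None = None,
    levels: dict | None = None,
) -> MixedAnova:
    """Fit ``response ~ factors (+ interactions) + (1|group)`` by REML.

    A fit whose participant variance collapses to the boundary is flagged
    ``singular`` (with a warning); its inference coincides with the
    fixed-effects ANOVA, which is the documented fallback.
    """
    sub = df.dropna(subset=[response]).reset_index(drop=True)
    if sub[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups for a mixed ANOVA")
    design = build_design(sub, factors, interactions=interactions, levels=levels)
    y = sub[response].to_numpy(dtype=float)
    model = MixedModel(y, design.X, sub[group_col].to_numpy())
    # single-response fits are cheap: converge the variance ratio tightly
    fit = model.fit(ftol=1e-13, maxiter=800)
    singular = bool(fit.theta[0, 0] < _BOUNDARY)
    if singular:
        warnings.warn(
            "participant variance estimated at the boundary; "
            "inference reduces to the fixed-effects ANOVA",
            stacklevel=2,
        )
    rows = []
    for term in design.terms:
        L = design.contrast_block(term)
        F, num_df, den_df, p = model.ftest(fit, L)
        rows.append({"term": term, "F": F[0], "num_df": num_df[0],
                     "den_df": den_df[0], "p": p[0]})
    table = pd.DataFrame(rows)
    return MixedAnova(design=design, model=model, fit=fit,
                      anova_table=table, singular=singular)
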