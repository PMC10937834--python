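"""Fixed-effect design construction for the repeated-measures ANOVA models.

Factors are sum-to-zero (deviation) coded so that single-term contrast
blocks give Type-III-style tests, and least-squares means are computed by
averaging encoded prediction rows over the full factorial grid with equal
weights — the marginal-means convention of the mixed-ANOVA workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["Design", "build_design"]


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Deviation coding: columns for levels[:-1], last level coded -1."""
    n, L = len(values), len(levels)
    out = np.zeros((n, L - 1))
    pos = {lev: i for i, lev in enumerate(levels)}
    idx = values.map(pos)
    if idx.isna().any():
        bad = values[idx.isna()].unique().tolist()
        raise ValueError(f"values outside declared levels: {bad}")
    idx = idx.to_numpy(dtype=int)
    for j in range(L - 1):
        out[idx == j, j] = 1.0
    out[idx == L - 1, :] = -1.0
    return out


@dataclass
class Design:
    X: np.ndarray                   # (n, p) including intercept
    columns: list                   # column names
    terms: dict                     # term name -> list of column indices
    factors: dict                   # factor name -> ordered levels
    interactions: list              # list of (a, b) tuples

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def contrast_block(self, term: str) -> np.ndarray:
        """Rows of an L matrix testing H0: all coefficients of ``term`` = 0."""
        idx = self.terms[term]
        L = np.zeros((len(idx), self.p))
        for r, j in enumerate(idx):
            L[r, j] = 1.0
        return L

    def encode_cells(self, cells: pd.DataFrame) -> np.ndarray:
        """Encode arbitrary factor-level combinations as prediction rows."""
        n = len(cells)
        X = np.zeros((n, self.p))
        X[:, 0] = 1.0
        coded = {
            f: _sum_code(cells[f], levels) for f, levels in self.factors.items()
        }
        for f in self.factors:
            X[:, self.terms[f]] = coded[f]
        for a, b in self.interactions:
            cols = []
            for i in range(coded[a].shape[1]):
                for j in range(coded[b].shape[1]):
                    cols.append(coded[a][:, i] * coded[b][:, j])
            X[:, self.terms[f"{a}:{b}"]] = np.column_stack(cols)
        return X

    def _full_grid(self) -> pd.DataFrame:
        names = list(self.factors)
        combos = list(product(*[self.factors[f] for f in names]))
        return pd.DataFrame(combos, columns=names)

    def lsmean_rows(self, by) -> tuple[pd.DataFrame, np.ndarray]:
        """Equal-weight marginal prediction rows for each level combination
        of the factor(s) in ``by``, averaging over all other factors."""
        if isinstance(by, str):
            by = [by]
        grid = self._full_grid()
        enc = self.encode_cells(grid)
        keys = grid[by]
        cells = keys.drop_duplicates().reset_index(drop=True)
        rows = np.empty((len(cells), self.p))
        for i, (_, cell) in enumerate(cells.iterrows()):
            m = np.ones(len(grid), dtype=bool)
            for f in by:
                m &= (keys[f] == cell[f]).to_numpy()
            rows[i] = enc[m].mean(axis=0)
        return cells, rows


def build_design(
    df: pd.DataFrame,
    factors,
    interactions: list | None = None,
    levels: dict | None = None,
) -> Design:
    """Intercept + sum-coded main effects (+ optional two-way interactions).

    ``factors`` is an ordered list of column names; ``levels`` may pin the
    level order (defaults to order of first appearance). Factors with a
    single observed level are dropped with a warning-free no-op (aliased
    with the intercept).
    """
    interactions = interactions or []
    levels = dict(levels or {})
    fac = {}
    for f in factors:
        lv = list(levels.get(f, pd.unique(df[f])))
        if len(lv) < 2:
            continue  # constant factor: aliased with intercept, dropped
        fac[f] = lv

    cols = ["Intercept"]
    terms = {}
    blocks = [np.ones((len(df), 1))]
    coded = {}
    for f, lv in fac.items():
        coded[f] = _sum_code(df[f], lv)
        terms[f] = list(range(len(cols), len(cols) + len(lv) - 1))
        cols += [f"{f}[{l}]" for l in lv[:-1]]
        blocks.append(coded[f])
    kept_inter = []
    for a, b in interactions:
        if a not in fac or b not in fac:
            continue
        kept_inter.append((a, b))
        prod_cols = []
        names = []
        for i, la in enumerate(fac[a][:-1]):
            for j, lb in enumerate(fac[b][:-1]):
                prod_cols.append(coded[a][:, i] * coded[b][:, j])
                names.append(f"{a}[{la}]:{b}[{lb}]")
        terms[f"{a}:{b}"] = list(range(len(cols), len(cols) + len(names)))
        cols += names
        blocks.append(np.column_stack(prod_cols))
    X = np.hstack(blocks)
    return Design(X=X, columns=cols, terms=terms, factors=fac,
                  interactions=kept_inter)
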