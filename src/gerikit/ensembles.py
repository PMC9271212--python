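"""Longitudinal Arc+ population statistics: session fractions, pairwise and
consecutive overlap against chance, reexpression trees and persistence.

Call tables are long-format DataFrames with columns (cell_id, session,
call); a cell that is not-determined (ND) in a session is excluded from
that session's denominator. Chance overlap is the product of the marginal
Arc+ fractions over the pairwise universe (cells usable in both sessions),
with hypergeometric inference; a label-shuffle null is available as an
alternative method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import ARC_NEG, ARC_POS, ND


@dataclass
class OverlapResult:
    observed_fraction: float
    chance_fraction: float
    p_value: float  # upper-tail P(X >= observed)
    p_mid: float  # mid-P (discreteness-corrected)
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    method: str = "analytic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.observed_fraction <= 1.0
                and 0.0 <= self.chance_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap exceeds the smaller set")


def _pivot(table: pd.DataFrame) -> pd.DataFrame:
    """Wide cells x sessions call matrix."""
    return table.pivot(index="cell_id", columns="session", values="call")


def session_fraction(table: pd.DataFrame, session: int,
                     ci_alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Fraction of Arc+ cells among usable (non-ND) cells, with a
    Clopper-Pearson binomial confidence interval."""
    calls = table.loc[table["session"] == session, "call"]
    usable = calls[calls != ND]
    n = len(usable)
    if n == 0:
        raise ValueError(f"no usable cells in session {session}")
    k = int((usable == ARC_POS).sum())
    lo = stats.beta.ppf(ci_alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - ci_alpha / 2, k + 1, n - k) if k < n else 1.0
    return k / n, (float(lo), float(hi))


def pairwise_overlap(table: pd.DataFrame, session_a: int, session_b: int,
                     method: str = "analytic", n_shuffles: int = 1000,
                     seed: int = 0) -> OverlapResult:
    """Observed vs chance overlap of the Arc+ sets of two sessions.

    Universe = cells usable in both sessions. Observed = |A n B| /
    universe; chance = (|A|/n) * (|B|/n). The analytic p-value is the
    hypergeometric upper tail P(X >= observed overlap); ``method=
    "shuffle"`` estimates it by label shuffles instead. ``p_mid`` applies
    the mid-P correction (half weight on the observed count), appropriate
    when calibrating discrete p-values against a uniform reference.
    """
    wide = _pivot(table)
    if session_a not in wide.columns or session_b not in wide.columns:
        raise ValueError("session missing from table")
    sub = wide[[session_a, session_b]].dropna()
    sub = sub[(sub != ND).all(axis=1)]
    n = len(sub)
    if n == 0:
        raise ValueError("empty pairwise universe")
    a = sub[session_a] == ARC_POS
    b = sub[session_b] == ARC_POS
    na, nb = int(a.sum()), int(b.sum())
    k = int((a & b).sum())
    observed = k / n
    chance = (na / n) * (nb / n)

    if method == "analytic":
        # X ~ Hypergeom(n, na, nb): overlap when B's labels are random
        p = float(stats.hypergeom.sf(k - 1, n, na, nb))
        p_mid = float(stats.hypergeom.sf(k, n, na, nb)
                      + 0.5 * stats.hypergeom.pmf(k, n, na, nb))
    elif method == "shuffle":
        if n_shuffles < 1:
            raise ValueError("need at least one shuffle")
        rng = np.random.default_rng(seed)
        bv = b.to_numpy()
        ks = np.array([int((a.to_numpy() & rng.permutation(bv)).sum())
                       for _ in range(n_shuffles)])
        p = float((1 + np.sum(ks >= k)) / (1 + n_shuffles))
        p_mid = float((np.sum(ks > k) + 0.5 * np.sum(ks == k) + 0.5)
                      / (1 + n_shuffles))
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapResult(observed, chance, p, p_mid, n, na, nb, k, method)


def consecutive_overlap(table: pd.DataFrame) -> list[Optional[float]]:
    """Per adjacent session pair (k, k+1): |pos_k n pos_{k+1}| / |pos_k|,
    over cells usable in both sessions; None when session k has no
    positives."""
    wide = _pivot(table)
    sessions = sorted(wide.columns)
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    out: list[Optional[float]] = []
    for s0, s1 in zip(sessions, sessions[1:]):
        sub = wide[[s0, s1]].dropna()
        sub = sub[(sub != ND).all(axis=1)]
        prev_pos = sub[s0] == ARC_POS
        if prev_pos.sum() == 0:
            out.append(None)
            continue
        both = prev_pos & (sub[s1] == ARC_POS)
        out.append(float(both.sum() / prev_pos.sum()))
    return out


@dataclass
class TreeNode:
    """One history node of a reexpression tree.

    ``history`` is the tuple of pos/neg outcomes so far; ``fraction`` is
    this cohort's share of the root population; ``p_next`` is the
    conditional probability of being Arc+ in the next session (None at the
    leaves)."""

    history: tuple[bool, ...]
    fraction: float
    n_cells: int
    p_next: Optional[float] = None
    children: dict = field(default_factory=dict)


def reexpression_tree(table: pd.DataFrame) -> TreeNode:
    """Binary tree of Arc expression histories.

    The cohort is the set of cells usable (non-ND) in *all* sessions; the
    first split is the fraction expressing Arc after the first session, and
    each deeper layer splits on the presence of a TS in the next session.
    Leaf fractions sum to 1 over the cohort.
    """
    wide = _pivot(table)
    sessions = sorted(wide.columns)
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    cohort = wide[(wide != ND).all(axis=1)].dropna()
    n_root = len(cohort)
    if n_root == 0:
        raise ValueError("empty cohort after ND exclusion")
    state = (cohort[sessions] == ARC_POS).to_numpy()

    def build(mask: np.ndarray, history: tuple[bool, ...]) -> TreeNode:
        n = int(mask.sum())
        node = TreeNode(history=history, fraction=n / n_root, n_cells=n)
        depth = len(history)
        if depth < len(sessions) and n > 0:
            nxt = state[:, depth]
            node.p_next = float((mask & nxt).sum() / n)
            node.children[True] = build(mask & nxt, history + (True,))
            node.children[False] = build(mask & ~nxt, history + (False,))
        return node

    return build(np.ones(n_root, dtype=bool), ())


def persistence_count(table: pd.DataFrame) -> tuple[pd.Series, Optional[float]]:
    """Histogram of per-cell Arc-expression counts and the fraction of
    cells positive in every session (among cells usable in all sessions)."""
    wide = _pivot(table)
    sessions = sorted(wide.columns)
    usable_all = wide[(wide != ND).all(axis=1)].dropna()
    counts = (usable_all[sessions] == ARC_POS).sum(axis=1)
    hist = counts.value_counts().sort_index()
    if len(usable_all) == 0:
        return hist, None
    persistent = float((counts == len(sessions)).sum() / len(usable_all))
    return hist, persistent
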