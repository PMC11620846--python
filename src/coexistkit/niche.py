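"""Niche breadth and overlap over binned resource gradients.

A resource gradient is an environmental variable cut into ordered levels
(the published scheme uses 11 per variable).  A species' niche profile is
the proportion of its importance value falling in each level; Shannon
entropy of the profile gives niche breadth B_S and the cosine-type Pianka
index O_ik gives pairwise overlap:

    B_S  = -sum_j P_ij ln P_ij
    O_ik = sum_j P_ij P_kj / sqrt(sum_j P_ij^2 * sum_j P_kj^2)

The plots themselves may serve as resource states ("overall level").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradientScheme",
    "bin_gradient",
    "niche_profiles",
    "shannon_breadth",
    "pianka_overlap",
    "overlap_matrix",
    "overlap_summary",
    "table6_scheme",
]


class UndefinedProfileError(ValueError):
    """Species has zero importance everywhere: niche profile undefined."""


@dataclass
class GradientScheme:
    """Ordered interval bins for one environmental variable.

    ``levels`` is a list of (lo, hi) pairs, half-open [lo, hi); the first
    level is open below (lo may be None/-inf) and the last open above.
    Published level tables may contain gaps between consecutive intervals
    (they were drawn from observed values): a value falling in a gap is
    assigned to the level whose nearest boundary is closest, ties going to
    the lower level.
    """

    variable: str
    levels: list[tuple[float | None, float | None]]

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError("a gradient scheme needs at least 2 levels")
        prev_hi = None
        for lo, hi in self.levels:
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"empty interval [{lo}, {hi})")
            if prev_hi is not None and lo is not None and lo < prev_hi:
                raise ValueError("overlapping gradient intervals")
            prev_hi = hi if hi is not None else prev_hi

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def assign(self, value: float) -> int:
        """1-based level for ``value``, applying the gap rule where needed."""
        if not np.isfinite(value):
            raise ValueError(f"non-finite gradient value {value}")
        for i, (lo, hi) in enumerate(self.levels):
            lo_ = -np.inf if lo is None or i == 0 else lo
            hi_ = np.inf if hi is None or i == len(self.levels) - 1 else hi
            if lo_ <= value < hi_:
                return i + 1
        # Value lies in a printed gap: nearest boundary wins, ties to lower.
        best, best_dist = None, np.inf
        for i, (lo, hi) in enumerate(self.levels):
            for bound in (lo, hi):
                if bound is None:
                    continue
                dist = abs(value - bound)
                if dist < best_dist - 1e-12:
                    best, best_dist = i + 1, dist
        if best is None:
            raise ValueError(f"value {value} not coverable by any level")
        return best


def table6_scheme(variable: str) -> GradientScheme:
    """The published 11-level scheme for pH, t_k or a_k."""
    from .fixtures import load_fixture

    table = load_fixture("gradient_levels")
    sub = table[table["variable"] == variable]
    if sub.empty:
        raise KeyError(f"no published gradient levels for {variable!r}")
    levels = [
        (None if pd.isna(lo) else float(lo), None if pd.isna(hi) else float(hi))
        for lo, hi in zip(sub["lo"], sub["hi"])
    ]
    return GradientScheme(variable, levels)


def bin_gradient(iv_matrix: pd.DataFrame, env_values: pd.Series,
                 scheme: GradientScheme):
    """Assign plots to gradient levels and average species IV within levels.

    ``iv_matrix`` is species x plot; ``env_values`` maps each plot to its
    value of the gradient variable.  Returns (plot->level Series,
    species x level DataFrame of mean IV; levels with no plots get 0).
    """
    missing = [p for p in iv_matrix.columns if p not in env_values.index]
    if missing:
        raise ValueError(f"plots without environment values: {missing}")
    levels = pd.Series(
        {p: scheme.assign(float(env_values[p])) for p in iv_matrix.columns},
        name=scheme.variable,
    )
    level_iv = pd.DataFrame(
        0.0, index=iv_matrix.index, columns=range(1, scheme.n_levels + 1)
    )
    for lev, plots in levels.groupby(levels).groups.items():
        level_iv[lev] = iv_matrix[list(plots)].mean(axis=1)
    return levels, level_iv


def niche_profiles(state_iv: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise species x state IVs to proportions P_ij summing to 1."""
    totals = state_iv.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise UndefinedProfileError(
            f"species with zero total importance: {list(zero.index)}")
    return state_iv.div(totals, axis=0)


def shannon_breadth(profile) -> float:
    """Shannon niche breadth B_S (nats) of a proportion profile; 0 ln 0 := 0."""
    p = np.asarray(profile, dtype=float)
    if p.sum() <= 0:
        raise UndefinedProfileError("all-zero profile")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("profile proportions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def pianka_overlap(profile_i, profile_k) -> float:
    """Pianka overlap O_ik of two proportion profiles on shared states."""
    pi = np.asarray(profile_i, dtype=float)
    pk = np.asarray(profile_k, dtype=float)
    if pi.shape != pk.shape:
        raise ValueError("profiles defined over different resource states")
    denom = np.sqrt((pi ** 2).sum() * (pk ** 2).sum())
    if denom == 0:
        raise UndefinedProfileError("all-zero profile in overlap")
    return float(np.dot(pi, pk) / denom)


def overlap_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric species x species Pianka overlap matrix (unit diagonal)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 species")
    p = profiles.values.astype(float)
    norms = np.sqrt((p ** 2).sum(axis=1))
    if (norms == 0).any():
        raise UndefinedProfileError("all-zero profile in overlap matrix")
    m = (p @ p.T) / np.outer(norms, norms)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(np.clip(m, 0.0, 1.0),
                        index=profiles.index, columns=profiles.index)


def overlap_summary(m: pd.DataFrame, threshold: float = 0.5) -> dict:
    """Counts and moments of the unordered off-diagonal overlap pairs."""
    vals = m.values[np.triu_indices(len(m), k=1)]
    n = len(vals)
    n_ge = int((vals >= threshold).sum())
    return {
        "n_pairs": n,
        "n_ge": n_ge,
        "n_lt": n - n_ge,
        "pct_ge": 100.0 * n_ge / n,
        "pct_lt": 100.0 * (n - n_ge) / n,
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }
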