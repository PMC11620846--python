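"""Interspecific association tests on plot-level occupancy and abundance.

Three complementary views of pairwise association are provided, plus a
community-wide test:

* variance ratio (VR) of plot species richness against the sum of per
  species binomial variances, with W = N * VR tested against chi-square
  bounds — an overall association test;
* Yates-corrected chi-square on each pair's 2x2 presence table, classified
  at the df=1 critical values 3.841 (p<0.05) and 6.635 (p<0.01);
* Pearson and Spearman correlation of plot-level abundances with two-sided
  t-approximation p-values.

Cell naming for the 2x2 table follows the survey convention: ``b`` = plots
with both species, ``c`` = plots with neither, ``a`` and ``d`` = plots with
exactly one.  The association sign compares the observed joint-presence
count ``b`` with its independence expectation from the margins, so it does
not depend on that labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "to_presence",
    "variance_ratio_test",
    "yates_chi2",
    "pairwise_association",
    "correlation_tests",
    "association_summary",
    "assign_species_groups",
    "VarianceRatioResult",
    "PairAssociation",
    "CHI2_P05",
    "CHI2_P01",
]

CHI2_P05 = 3.841
CHI2_P01 = 6.635


@dataclass
class VarianceRatioResult:
    n_plots: int
    n_species: int
    richness: np.ndarray
    mean_richness: float
    s2_t: float
    d2_t: float
    vr: float
    w: float
    lower: float
    upper: float
    verdict: str


@dataclass
class PairAssociation:
    species_i: str
    species_k: str
    a: int
    b: int
    c: int
    d: int
    chi2: float | None
    sign: str          # '+', '-', or 'none'
    significance: str  # 'extremely-significant', 'significant',
                       # 'not-significant', 'no-association'


def to_presence(iv_or_records, species: list[str] | None = None) -> pd.DataFrame:
    """Species x plot binary occupancy from an IV matrix or quadrat records.

    A species is present in a plot if it occurs in any of its quadrats.
    ``species`` restricts and orders the rows (e.g. the dominant set).
    """
    if isinstance(iv_or_records, pd.DataFrame):
        mat = (iv_or_records > 0).astype(int)
    else:
        from .importance import compute_importance

        mat = (compute_importance(iv_or_records).iv_matrix > 0).astype(int)
    if species is not None:
        if not len(species):
            raise ValueError("empty species subset")
        missing = [s for s in species if s not in mat.index]
        if missing:
            raise ValueError(f"species absent from all plots: {missing}")
        mat = mat.loc[species]
    absent = mat.index[mat.sum(axis=1) == 0]
    if len(absent):
        raise ValueError(f"species absent from all plots: {list(absent)}")
    return mat


def variance_ratio_test(presence: pd.DataFrame, alpha: float = 0.05) -> VarianceRatioResult:
    """Schluter's variance-ratio test of overall association.

    VR = S_T^2 / delta_T^2 where S_T^2 is the (population) variance of plot
    richness T_j and delta_T^2 = sum_i p_i (1 - p_i) with p_i the occupancy
    frequency of species i.  W = N * VR is compared with the chi-square
    quantiles at N degrees of freedom: W inside the (alpha, 1 - alpha)
    quantile interval means the overall association is not significant.
    """
    p = presence.values.astype(float)
    n_species, n_plots = p.shape
    if n_species < 2 or n_plots < 2:
        raise ValueError("need at least 2 species and 2 plots")
    t_j = p.sum(axis=0)
    t_bar = t_j.mean()
    s2_t = float(((t_j - t_bar) ** 2).mean())
    occ = p.mean(axis=1)
    d2_t = float((occ * (1 - occ)).sum())
    if d2_t == 0:
        raise ValueError("degenerate presence matrix: every species in all or no plots")
    vr = s2_t / d2_t
    w = n_plots * vr
    lower = float(stats.chi2.ppf(alpha, n_plots))
    upper = float(stats.chi2.ppf(1 - alpha, n_plots))
    if lower < w < upper:
        verdict = "not-significant"
    elif vr > 1:
        verdict = "significant-positive"
    else:
        verdict = "significant-negative"
    return VarianceRatioResult(n_plots, n_species, t_j, float(t_bar),
                               s2_t, d2_t, float(vr), float(w),
                               lower, upper, verdict)


def yates_chi2(a: int, b: int, c: int, d: int,
               species_i: str = "i", species_k: str = "k") -> PairAssociation:
    """Yates-corrected chi-square for one species pair's 2x2 table.

    chi2 = N (|ad - bc| - 0.5 N)^2 / [(a+b)(b+d)(c+d)(a+c)] with b = both
    present, c = neither, a/d = exactly one.  If any marginal product is
    zero the statistic is undefined and the pair is classed
    'no-association'.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative 2x2 cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty 2x2 table")
    margins = (a + b) * (b + d) * (c + d) * (a + c)
    if margins == 0:
        return PairAssociation(species_i, species_k, a, b, c, d,
                               None, "none", "no-association")
    expected_b = (a + b) * (b + d) / n
    sign = "+" if b > expected_b else ("-" if b < expected_b else "none")
    chi2 = n * (abs(a * d - b * c) - 0.5 * n) ** 2 / margins
    if chi2 >= CHI2_P01:
        cls = "extremely-significant"
    elif chi2 >= CHI2_P05:
        cls = "significant"
    else:
        cls = "not-significant"
    return PairAssociation(species_i, species_k, a, b, c, d,
                           float(chi2), sign, cls)


def pair_cells(row_i: np.ndarray, row_k: np.ndarray) -> tuple[int, int, int, int]:
    """2x2 cells (a, b, c, d) from two binary occupancy rows."""
    b = int(((row_i == 1) & (row_k == 1)).sum())
    c = int(((row_i == 0) & (row_k == 0)).sum())
    a = int(((row_i == 1) & (row_k == 0)).sum())
    d = int(((row_i == 0) & (row_k == 1)).sum())
    return a, b, c, d


def pairwise_association(presence: pd.DataFrame):
    """Yates chi-square over all unordered species pairs, with a summary."""
    if len(presence) < 2:
        raise ValueError("need at least 2 species")
    pairs = []
    for si, sk in combinations(presence.index, 2):
        a, b, c, d = pair_cells(presence.loc[si].values, presence.loc[sk].values)
        pairs.append(yates_chi2(a, b, c, d, si, sk))
    return pairs, association_summary(pairs)


def association_summary(pairs: list[PairAssociation]) -> dict:
    """Table-8-style tally of association classes by sign."""
    counts = {
        "positive": {"extremely-significant": 0, "significant": 0, "not-significant": 0},
        "negative": {"extremely-significant": 0, "significant": 0, "not-significant": 0},
        "no-association": 0,
    }
    for p in pairs:
        if p.significance == "no-association":
            counts["no-association"] += 1
        elif p.sign == "+":
            counts["positive"][p.significance] += 1
        elif p.sign == "-":
            counts["negative"][p.significance] += 1
        else:  # sign 'none' with a defined statistic: tally as no-association
            counts["no-association"] += 1
    n_pos = sum(counts["positive"].values())
    n_neg = sum(counts["negative"].values())
    n_sig = (counts["positive"]["significant"]
             + counts["positive"]["extremely-significant"]
             + counts["negative"]["significant"]
             + counts["negative"]["extremely-significant"])
    total = len(pairs)
    return {
        "counts": counts,
        "n_pairs": total,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "pos_neg_ratio": n_pos / n_neg if n_neg else np.inf,
        "significance_rate_pct": 100.0 * n_sig / total if total else 0.0,
    }


def _star_class(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _corr_significance(p: float) -> str:
    if p < 0.01:
        return "extremely-significant"
    if p < 0.05:
        return "significant"
    return "not-significant"


def correlation_tests(abundance: pd.DataFrame):
    """Pearson and Spearman correlation matrices over species abundances.

    ``abundance`` is species x plot counts (plot-level sums).  Spearman uses
    mid-ranks, so it equals Pearson on ranks and stays in [-1, 1] under
    ties.  Two-sided p-values use the t approximation with N-2 df.  Returns
    (DataFrame of per-pair results, {'pearson': summary, 'spearman':
    summary}) with summaries in the same form as ``association_summary``.
    """
    n = abundance.shape[1]
    if n < 3:
        raise ValueError("need at least 3 plots for correlation tests")
    species = list(abundance.index)
    x = abundance.values.astype(float)
    ranks = pd.DataFrame(x.T).rank().values.T  # mid-ranks per species
    rows = []
    for i, k in combinations(range(len(species)), 2):
        row = {"species_i": species[i], "species_k": species[k]}
        for name, data in (("pearson", x), ("spearman", ranks)):
            xi, xk = data[i], data[k]
            if np.std(xi) == 0 or np.std(xk) == 0:
                row[f"r_{name}"] = np.nan
                row[f"p_{name}"] = np.nan
                row[f"stars_{name}"] = ""
                continue
            r = float(np.corrcoef(xi, xk)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = float(2 * stats.t.sf(abs(t), n - 2))
            row[f"r_{name}"] = r
            row[f"p_{name}"] = p
            row[f"stars_{name}"] = _star_class(p)
        rows.append(row)
    table = pd.DataFrame(rows)
    summaries = {}
    for name in ("pearson", "spearman"):
        counts = {
            "positive": {"extremely-significant": 0, "significant": 0, "not-significant": 0},
            "negative": {"extremely-significant": 0, "significant": 0, "not-significant": 0},
            "no-association": 0,
        }
        for _, row in table.iterrows():
            r, p = row[f"r_{name}"], row[f"p_{name}"]
            if not np.isfinite(r) or r == 0:
                counts["no-association"] += 1
            else:
                side = "positive" if r > 0 else "negative"
                counts[side][_corr_significance(p)] += 1
        n_pos = sum(counts["positive"].values())
        n_neg = sum(counts["negative"].values())
        n_sig = sum(counts[s][c] for s in ("positive", "negative")
                    for c in ("significant", "extremely-significant"))
        summaries[name] = {
            "counts": counts,
            "n_pairs": len(table),
            "n_positive": n_pos,
            "n_negative": n_neg,
            "pos_neg_ratio": n_pos / n_neg if n_neg else np.inf,
            "significance_rate_pct": 100.0 * n_sig / len(table) if len(table) else 0.0,
        }
    return table, summaries


def assign_species_groups(scores: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cluster species into ecological groups from their ordination scores.

    Agglomerative clustering (average linkage, Euclidean) on the species'
    signed scores along the selected environmental axes.  This is a
    reproducible stand-in for the expert grouping practitioners draw by eye
    from an ordination biplot; outputs label it as heuristic.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} species available")
    if k == 1:
        return pd.Series(1, index=scores.index, name="group")
    z = linkage(scores.values.astype(float), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="group")
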