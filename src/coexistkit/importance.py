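"""Species importance values and dominant-species screening.

The importance value (IV%) of a species in a plot is the mean of its
relative abundance, relative frequency and relative coverage, each expressed
as a percentage of the plot total:

    IV% = (relative abundance + relative frequency + relative coverage) / 3

Relative frequency uses the fraction of the plot's quadrats occupied by the
species, normalised across species so the column sums to 100 within each
plot.  Species-level mean IV averages over *all* plots, counting zero where
the species is absent, so the species means themselves sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QuadratRecord

__all__ = ["ImportanceTable", "compute_importance", "screen_dominant"]


@dataclass
class ImportanceTable:
    """Per-(species, plot) IV components plus species-level means.

    ``per_plot`` is a tidy DataFrame with columns species, plot,
    relative_abundance, relative_frequency, relative_coverage, iv (all %).
    ``mean_iv`` is a Series over species (mean over all plots, %).
    ``iv_matrix`` pivots iv to species x plot with zeros for absences.
    """

    per_plot: pd.DataFrame
    mean_iv: pd.Series

    @property
    def iv_matrix(self) -> pd.DataFrame:
        m = self.per_plot.pivot_table(index="species", columns="plot",
                                      values="iv", fill_value=0.0,
                                      aggfunc="sum")
        return m.reindex(self.mean_iv.index)

    @property
    def species(self) -> list[str]:
        return list(self.mean_iv.index)


def compute_importance(records: list[QuadratRecord]) -> ImportanceTable:
    """Compute the per-plot importance table from quadrat records.

    Within each plot, abundance and coverage are summed over the plot's
    quadrats per species; frequency is the number of occupied quadrats.
    Each component is normalised to percent across the species present in
    the plot.
    """
    if not records:
        raise ValueError("no records supplied")
    df = pd.DataFrame(
        {
            "plot": [r.plot_id for r in records],
            "quadrat": [r.quadrat_id for r in records],
            "species": [r.species for r in records],
            "abundance": [r.abundance for r in records],
            "coverage": [r.coverage for r in records],
        }
    )
    rows = []
    plots = sorted(df["plot"].unique())
    for plot, sub in df.groupby("plot"):
        ab = sub.groupby("species")["abundance"].sum()
        cov = sub.groupby("species")["coverage"].sum()
        freq = sub.groupby("species")["quadrat"].nunique()
        if ab.sum() == 0:
            raise ValueError(f"plot {plot!r} has zero total abundance")
        ra = 100.0 * ab / ab.sum()
        rf = 100.0 * freq / freq.sum()
        rc = 100.0 * cov / cov.sum() if cov.sum() > 0 else cov * 0.0
        for sp in ab.index:
            rows.append(
                {
                    "species": sp, "plot": plot,
                    "relative_abundance": ra[sp],
                    "relative_frequency": rf[sp],
                    "relative_coverage": rc[sp],
                    "iv": (ra[sp] + rf[sp] + rc[sp]) / 3.0,
                }
            )
    per_plot = pd.DataFrame(rows)
    # Mean over all plots, absences counted as zero.
    pivot = per_plot.pivot_table(index="species", columns="plot", values="iv",
                                 fill_value=0.0, aggfunc="sum")
    pivot = pivot.reindex(columns=plots, fill_value=0.0)
    mean_iv = pivot.mean(axis=1).sort_values(ascending=False)
    mean_iv.name = "mean_iv"
    return ImportanceTable(per_plot=per_plot, mean_iv=mean_iv)


def screen_dominant(iv: ImportanceTable | pd.Series, threshold: float = 1.0) -> list[str]:
    """Species with mean IV strictly above ``threshold`` (%), most dominant first."""
    mean_iv = iv.mean_iv if isinstance(iv, ImportanceTable) else iv
    sel = mean_iv[mean_iv > threshold].sort_values(ascending=False)
    return list(sel.index)
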