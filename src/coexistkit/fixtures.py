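"""Packaged reference tables from the island shrub-layer survey.

Five small tables ship with the package, stored at the precision they were
published at:

- ``plots``: topography, crown density, isolation and climate for the 40
  survey plots (aspect as compass azimuth).
- ``soil``: nine soil-chemistry indicators for the same 40 plots.
- ``dominant_iv``: the 23 dominant shrub species with their mean importance
  values (%) and Shannon niche breadths on four resource gradients.
- ``gradient_levels``: the 11-level binning of pH, total potassium and
  available potassium used for gradient niche analysis.
- ``overlap_matrix``: the published Pianka overlap semi-matrix over the 23
  dominant species, reflected to a full symmetric matrix.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = ["load_fixture", "FIXTURES"]

FIXTURES = ("plots", "soil", "dominant_iv", "gradient_levels", "overlap_matrix")


def _data_path(name: str):
    return importlib.resources.files("coexistkit").joinpath("data", name)


def load_fixture(name: str):
    """Return one of the packaged tables as a pandas object.

    ``overlap_matrix`` is returned as a symmetric species-by-species
    DataFrame with unit diagonal; all others as the stored table with the
    plot / species column as index.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    if name == "overlap_matrix":
        lower = pd.read_csv(_data_path("overlap_lower.csv"), index_col=0)
        species = list(lower.columns) + [lower.index[-1]]
        n = len(species)
        m = np.eye(n)
        for i, sp_row in enumerate(lower.index):
            ri = species.index(sp_row)
            for sp_col, v in lower.loc[sp_row].items():
                if pd.notna(v):
                    ci = species.index(sp_col)
                    m[ri, ci] = m[ci, ri] = float(v)
        return pd.DataFrame(m, index=species, columns=species)
    fname = {"plots": "plots.csv", "soil": "soil.csv",
             "dominant_iv": "dominant_iv.csv",
             "gradient_levels": "gradient_levels.csv"}[name]
    index_col = None if name == "gradient_levels" else 0
    return pd.read_csv(_data_path(fname), index_col=index_col)
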