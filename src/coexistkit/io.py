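"""Reading and validation of quadrat records, environment tables and phylogenies.

All tabular input is plain UTF-8 CSV with a header row.  Quadrat records
carry one row per (plot, quadrat, species) with an individual count and a
percent cover; zero-abundance rows are dropped on load.  Environment tables
follow the survey schema: nine soil-chemistry columns plus topography,
crown density, isolation distances and climate.  Slope aspect may be given
either as a category name (Adret, Semi-adret, Semi-ubac, Ubac) or as a
compass azimuth in degrees, which is mapped onto the four categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QuadratRecord",
    "PlotEnvironment",
    "PhyloDistances",
    "SchemaError",
    "ValidationError",
    "aspect_category",
    "read_records",
    "read_environment",
    "read_newick_distances",
    "read_distance_matrix",
    "write_records",
    "write_environment",
]


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A value violates a domain invariant (with the offending row)."""


@dataclass(frozen=True)
class QuadratRecord:
    plot_id: str
    quadrat_id: str
    species: str
    abundance: int
    coverage: float
    height: float | None = None


# Ordinal aspect codes: 1 = sun-facing (adret) ... 4 = shade-facing (ubac).
ASPECT_CODES = {"Adret": 1, "Semi-adret": 2, "Semi-ubac": 3, "Ubac": 4}

# Azimuth intervals per category, closed on the lower bound, open above.
_ASPECT_RANGES = [
    (157.5, 247.5, "Adret"),
    (112.5, 157.5, "Semi-adret"),
    (247.5, 292.5, "Semi-adret"),
    (67.5, 112.5, "Semi-ubac"),
    (292.5, 337.5, "Semi-ubac"),
    (0.0, 67.5, "Ubac"),
    (337.5, 360.0, "Ubac"),
]


def aspect_category(value) -> str:
    """Map an aspect token (category name or azimuth degrees) to a category.

    Azimuths are interpreted on [0, 360); each interval is closed on its
    lower bound and open on the upper, so 0 deg maps to Ubac and 157.5 deg
    to Adret.
    """
    if isinstance(value, str):
        token = value.strip()
        for name in ASPECT_CODES:
            if token.lower() == name.lower():
                return name
        try:
            value = float(token)
        except ValueError:
            raise ValidationError(f"unknown aspect token {token!r}") from None
    az = float(value) % 360.0
    for lo, hi, name in _ASPECT_RANGES:
        if lo <= az < hi:
            return name
    if az == 360.0 or az == 0.0:  # pragma: no cover - folded by modulo
        return "Ubac"
    raise ValidationError(f"azimuth {az} not coverable by aspect ranges")


@dataclass
class PlotEnvironment:
    """Per-plot environment row; soil chemistry plus topography and climate.

    ``slope_aspect`` is stored as the ordinal code 1-4 (adret to ubac);
    ``aspect_name`` keeps the category label.
    """

    plot_id: str
    values: dict = field(default_factory=dict)

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None


@dataclass
class PhyloDistances:
    """Patristic distances between taxa (symmetric, zero diagonal)."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxa in distance matrix")
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if (self.d < 0).any():
            raise ValidationError("negative patristic distance")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("nonzero diagonal in distance matrix")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])

    def submatrix(self, taxa: list[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa]
        return self.d[np.ix_(idx, idx)]


_RECORD_COLUMNS = ["plot", "quadrat", "species", "abundance", "coverage"]


def read_records(path) -> list[QuadratRecord]:
    """Read quadrat survey records from CSV.

    Required columns: plot, quadrat, species, abundance, coverage; optional
    height.  Labels are whitespace-trimmed and case-sensitive.  Rows with
    abundance 0 are dropped; duplicate (plot, quadrat, species) keys and
    negative counts or covers are errors.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in _RECORD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    records: list[QuadratRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        plot = str(row["plot"]).strip()
        quad = str(row["quadrat"]).strip()
        sp = str(row["species"]).strip()
        try:
            ab = float(row["abundance"])
            cov = float(row["coverage"])
        except (TypeError, ValueError):
            raise ValidationError(f"non-numeric abundance/coverage at row {i}")
        if ab < 0:
            raise ValidationError(f"negative abundance at row {i}")
        if not ab.is_integer():
            raise ValidationError(f"non-integer abundance at row {i}")
        if cov < 0 or cov > 100:
            raise ValidationError(f"coverage outside [0, 100] at row {i}")
        if ab == 0:
            continue
        key = (plot, quad, sp)
        if key in seen:
            raise ValidationError(f"duplicate (plot,quadrat,species) {key} at row {i}")
        seen.add(key)
        height = None
        if "height" in df.columns and pd.notna(row["height"]):
            height = float(row["height"])
            if height < 0:
                raise ValidationError(f"negative height at row {i}")
        records.append(QuadratRecord(plot, quad, sp, int(ab), cov, height))
    return records


_ENV_NUMERIC = [
    "pH", "t_k", "a_k", "t_p", "a_p", "t_n", "a_n", "som", "salt",
    "elevation", "slope", "crown_density",
    "dist_coastline", "dist_nearest_island", "dist_mainland",
    "air_temperature", "precipitation", "wind_speed",
]
_TOPO_CODES = {"Low": 1, "Middle": 2, "Up": 3}


def read_environment(path) -> list[PlotEnvironment]:
    """Read a per-plot environment CSV.

    Any subset of the numeric schema columns may be present; ``aspect``
    (azimuth or category) is converted to an ordinal ``slope_aspect`` code
    and ``topographic_position`` (Low/Middle/Up) to 1-3.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    if "plot" not in df.columns:
        raise SchemaError(f"missing required column 'plot' in {path}")
    out = []
    for i, row in df.iterrows():
        vals: dict = {}
        for col in _ENV_NUMERIC:
            if col in df.columns:
                v = float(row[col])
                if not np.isfinite(v):
                    raise ValidationError(f"non-finite {col} at row {i + 2}")
                vals[col] = v
        # keep any extra numeric columns (e.g. simulated gradients)
        known = set(_ENV_NUMERIC) | {"plot", "aspect", "topographic_position"}
        for col in df.columns:
            if col not in known and pd.api.types.is_numeric_dtype(df[col]):
                v = float(row[col])
                if not np.isfinite(v):
                    raise ValidationError(f"non-finite {col} at row {i + 2}")
                vals[col] = v
        if "crown_density" in vals and not (0 <= vals["crown_density"] <= 1):
            raise ValidationError(f"crown_density outside [0,1] at row {i + 2}")
        if "aspect" in df.columns:
            name = aspect_category(row["aspect"])
            vals["aspect_name"] = name
            vals["slope_aspect"] = ASPECT_CODES[name]
        if "topographic_position" in df.columns:
            pos = str(row["topographic_position"]).strip()
            if pos not in _TOPO_CODES:
                raise ValidationError(f"unknown topographic position {pos!r} at row {i + 2}")
            vals["topographic_position"] = _TOPO_CODES[pos]
            vals["topographic_position_name"] = pos
        out.append(PlotEnvironment(str(row["plot"]).strip(), vals))
    return out


def environment_frame(envs: list[PlotEnvironment]) -> pd.DataFrame:
    """Tidy numeric DataFrame (plots as index) from environment rows."""
    rows = {}
    for e in envs:
        rows[e.plot_id] = {k: v for k, v in e.values.items() if isinstance(v, (int, float))}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_newick_distances(path) -> PhyloDistances:
    """Patristic (branch-length sum) leaf-to-leaf distances from a newick tree."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    leaves = tree.leaf_node_iter()
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValidationError("unlabeled leaf in newick tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValidationError("missing branch length in newick tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PhyloDistances(labels, d)


def read_distance_matrix(path) -> PhyloDistances:
    """Square CSV distance matrix with taxa as header and first column."""
    df = pd.read_csv(path, index_col=0)
    taxa = [str(t).strip() for t in df.columns]
    if [str(t).strip() for t in df.index] != taxa:
        raise SchemaError("distance matrix rows and columns disagree")
    return PhyloDistances(taxa, df.values.astype(float))


def write_records(records: list[QuadratRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "plot": r.plot_id, "quadrat": r.quadrat_id, "species": r.species,
            "abundance": r.abundance, "coverage": r.coverage,
        }
        if r.height is not None:
            row["height"] = r.height
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_environment(envs: list[PlotEnvironment], path) -> None:
    rows = []
    for e in envs:
        row = {"plot": e.plot_id}
        for k, v in e.values.items():
            if k == "aspect_name":
                row["aspect"] = v
            elif k == "topographic_position_name":
                row["topographic_position"] = v
            elif k in ("slope_aspect", "topographic_position"):
                continue
            else:
                row[k] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
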