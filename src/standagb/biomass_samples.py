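"""Per-tree allometric biomass and 30-m grid AGB sample construction.

Per-tree aboveground biomass follows species-specific piecewise power-law
allometry of the form ``Ma = c·D^p·H^q`` (Ma in kg, D in cm, H in m), with
separate coefficient sets for small (D < 5 cm) and large (D ≥ 5 cm) stems,
after the Chinese national tree-biomass standard GB/T 43648-2024 for the
three major afforestation species of the Inner Mongolia plantations.

Grid samples aggregate per-tree biomass over 30-m cells:
``AGB = Σ Ma_i / S`` with S the cell area, expressed in g/m².  Cells that
touch a stand boundary, intersect an exclusion mask (roads, buildings), or
mix species are edge-flagged and withheld from the sample set so training
samples stay spectrally homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .height_dbh import FitMetrics, compute_metrics
from .raster import GridSpec

__all__ = [
    "ALLOMETRY",
    "SPECIES",
    "SMALL_TREE_DBH_CM",
    "tree_agb",
    "AGBSample",
    "SampleSet",
    "build_samples",
    "validate_samples",
    "samples_to_frame",
]

#: D threshold (cm) between the small- and large-stem coefficient branches.
#: The boundary itself belongs to the large-stem branch (D ≥ 5 cm).
SMALL_TREE_DBH_CM = 5.0

#: Species → {branch → (c, p, q)} for Ma = c·D^p·H^q, plus the published
#: fit statistics of the source models (metadata only, not recomputable).
ALLOMETRY: dict[str, dict] = {
    "poplar": {
        "small": (0.09585, 1.67005, 0.59163),
        "large": (0.05559, 2.00861, 0.59163),
        "r2": 0.95,
        "mpe_pct": 4.23,
    },
    "mongolian_scots_pine": {
        "small": (0.17577, 1.50770, 0.34775),
        "large": (0.05460, 2.23412, 0.34775),
        "r2": 0.94,
        "mpe_pct": 5.10,
    },
    "chinese_red_pine": {
        "small": (0.39835, 1.07994, 0.43610),
        "large": (0.067765, 2.18050, 0.43610),
        "r2": 0.94,
        "mpe_pct": 5.12,
    },
}

SPECIES = tuple(ALLOMETRY)


def tree_agb(species: str, dbh_cm, height_m):
    """Per-tree aboveground biomass Ma (kg) from DBH (cm) and height (m).

    Vectorized over ``dbh_cm`` / ``height_m``; the coefficient branch is
    chosen elementwise by the D < 5 cm / D ≥ 5 cm rule.
    """
    if species not in ALLOMETRY:
        raise KeyError(
            f"unknown species {species!r}; known species: {', '.join(SPECIES)}"
        )
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("DBH and height must be positive")
    eq = ALLOMETRY[species]
    cs, ps, qs = eq["small"]
    cl, pl, ql = eq["large"]
    small = d < SMALL_TREE_DBH_CM
    ma = np.where(small, cs * d**ps * h**qs, cl * d**pl * h**ql)
    return float(ma) if ma.ndim == 0 else ma


@dataclass
class AGBSample:
    """One 30-m grid cell of the biomass sample set."""

    cell_row: int
    cell_col: int
    x_center: float
    y_center: float
    agb_g_m2: float
    n_trees: int
    species: str
    s_m2: float
    edge_flag: bool = False


@dataclass
class SampleSet:
    samples: list[AGBSample]
    edge_cells: list[AGBSample] = field(default_factory=list)
    n_trees_excluded: int = 0

    @property
    def n_edge(self) -> int:
        return len(self.edge_cells)


def samples_to_frame(samples) -> pd.DataFrame:
    cols = ["cell_row", "cell_col", "x_center", "y_center", "species",
            "n_trees", "agb_g_m2"]
    rows = [{c: getattr(s, c) for c in cols} for s in samples]
    return pd.DataFrame(rows, columns=cols)


def build_samples(trees: pd.DataFrame, grid: GridSpec, stands,
                  exclusion_mask=None) -> SampleSet:
    """Aggregate per-tree AGB into grid-cell samples with edge filtering.

    Parameters
    ----------
    trees
        Tree list with columns x, y, species, dbh_cm, height_m and agb_kg;
        rows with missing DBH/AGB (e.g. flagged by model inversion) are
        excluded and counted.
    grid
        Target sample grid (normally the 30-m feature grid); trees are
        assigned to the half-open cell containing their apex.
    stands
        Sequence of ``(polygon, species)`` stand geometries; a cell not
        fully contained in a single stand is edge-flagged.
    exclusion_mask
        Optional iterable of polygons (roads, buildings); any intersection
        edge-flags the cell.

    Returns a :class:`SampleSet`: clean interior samples, edge-flagged
    cells (with their internally computed AGB, so mass is accounted for),
    and the excluded-tree count.  Cells containing no trees are omitted.
    """
    required = {"x", "y", "species", "agb_kg"}
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"tree table lacks columns: {sorted(missing)}")

    usable = trees.dropna(subset=["agb_kg"])
    n_excluded = len(trees) - len(usable)

    cell_area = grid.cell * grid.cell
    row, col = grid.index_of(usable["x"].to_numpy(), usable["y"].to_numpy())
    inside = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    usable = usable.iloc[np.flatnonzero(inside)]
    row, col = row[inside], col[inside]

    samples: list[AGBSample] = []
    edge_cells: list[AGBSample] = []
    exclusion_mask = list(exclusion_mask or [])
    grouped = usable.groupby([row, col], sort=True)
    for (r, c), cell_trees in grouped:
        x0 = grid.x0 + c * grid.cell
        y1 = grid.y0 - r * grid.cell
        cell_box = box(x0, y1 - grid.cell, x0 + grid.cell, y1)
        species = cell_trees["species"].unique()
        agb = float(cell_trees["agb_kg"].sum()) * 1000.0 / cell_area

        interior = any(poly.covers(cell_box) for poly, _ in stands)
        excluded = any(poly.intersects(cell_box) for poly in exclusion_mask)
        edge = (not interior) or excluded or len(species) > 1

        sample = AGBSample(
            cell_row=int(r), cell_col=int(c),
            x_center=x0 + grid.cell / 2, y_center=y1 - grid.cell / 2,
            agb_g_m2=agb, n_trees=len(cell_trees),
            species=species[0] if len(species) == 1 else "mixed",
            s_m2=cell_area, edge_flag=edge,
        )
        (edge_cells if edge else samples).append(sample)

    return SampleSet(samples=samples, edge_cells=edge_cells,
                     n_trees_excluded=n_excluded)


def validate_samples(samples, field_points) -> FitMetrics:
    """Score sample AGB against independent field AGB on overlapping cells.

    ``field_points`` is an iterable of ``((cell_row, cell_col), agb_g_m2)``;
    at least two overlapping cells are required.
    """
    by_cell = {(s.cell_row, s.cell_col): s.agb_g_m2 for s in samples}
    pred, obs = [], []
    for cell, agb in field_points:
        if tuple(cell) in by_cell:
            pred.append(by_cell[tuple(cell)])
            obs.append(agb)
    if len(pred) < 2:
        raise ValueError(
            f"need at least 2 overlapping cells, found {len(pred)}"
        )
    return compute_metrics(pred, obs, k=2)
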