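"""Georeferenced synthetic plantation scenes with known ground truth.

The generator emulates the data sources of a sparse-plantation biomass
survey: single-species rectangular stands on gentle terrain, a tree list
whose height–DBH pairs lie exactly on a known species growth curve, a
drone-LiDAR-like point cloud (ground returns on the terrain surface, crown
returns on conical or paraboloid crown envelopes, one guaranteed apex
return per tree), and a 13-band reflectance image whose signal bands are
stated monotone logistic functions of the local true AGB density plus
Gaussian noise.  Everything shares one local projected CRS in meters, and
every stochastic draw flows from a single seeded generator, so a scene is
byte-reproducible from its configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .biomass_samples import SPECIES, tree_agb
from .height_dbh import hd_inverse
from .point_cloud import CLASS_CODES, PointCloud
from .raster import GridSpec, Raster
from .spectral_features import ALL_BAND_NAMES

__all__ = [
    "DEFAULT_HD_TRUTH",
    "BAND_PROFILES",
    "SIGNAL_FEATURES",
    "SceneConfig",
    "TruthTable",
    "Scene",
    "generate_scene",
    "write_scene",
    "read_scene",
    "terrain_elevation",
]

#: Conifers get conical crowns; the broadleaf poplar gets paraboloids.
CONIFERS = ("mongolian_scots_pine", "chinese_red_pine")

#: True per-species height–DBH curves (form, a, b) used by the generator.
#: One curve per supported species, with magnitudes typical of young
#: plantation stands (H 4–12 m, D roughly 3–25 cm).
DEFAULT_HD_TRUTH: dict[str, tuple[str, float, float]] = {
    "poplar": ("bates", 22.0, 9.0),
    "mongolian_scots_pine": ("power", 1.2, 0.7),
    "chinese_red_pine": ("linear", 1.5, 0.6),
}

#: Reflectance model: band value = base + gain · L(AGB) + noise, with
#: L the logistic in :func:`_agb_logistic`.  NIR and red-edge bands rise
#: with biomass, red/SWIR and blue fall; B1/B9/B10 carry no signal.
BAND_PROFILES: dict[str, tuple[float, float]] = {
    "B1": (0.08, 0.0), "B2": (0.10, -0.05), "B3": (0.11, 0.02),
    "B4": (0.20, -0.12), "B5": (0.08, 0.10), "B6": (0.10, 0.22),
    "B7": (0.12, 0.25), "B8": (0.15, 0.30), "B9": (0.05, 0.0),
    "B10": (0.01, 0.0), "B11": (0.30, -0.18), "B12": (0.25, -0.15),
    "B8A": (0.16, 0.30),
}

#: Predictor-stack layers that carry the generated AGB signal (everything
#: derived from a band with non-zero gain; only the terrain layers do not).
SIGNAL_FEATURES = tuple(
    n for n in (
        "B2", "B3", "B4", "B5", "B6", "B7", "B8", "B11", "B12",
        "NDVI", "RENDVI", "NDWI", "EVI", "RVI", "DVI", "VDVI", "SAVI",
        "MSAVI", "NBR", "NDMI", "TCB", "TCG", "TCW",
    )
)

#: Logistic midpoint/scale (g/m²) chosen so the curve stays well away from
#: saturation over the cell-AGB envelope sparse young stands produce
#: (roughly tens to a couple of thousand g/m²).
_LOGISTIC_MID = 500.0
_LOGISTIC_SCALE = 350.0


def _agb_logistic(agb_g_m2):
    return 1.0 / (1.0 + np.exp(-(np.asarray(agb_g_m2, float) - _LOGISTIC_MID)
                               / _LOGISTIC_SCALE))


def terrain_elevation(x, y):
    """Analytic gentle terrain surface (m): mild trend plus low swells."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return (100.0 + 0.004 * x + 0.002 * y
            + 1.5 * np.sin(x / 120.0) * np.cos(y / 150.0))


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic scene.

    The default point density matches the triple-echo drone survey the
    scene emulates (~450 pts/m²); desk-scale runs pass a reduced density.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 240.0, 240.0)
    cell_size_dem: float = 30.0
    species_list: tuple[str, ...] = SPECIES
    stems_per_ha: float = 600.0
    height_range_m: tuple[float, float] = (4.0, 12.0)
    hd_truth: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HD_TRUTH))
    point_density_pts_m2: float = 450.0
    noise_sd_z_m: float = 0.03
    reflectance_noise_sd: float = 0.005
    seed: int = 0
    stand_tile_m: float = 120.0
    crown_diameter_frac: float = 0.25
    min_apex_separation_m: float | None = None
    band_cell_m: float = 10.0
    sample_cell_m: float = 30.0
    crs: str = "local-m"

    def __post_init__(self):
        x0, y0, x1, y1 = self.extent
        if (x1 - x0) <= 0 or (y1 - y0) <= 0:
            raise ValueError("extent must have positive area")
        if self.point_density_pts_m2 <= 0:
            raise ValueError("point density must be positive")
        if self.stems_per_ha < 0:
            raise ValueError("stems_per_ha must be non-negative")
        unknown = set(self.species_list) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        forms = {self.hd_truth[s][0] for s in self.species_list}
        if "power" in forms and self.height_range_m[0] < 1.3:
            raise ValueError(
                "height range must start at or above breast height (1.3 m) "
                "when a power-form growth curve is used")

    @property
    def mean_crown_diameter_m(self) -> float:
        """Field mean crown diameter implied by the crown-size model."""
        return self.crown_diameter_frac * float(np.mean(self.height_range_m))

    @property
    def apex_separation_m(self) -> float:
        """Minimum apex spacing; defaults to the mean crown diameter."""
        if self.min_apex_separation_m is not None:
            return self.min_apex_separation_m
        return self.mean_crown_diameter_m


@dataclass
class TruthTable:
    """Ground truth: per-tree records plus species-attributed stands."""

    trees: pd.DataFrame  # x, y, species, height_m, dbh_cm, agb_kg, ...
    stand_polygons: list  # [(shapely Polygon, species), ...]


@dataclass
class Scene:
    truth: TruthTable
    cloud: PointCloud
    bands: dict[str, Raster]
    dem: Raster
    agb_truth: Raster  # true cell AGB (g/m²) on the sample grid
    grid: GridSpec  # 30-m sample grid
    config: SceneConfig


def _make_stands(cfg: SceneConfig, rng):
    """Tile the extent into single-species rectangular stands."""
    x0, y0, x1, y1 = cfg.extent
    t = cfg.stand_tile_m
    stands, means = [], []
    k = 0
    for sy in np.arange(y0, y1 - 1e-9, t):
        for sx in np.arange(x0, x1 - 1e-9, t):
            poly = box(sx, sy, min(sx + t, x1), min(sy + t, y1))
            species = cfg.species_list[k % len(cfg.species_list)]
            stands.append((poly, species))
            means.append(rng.uniform(*cfg.height_range_m))
            k += 1
    return stands, means


class _ApexPlacer:
    """Dart-throwing apex placement with a scene-wide minimum separation.

    The occupancy grid is shared across stands so the separation holds
    across stand boundaries too, which keeps segmentation ground truth
    well posed everywhere.
    """

    def __init__(self, min_sep: float, rng):
        self.min_sep = min_sep
        self.rng = rng
        self._pts: list[tuple[float, float]] = []
        self._cells: dict[tuple[int, int], list[int]] = {}

    def _clear_of_neighbors(self, px, py) -> bool:
        s = self.min_sep
        cx, cy = int(px // s), int(py // s)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for i in self._cells.get((cx + dx, cy + dy), ()):
                    qx, qy = self._pts[i]
                    if (qx - px) ** 2 + (qy - py) ** 2 < s * s:
                        return False
        return True

    def place(self, poly, n) -> np.ndarray:
        sx0, sy0, sx1, sy1 = poly.bounds
        margin = 1.0  # keep apexes off shared stand boundaries
        if sx1 - sx0 <= 2 * margin or sy1 - sy0 <= 2 * margin:
            return np.empty((0, 2))
        area = (sx1 - sx0 - 2 * margin) * (sy1 - sy0 - 2 * margin)
        if n * math.pi * (self.min_sep / 2) ** 2 > 0.6 * area:
            raise ValueError(
                f"requested stem density places apexes closer than the "
                f"minimum separation of {self.min_sep:.2f} m")
        placed = []
        attempts = 0
        while len(placed) < n and attempts < 200 * n:
            attempts += 1
            px = self.rng.uniform(sx0 + margin, sx1 - margin)
            py = self.rng.uniform(sy0 + margin, sy1 - margin)
            if self._clear_of_neighbors(px, py):
                s = self.min_sep
                key = (int(px // s), int(py // s))
                self._cells.setdefault(key, []).append(len(self._pts))
                self._pts.append((px, py))
                placed.append((px, py))
        if len(placed) < n:
            raise ValueError(
                f"could not place {n} apexes with minimum separation "
                f"{self.min_sep:.2f} m (placed {len(placed)})")
        return np.asarray(placed)


def _sample_grid(cfg: SceneConfig) -> GridSpec:
    x0, y0, x1, y1 = cfg.extent
    c = cfg.sample_cell_m
    return GridSpec(x0, y1, c, int(round((y1 - y0) / c)),
                    int(round((x1 - x0) / c)), cfg.crs)


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full scene: truth table, point cloud, bands, DEM."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    x0, y0, x1, y1 = cfg.extent
    area_m2 = (x1 - x0) * (y1 - y0)
    min_sep = cfg.apex_separation_m

    stands, stand_means = _make_stands(cfg, rng)

    # --- tree list: positions, heights on the true growth curves ---
    records = []
    placer = _ApexPlacer(min_sep, rng)
    for (poly, species), h_mean in zip(stands, stand_means):
        n = int(round(cfg.stems_per_ha * poly.area / 1e4))
        if n == 0 or cfg.stems_per_ha == 0:
            continue
        pts = placer.place(poly, n)
        lo = max(cfg.height_range_m[0], 0.85 * h_mean)
        hi = min(cfg.height_range_m[1], 1.15 * h_mean)
        h = rng.uniform(lo, hi, size=len(pts))
        form, a, b = cfg.hd_truth[species]
        d = hd_inverse(form, a, b, h)
        ma = tree_agb(species, d, h)
        crown_d = cfg.crown_diameter_frac * h * rng.uniform(0.9, 1.1, len(pts))
        crown_base = np.minimum(np.maximum(2.0, 0.3 * h), 0.6 * h)
        for i in range(len(pts)):
            records.append({
                "x": pts[i, 0], "y": pts[i, 1], "species": species,
                "height_m": h[i], "dbh_cm": d[i], "agb_kg": ma[i],
                "crown_diameter_m": crown_d[i], "crown_base_m": crown_base[i],
            })
    trees = pd.DataFrame(records, columns=[
        "x", "y", "species", "height_m", "dbh_cm", "agb_kg",
        "crown_diameter_m", "crown_base_m"])

    # --- point cloud: crowns on their envelopes, remainder on the ground ---
    density = cfg.point_density_pts_m2
    crown_chunks = []
    n_crown_total = 0
    for row in trees.itertuples():
        radius = row.crown_diameter_m / 2.0
        # triple-echo pattern: canopy yields ~3 returns per pulse, and the
        # intercepted pulses are debited from the ground-return budget
        n_i = int(round(3.0 * density * math.pi * radius**2))
        n_crown_total += n_i + 4
        u = rng.uniform(size=n_i)
        theta = rng.uniform(0, 2 * math.pi, size=n_i)
        # radial density concentrated toward the crown center: steep upper
        # crown surfaces return more echoes per unit ground area
        r = radius * u
        px = row.x + r * np.cos(theta)
        py = row.y + r * np.sin(theta)
        depth = row.height_m - row.crown_base_m
        frac = r / radius if radius > 0 else np.zeros(n_i)
        shape = (1.0 - frac) if row.species in CONIFERS else (1.0 - frac**2)
        fill = rng.uniform(0.85, 1.0, size=n_i)  # solid-crown vertical jitter
        pz = (terrain_elevation(px, py) + row.crown_base_m
              + depth * shape * fill
              + rng.normal(0, cfg.noise_sd_z_m, size=n_i))
        # guaranteed apex return at the true tree top, plus a small treetop
        # echo cluster (multi-echo scanners return several hits at the tip)
        tr = 0.25 * rng.uniform(size=3)
        tth = rng.uniform(0, 2 * math.pi, size=3)
        ground_z = terrain_elevation(row.x, row.y)
        px = np.concatenate([px, [row.x], row.x + tr * np.cos(tth)])
        py = np.concatenate([py, [row.y], row.y + tr * np.sin(tth)])
        tip_z = ground_z + row.height_m
        pz = np.concatenate([
            pz, [tip_z + rng.normal(0, cfg.noise_sd_z_m)],
            tip_z - rng.uniform(0.05, 0.4, size=3)])
        crown_chunks.append(np.column_stack([px, py, pz]))

    # ground returns cover a small survey margin beyond the extent so crown
    # returns spilling past the boundary still sit above sampled terrain
    pad = 2.0
    pad_area = (x1 - x0 + 2 * pad) * (y1 - y0 + 2 * pad)
    n_total = int(round(density * pad_area))
    n_ground = max(n_total - n_crown_total, 0)
    gx = rng.uniform(x0 - pad, x1 + pad, size=n_ground)
    gy = rng.uniform(y0 - pad, y1 + pad, size=n_ground)
    gz = terrain_elevation(gx, gy) + rng.normal(0, cfg.noise_sd_z_m,
                                                size=n_ground)
    parts = [np.column_stack([gx, gy, gz])] + crown_chunks
    xyz = np.vstack(parts) if parts else np.empty((0, 3))
    cls = np.concatenate([
        np.full(n_ground, CLASS_CODES["ground"], dtype=np.int32),
        np.full(xyz.shape[0] - n_ground, CLASS_CODES["vegetation"],
                dtype=np.int32),
    ])
    cloud = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2], cls)

    # --- rasters ---
    grid = _sample_grid(cfg)
    agb_cells = np.zeros((grid.nrows, grid.ncols))
    if len(trees):
        row_i, col_i = grid.index_of(trees["x"].to_numpy(),
                                     trees["y"].to_numpy())
        np.add.at(agb_cells, (row_i, col_i), trees["agb_kg"].to_numpy())
    agb_truth = Raster(agb_cells * 1000.0 / (grid.cell**2), grid)

    dem_grid = GridSpec(x0, y1, cfg.cell_size_dem,
                        int(round((y1 - y0) / cfg.cell_size_dem)),
                        int(round((x1 - x0) / cfg.cell_size_dem)), cfg.crs)
    dxs, dys = dem_grid.cell_centers()
    dxx, dyy = np.meshgrid(dxs, dys)
    dem = Raster(terrain_elevation(dxx, dyy), dem_grid)

    band_grid = GridSpec(x0, y1, cfg.band_cell_m,
                         int(round((y1 - y0) / cfg.band_cell_m)),
                         int(round((x1 - x0) / cfg.band_cell_m)), cfg.crs)
    bxs, bys = band_grid.cell_centers()
    bxx, byy = np.meshgrid(bxs, bys)
    brow, bcol = grid.index_of(bxx.ravel(), byy.ravel())
    brow = np.clip(brow, 0, grid.nrows - 1)
    bcol = np.clip(bcol, 0, grid.ncols - 1)
    local_agb = agb_truth.data[brow, bcol].reshape(band_grid.nrows,
                                                   band_grid.ncols)
    signal = _agb_logistic(local_agb)
    bands = {}
    for name in ALL_BAND_NAMES:
        base, gain = BAND_PROFILES[name]
        noise = rng.normal(0, cfg.reflectance_noise_sd, size=signal.shape)
        bands[name] = Raster(base + gain * signal + noise, band_grid)

    truth = TruthTable(trees=trees, stand_polygons=stands)
    return Scene(truth=truth, cloud=cloud, bands=bands, dem=dem,
                 agb_truth=agb_truth, grid=grid, config=cfg)


# ---------------------------------------------------------------------------
# scene serialization (all plain-text formats)

def write_scene(scene: Scene, dirpath) -> None:
    """Write a scene to disk: CSV cloud and tree list, ASCII-grid rasters,
    GeoJSON stands.  A read-back round trip reproduces values to ≤1e-6."""
    from pathlib import Path

    from .point_cloud import write_cloud
    from .raster import write_ascii
    from .vector import write_stands

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_cloud(scene.cloud, d / "cloud.csv")
    scene.truth.trees.to_csv(d / "trees_true.csv", index=False,
                             float_format="%.8g")
    write_stands(scene.truth.stand_polygons, d / "stands.geojson")
    write_ascii(scene.dem, d / "dem.asc")
    write_ascii(scene.agb_truth, d / "agb_truth.asc")
    bdir = d / "bands"
    bdir.mkdir(exist_ok=True)
    for name, r in scene.bands.items():
        write_ascii(r, bdir / f"{name}.asc")


def read_scene(dirpath, config: SceneConfig | None = None) -> Scene:
    """Read back a scene written by :func:`write_scene`."""
    from pathlib import Path

    from .point_cloud import read_cloud
    from .raster import read_ascii
    from .vector import read_stands

    d = Path(dirpath)
    cloud = read_cloud(d / "cloud.csv")
    trees = pd.read_csv(d / "trees_true.csv")
    stands = read_stands(d / "stands.geojson")
    dem = read_ascii(d / "dem.asc")
    agb_truth = read_ascii(d / "agb_truth.asc")
    agb_truth.data[np.isnan(agb_truth.data)] = 0.0
    bands = {name: read_ascii(d / "bands" / f"{name}.asc")
             for name in ALL_BAND_NAMES}
    cfg = config or SceneConfig()
    return Scene(truth=TruthTable(trees=trees, stand_polygons=stands),
                 cloud=cloud, bands=bands, dem=dem, agb_truth=agb_truth,
                 grid=agb_truth.grid, config=cfg)
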