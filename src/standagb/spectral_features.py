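"""The 26 predictor variables: bands, vegetation indices, tasseled cap, terrain.

The predictor stack mirrors the variable set commonly used for sparse-stand
biomass mapping from Sentinel-2-style imagery: nine reflectance bands
(B2–B8, B11, B12), eleven vegetation indices, the three tasseled-cap
components (brightness, greenness, wetness) as fixed 13-band linear
combinations, and three terrain variables (elevation, slope, aspect) from a
DEM.  Everything is evaluated per pixel on a common 30-m grid; inputs on
finer grids are nearest-neighbor resampled first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import GridSpec, Raster

__all__ = [
    "ALL_BAND_NAMES",
    "SPECTRAL_FEATURES",
    "INDEX_FEATURES",
    "TASSELED_CAP_COEFFS",
    "TERRAIN_FEATURES",
    "FEATURE_NAMES",
    "FeatureStack",
    "resample_to_grid",
    "compute_vegetation_indices",
    "tasseled_cap",
    "terrain_features",
    "assemble_stack",
]

#: Input band order for the tasseled-cap dot products.
ALL_BAND_NAMES = ("B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8",
                  "B9", "B10", "B11", "B12", "B8A")

SPECTRAL_FEATURES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B11", "B12")
INDEX_FEATURES = ("NDVI", "RENDVI", "NDWI", "EVI", "RVI", "DVI", "VDVI",
                  "SAVI", "MSAVI", "NBR", "NDMI")
TERRAIN_FEATURES = ("DEM", "Aspect", "Slope")
FEATURE_NAMES = SPECTRAL_FEATURES + INDEX_FEATURES + ("TCB", "TCG", "TCW") \
    + TERRAIN_FEATURES

#: Published brightness/greenness/wetness coefficient vectors over
#: (B1..B12, B8A).  A user-supplied mapping with the same shape may be
#: passed to :func:`tasseled_cap` to swap in alternative conventions
#: (e.g. signed greenness coefficients).
TASSELED_CAP_COEFFS: dict[str, tuple[float, ...]] = {
    "TCB": (0.0356, 0.0822, 0.136, 0.2611, 0.2964, 0.3338, 0.3877, 0.3895,
            0.0949, 0.0009, 0.3882, 0.1366, 0.475),
    "TCG": (0.0635, 0.1128, 0.168, 0.348, 0.3303, 0.0852, 0.3302, 0.3165,
            0.0467, 0.0009, 0.4578, 0.4064, 0.3625),
    "TCW": (0.0649, 0.1363, 0.2802, 0.3072, 0.5288, 0.1379, 0.0001, 0.0807,
            0.0302, 0.003, 0.4064, 0.5602, 0.1389),
}

#: Bands each vegetation index needs.
_INDEX_BANDS = {
    "NDVI": ("B8", "B4"), "RENDVI": ("B6", "B5"), "NDWI": ("B3", "B8"),
    "EVI": ("B8", "B4", "B2"), "RVI": ("B8", "B4"), "DVI": ("B8", "B4"),
    "VDVI": ("B3", "B4", "B2"), "SAVI": ("B8", "B4"), "MSAVI": ("B8", "B4"),
    "NBR": ("B8", "B12"), "NDMI": ("B8", "B11"),
}

#: Aspect value reported for flat cells.
FLAT_ASPECT = -1.0


@dataclass
class FeatureStack:
    """26 co-registered 30-m predictor layers keyed by canonical name."""

    layers: dict[str, Raster]
    missing_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.layers)
        if set(names) != set(FEATURE_NAMES):
            extra = sorted(set(names) - set(FEATURE_NAMES))
            absent = sorted(set(FEATURE_NAMES) - set(names))
            raise ValueError(
                f"feature stack must have exactly the 26 canonical layers; "
                f"missing {absent}, unexpected {extra}"
            )
        ref = self.layers[FEATURE_NAMES[0]]
        for name, r in self.layers.items():
            if not r.same_grid(ref):
                raise ValueError(f"layer {name} is not on the common grid")
            if not np.isfinite(r.data).any():
                raise ValueError(f"layer {name} is entirely non-finite")

    @property
    def grid(self) -> GridSpec:
        return self.layers[FEATURE_NAMES[0]].grid

    def as_array(self) -> np.ndarray:
        """(nrows, ncols, 26) array in FEATURE_NAMES order."""
        return np.stack([self.layers[n].data for n in FEATURE_NAMES], axis=-1)


def resample_to_grid(raster: Raster, target: GridSpec) -> Raster:
    """Nearest-neighbor resampling: sample the source at target cell centers.

    Output values are always drawn from source cells, never interpolated.
    """
    if raster.grid.crs != target.crs:
        raise ValueError(
            f"CRS mismatch: source {raster.grid.crs!r} vs target {target.crs!r}"
        )
    xs, ys = target.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    row, col = raster.grid.index_of(xx.ravel(), yy.ravel())
    row = np.clip(row, 0, raster.grid.nrows - 1)
    col = np.clip(col, 0, raster.grid.ncols - 1)
    data = raster.data[row, col].reshape(target.nrows, target.ncols)
    return Raster(data, target)


def _safe_divide(num, den):
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def compute_vegetation_indices(bands: dict[str, Raster]):
    """Evaluate the 11 vegetation indices per pixel.

    Returns ``(indices, zero_den_counts)``: rasters keyed by index name and
    the per-index count of pixels lost to zero denominators (NaN output).
    """
    for name, needed in _INDEX_BANDS.items():
        absent = [b for b in needed if b not in bands]
        if absent:
            raise ValueError(f"missing band(s) {absent} required by {name}")
    grid = bands["B8"].grid
    b = {k: v.data for k, v in bands.items()}
    out: dict[str, np.ndarray] = {}
    out["NDVI"] = _safe_divide(b["B8"] - b["B4"], b["B8"] + b["B4"])
    out["RENDVI"] = _safe_divide(b["B6"] - b["B5"], b["B6"] + b["B5"])
    out["NDWI"] = _safe_divide(b["B3"] - b["B8"], b["B3"] + b["B8"])
    out["EVI"] = 2.5 * _safe_divide(
        b["B8"] - b["B4"], b["B8"] + 6.0 * b["B4"] - 7.5 * b["B2"] + 1.0)
    out["RVI"] = _safe_divide(b["B8"], b["B4"])
    out["DVI"] = b["B8"] - b["B4"]
    out["VDVI"] = _safe_divide(2.0 * b["B3"] - b["B4"] - b["B2"],
                               2.0 * b["B3"] + b["B4"] + b["B2"])
    out["SAVI"] = 1.5 * _safe_divide(b["B8"] - b["B4"],
                                     b["B8"] + b["B4"] + 0.5)
    with np.errstate(invalid="ignore"):
        out["MSAVI"] = (2.0 * b["B8"] + 1.0 - np.sqrt(
            (2.0 * b["B8"] + 1.0) ** 2 - 8.0 * (b["B8"] - b["B4"]))) / 2.0
    out["NBR"] = _safe_divide(b["B8"] - b["B12"], b["B8"] + b["B12"])
    out["NDMI"] = _safe_divide(b["B8"] - b["B11"], b["B8"] + b["B11"])

    counts = {k: int(np.isnan(v).sum()) for k, v in out.items()}
    return ({k: Raster(v, grid) for k, v in out.items()}, counts)


def tasseled_cap(bands: dict[str, Raster], coeffs=None):
    """Brightness/greenness/wetness as 13-band per-pixel dot products.

    ``coeffs`` may override the default published vectors with any mapping
    of the same component names to 13-element sequences.
    """
    absent = [b for b in ALL_BAND_NAMES if b not in bands]
    if absent:
        raise ValueError(f"tasseled cap needs all 13 bands; missing {absent}")
    coeffs = coeffs or TASSELED_CAP_COEFFS
    grid = bands["B1"].grid
    cube = np.stack([bands[b].data for b in ALL_BAND_NAMES], axis=-1)
    out = {}
    for comp in ("TCB", "TCG", "TCW"):
        vec = np.asarray(coeffs[comp], dtype=float)
        if vec.size != 13:
            raise ValueError(f"{comp} coefficient vector must have 13 entries")
        out[comp] = Raster(cube @ vec, grid)
    return out["TCB"], out["TCG"], out["TCW"]


def terrain_features(dem: Raster):
    """Elevation, slope and aspect from a DEM by Horn's 3×3 method.

    Slope is in degrees; aspect is the upslope azimuth in degrees clockwise
    from north (a surface rising due east has aspect 90°), with flat cells
    set to the sentinel ``FLAT_ASPECT``.
    """
    z = dem.data
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3×3 for Horn's method")
    cell = dem.grid.cell
    zp = np.pad(z, 1, mode="edge")
    # 3x3 neighborhood; rows run north->south, cols west->east
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(dzdx, dzdy)) % 360.0
    aspect[slope == 0.0] = FLAT_ASPECT
    return (Raster(z.copy(), dem.grid), Raster(slope, dem.grid),
            Raster(aspect, dem.grid))


def assemble_stack(bands: dict[str, Raster], dem: Raster,
                   target: GridSpec | None = None,
                   tc_coeffs=None) -> FeatureStack:
    """Build the full 26-layer predictor stack on a common 30-m grid.

    ``bands`` must carry all 13 reflectance bands (B1–B12, B8A); ``dem``
    the elevation raster.  If ``target`` is omitted the grid of B2 is used.
    """
    absent = [b for b in ALL_BAND_NAMES if b not in bands]
    if absent:
        dependent = ["TCB", "TCG", "TCW"]
        dependent += [i for i, req in _INDEX_BANDS.items()
                      if any(b in absent for b in req)]
        dependent += [b for b in absent if b in SPECTRAL_FEATURES]
        raise ValueError(
            f"missing band(s) {absent}; required by {sorted(set(dependent))}"
        )
    target = target or bands["B2"].grid
    bands30 = {name: resample_to_grid(r, target) for name, r in bands.items()}
    dem30 = resample_to_grid(dem, target)

    layers: dict[str, Raster] = {b: bands30[b] for b in SPECTRAL_FEATURES}
    indices, counts = compute_vegetation_indices(bands30)
    layers.update(indices)
    tcb, tcg, tcw = tasseled_cap(bands30, coeffs=tc_coeffs)
    layers.update({"TCB": tcb, "TCG": tcg, "TCW": tcw})
    elev, slope, aspect = terrain_features(dem30)
    layers.update({"DEM": elev, "Slope": slope, "Aspect": aspect})

    missing = {name: int(np.isnan(r.data).sum()) for name, r in layers.items()}
    missing.update(counts)
    return FeatureStack(layers=layers, missing_counts=missing)
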