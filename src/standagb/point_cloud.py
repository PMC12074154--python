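"""Point-cloud I/O, denoising, ground classification, height normalization.

Clouds are column arrays of (x, y, z, class) with LAS-style class codes.
Ground classification is a progressive TIN densification: seed the surface
from per-grid-cell elevation minima, triangulate, and iteratively accept
points lying within a vertical tolerance of the interpolated surface.
Height normalization subtracts the TIN-interpolated ground elevation so z
becomes height above ground.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

__all__ = [
    "CLASS_CODES",
    "PointCloud",
    "read_cloud",
    "write_cloud",
    "denoise",
    "classify_ground",
    "normalize_heights",
]

#: LAS class codes used throughout.
CLASS_CODES = {
    "unclassified": 1,
    "ground": 2,
    "vegetation": 5,
    "building": 6,
    "noise": 7,
}
_VALID_CODES = frozenset(CLASS_CODES.values())


@dataclass
class PointCloud:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    cls: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.cls is None:
            self.cls = np.full(self.x.shape, CLASS_CODES["unclassified"],
                               dtype=np.int32)
        self.cls = np.asarray(self.cls, dtype=np.int32)
        n = {a.shape for a in (self.x, self.y, self.z, self.cls)}
        if len(n) != 1:
            raise ValueError("coordinate/class arrays must share one length")
        bad = ~np.isfinite(np.column_stack([self.x, self.y, self.z])).all(axis=1)
        if bad.any():
            raise ValueError(
                f"non-finite coordinates at record {int(np.flatnonzero(bad)[0])}"
            )
        unknown = ~np.isin(self.cls, list(_VALID_CODES))
        if unknown.any():
            raise ValueError(
                f"unknown class code at record {int(np.flatnonzero(unknown)[0])}"
            )

    def __len__(self) -> int:
        return self.x.size

    def mask(self, code_name: str) -> np.ndarray:
        return self.cls == CLASS_CODES[code_name]

    def copy(self) -> "PointCloud":
        return PointCloud(self.x.copy(), self.y.copy(), self.z.copy(),
                          self.cls.copy())


def read_cloud(path) -> PointCloud:
    """Read a headerless ``x,y,z[,class]`` CSV point cloud."""
    path = Path(path)
    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed point record in {path.name}: {exc}") from exc
    if arr.shape[1] not in (3, 4):
        raise ValueError(
            f"{path.name}: expected 3 or 4 columns, got {arr.shape[1]}"
        )
    bad = ~np.isfinite(arr[:, :3]).all(axis=1)
    if bad.any():
        raise ValueError(
            f"{path.name}: non-finite coordinate at record "
            f"{int(np.flatnonzero(bad)[0])}"
        )
    cls = arr[:, 3].astype(np.int32) if arr.shape[1] == 4 else None
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2], cls)


def write_cloud(cloud: PointCloud, path) -> None:
    """Write ``x,y,z,class`` CSV at millimeter-scale stored precision."""
    arr = np.column_stack([cloud.x, cloud.y, cloud.z])
    with Path(path).open("w") as fh:
        for (px, py, pz), c in zip(arr, cloud.cls):
            fh.write(f"{px:.6f},{py:.6f},{pz:.6f},{c:d}\n")


def denoise(cloud: PointCloud, k: int = 8, n_sd: float = 3.0) -> PointCloud:
    """Statistical outlier removal: flag (not drop) isolated points as noise.

    A point whose mean distance to its k nearest neighbors exceeds the
    cloud-wide mean by ``n_sd`` standard deviations is relabeled with the
    noise class.  Point count is conserved.
    """
    if len(cloud) <= k:
        return cloud.copy()
    xyz = np.column_stack([cloud.x, cloud.y, cloud.z])
    dist, _ = cKDTree(xyz).query(xyz, k=k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    cutoff = mean_d.mean() + n_sd * mean_d.std()
    out = cloud.copy()
    out.cls[mean_d > cutoff] = CLASS_CODES["noise"]
    return out


def _seed_minima(x, y, z, grid_m):
    """Indices of the lowest point in each occupied grid cell."""
    ix = np.floor(x / grid_m).astype(np.int64)
    iy = np.floor(y / grid_m).astype(np.int64)
    key = (ix - ix.min()) * (iy.max() - iy.min() + 1) + (iy - iy.min())
    order = np.lexsort((z, key))
    first = np.ones(order.size, dtype=bool)
    first[1:] = key[order[1:]] != key[order[:-1]]
    return order[first]


def classify_ground(cloud: PointCloud, grid_m: float = 5.0,
                    z_tol_m: float = 0.3, max_iter: int = 10) -> PointCloud:
    """Label ground points by progressive TIN densification.

    Seeds are per-``grid_m``-cell elevation minima; each iteration
    triangulates the current ground set and accepts candidate points whose
    height differs from the interpolated surface by at most ``z_tol_m``.
    Candidates outside the triangulation hull are compared against the
    nearest ground point.  Noise-classified points are left untouched; all
    remaining non-ground points come back labeled vegetation.  The result
    depends only on coordinates, so a second application is a no-op.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    active = ~cloud.mask("noise")
    idx = np.flatnonzero(active)
    x, y, z = cloud.x[idx], cloud.y[idx], cloud.z[idx]

    seeds = _seed_minima(x, y, z, grid_m)
    if seeds.size < 3:
        raise ValueError(
            f"need at least 3 seed minima for the initial TIN, got {seeds.size}"
        )
    ground = np.zeros(idx.size, dtype=bool)
    ground[seeds] = True

    for _ in range(max_iter):
        gx = np.column_stack([x[ground], y[ground]])
        gz = z[ground]
        cand = np.flatnonzero(~ground)
        if cand.size == 0:
            break
        interp = LinearNDInterpolator(gx, gz)
        surf = interp(x[cand], y[cand])
        outside = np.isnan(surf)
        if outside.any():
            _, nn = cKDTree(gx).query(
                np.column_stack([x[cand[outside]], y[cand[outside]]]))
            surf[outside] = gz[nn]
        accept = np.abs(z[cand] - surf) <= z_tol_m
        if not accept.any():
            break
        ground[cand[accept]] = True

    out = cloud.copy()
    out.cls[idx] = np.where(ground, CLASS_CODES["ground"],
                            CLASS_CODES["vegetation"])
    return out


def normalize_heights(cloud: PointCloud) -> tuple[PointCloud, int]:
    """Replace z by height above the TIN-interpolated ground surface.

    Points outside the ground triangulation fall back to the nearest
    ground point's elevation; the count of such extrapolated points is
    returned alongside the normalized cloud.
    """
    gmask = cloud.mask("ground")
    if not gmask.any():
        raise ValueError("no ground points; run classify_ground first")
    gx = np.column_stack([cloud.x[gmask], cloud.y[gmask]])
    gz = cloud.z[gmask]

    if gx.shape[0] >= 3:
        interp = LinearNDInterpolator(gx, gz)
        surf = interp(cloud.x, cloud.y)
    else:
        surf = np.full(len(cloud), np.nan)
    outside = np.isnan(surf)
    n_extrapolated = int(outside.sum())
    if outside.any():
        _, nn = cKDTree(gx).query(
            np.column_stack([cloud.x[outside], cloud.y[outside]]))
        surf[outside] = gz[nn]

    out = cloud.copy()
    out.z = cloud.z - surf
    return out, n_extrapolated
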