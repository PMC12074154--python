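"""Individual-tree segmentation by seeded top-down region growing.

Points of a height-normalized cloud are processed in descending height.
The highest unprocessed point founds a new tree (it is a crown apex seed);
every subsequent point joins the segment owning the nearest already-assigned
point if that horizontal distance is below the spacing threshold, otherwise
it founds a new tree.  The spacing threshold is the field mean crown
diameter of the species being segmented.  Points below the minimum height
(default 2 m: ground, grass, stem bases) stay unassigned.

Per-tree attributes are the apex position and height, and the crown's
2-D convex-hull area with its equal-area circle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point
from shapely.prepared import prep

from .point_cloud import CLASS_CODES, PointCloud

__all__ = [
    "TreeSegment",
    "segment_trees",
    "extract_attributes",
    "assign_species",
    "DEFAULT_MIN_HEIGHT_M",
]

DEFAULT_MIN_HEIGHT_M = 2.0


@dataclass
class TreeSegment:
    tree_id: int
    indices: np.ndarray  # indices into the source cloud
    apex: tuple[float, float, float]  # (x, y, H)


def segment_trees(cloud: PointCloud, spacing_threshold_m: float,
                  min_height_m: float = DEFAULT_MIN_HEIGHT_M):
    """Cluster a normalized cloud into per-tree segments.

    Deterministic: points are visited in descending z with (x, y) as the
    tie-break, and a point equidistant to two segments joins the one with
    the lower tree id.  Returns segments ordered by tree id; an empty
    cloud, or one with no point at or above ``min_height_m``, yields an
    empty list.
    """
    if spacing_threshold_m <= 0:
        raise ValueError("spacing threshold must be positive")
    eligible = (cloud.z >= min_height_m) & (cloud.cls != CLASS_CODES["noise"])
    sel = np.flatnonzero(eligible)
    if sel.size == 0:
        return []
    x, y, z = cloud.x[sel], cloud.y[sel], cloud.z[sel]
    order = np.lexsort((y, x, -z))

    s = spacing_threshold_m
    s2 = s * s
    # spatial hash with cell edge = threshold: any assigned point within the
    # threshold of a query lies in the 3x3 cell neighborhood
    cells: dict[tuple[int, int], list[int]] = {}
    seg_of = np.empty(sel.size, dtype=np.int64)
    ax = np.empty(sel.size)
    ay = np.empty(sel.size)
    n_assigned = 0
    apex_of: list[int] = []  # founder (apex) per segment, as index into sel

    for j in order:
        px, py = x[j], y[j]
        cx, cy = int(np.floor(px / s)), int(np.floor(py / s))
        neigh: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                neigh.extend(cells.get((cx + dx, cy + dy), ()))
        seg = -1
        if neigh:
            ni = np.asarray(neigh, dtype=np.int64)
            d2 = (ax[ni] - px) ** 2 + (ay[ni] - py) ** 2
            dmin = d2.min()
            if dmin < s2:
                at_min = ni[d2 <= dmin + 1e-12]
                seg = int(seg_of[at_min].min())
        if seg < 0:
            seg = len(apex_of)
            apex_of.append(j)
        k = n_assigned
        ax[k], ay[k] = px, py
        seg_of[k] = seg
        cells.setdefault((cx, cy), []).append(k)
        n_assigned += 1

    return _collect_segments(sel, x, y, z, order, seg_of, apex_of)


def _collect_segments(sel, x, y, z, order, seg_of, apex_of):
    members: dict[int, list[int]] = {}
    for k, j in enumerate(order):
        members.setdefault(int(seg_of[k]), []).append(int(sel[j]))
    segments = []
    for tree_id in sorted(members):
        founder = apex_of[tree_id]
        segments.append(TreeSegment(
            tree_id=tree_id,
            indices=np.asarray(members[tree_id], dtype=np.int64),
            apex=(float(x[founder]), float(y[founder]), float(z[founder])),
        ))
    return segments


def extract_attributes(segments, cloud: PointCloud) -> pd.DataFrame:
    """Per-segment tree records: apex position, height, crown hull metrics.

    Height is the apex z; crown area is the area of the 2-D convex hull of
    the member points, and crown diameter the diameter of the equal-area
    circle.  Segments too small or degenerate for a hull get zero area and
    a raised ``flagged`` bit.
    """
    rows = []
    for seg in segments:
        xs = cloud.x[seg.indices]
        ys = cloud.y[seg.indices]
        area, flagged = 0.0, False
        if seg.indices.size >= 3:
            try:
                area = float(ConvexHull(np.column_stack([xs, ys])).volume)
            except QhullError:
                flagged = True
        else:
            flagged = True
        rows.append({
            "tree_id": seg.tree_id,
            "x": seg.apex[0],
            "y": seg.apex[1],
            "height_m": seg.apex[2],
            "crown_area_m2": area,
            "crown_diameter_m": 2.0 * np.sqrt(area / np.pi),
            "n_points": int(seg.indices.size),
            "flagged": flagged,
        })
    return pd.DataFrame(rows, columns=[
        "tree_id", "x", "y", "height_m", "crown_area_m2",
        "crown_diameter_m", "n_points", "flagged",
    ])


def assign_species(trees: pd.DataFrame, stands):
    """Attach a species label to each tree by stand-polygon overlay.

    ``stands`` is a sequence of ``(polygon, species)``.  Trees whose apex
    falls inside a stand inherit its species; trees outside every stand are
    dropped.  Returns ``(labelled_trees, n_dropped)``.  Overlapping stands
    with conflicting species are rejected.
    """
    stands = list(stands)
    for i in range(len(stands)):
        for j in range(i + 1, len(stands)):
            gi, si = stands[i]
            gj, sj = stands[j]
            if si != sj and gi.intersection(gj).area > 0:
                raise ValueError(
                    f"stand polygons {i} and {j} overlap with conflicting "
                    f"species ({si!r} vs {sj!r})"
                )
    prepared = [(prep(geom), species) for geom, species in stands]
    labels = []
    for _, row in trees.iterrows():
        pt = Point(row["x"], row["y"])
        label = next((sp for geom, sp in prepared if geom.covers(pt)), None)
        labels.append(label)
    out = trees.copy()
    out["species"] = labels
    kept = out.dropna(subset=["species"]).reset_index(drop=True)
    return kept, len(out) - len(kept)
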