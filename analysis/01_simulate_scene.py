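"""Generate the synthetic plantation scene with known per-tree ground truth.

Writes the point cloud (CSV), 13 reflectance bands and DEM (ASCII grids),
stand polygons (GeoJSON) and the true tree list under the working directory.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("simulate", cfg)
    print(f"scene: {m['n_trees']} trees in {m['n_stands']} stands, "
          f"{m['n_points']} LiDAR returns at "
          f"{m['point_density_pts_m2']:.0f} pts/m^2")


if __name__ == "__main__":
    main()
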