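"""Shared run configuration for the numbered analysis scripts.

One desk-scale synthetic experiment: a 270 m x 270 m scene (≈7.3 ha) of
four single-species stands at 350 stems/ha, scanned at 6 pts/m² (reduced
from the emulated survey's ~450 pts/m² for desk runtime), gridded at 30 m.
Every script operates on the same working directory so stages can be run
one after another or rerun individually.
"""

import argparse

from standagb.pipeline import RunConfig
from standagb.synthetic_scene import SceneConfig


def make_config(workdir: str, seed: int) -> RunConfig:
    scene = SceneConfig(
        extent=(0.0, 0.0, 270.0, 270.0), stand_tile_m=135.0,
        point_density_pts_m2=6.0, stems_per_ha=350.0,
        min_apex_separation_m=4.0, seed=seed)
    return RunConfig(workdir=workdir, scene=scene, seed=seed)


def parse_args(description: str) -> RunConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--workdir", default="results/experiment")
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()
    return make_config(args.workdir, args.seed)
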