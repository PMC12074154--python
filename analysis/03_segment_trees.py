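"""Segment individual trees by seeded top-down region growing.

The spacing threshold is the field mean crown diameter; the output is a
per-tree table of apex position, height and crown hull metrics.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("segment", cfg)
    print(f"{m['n_segments']} trees segmented at spacing threshold "
          f"{m['spacing_threshold_m']:.2f} m "
          f"(min height {m['min_height_m']:.1f} m)")


if __name__ == "__main__":
    main()
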