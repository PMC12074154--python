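"""Overlay species, invert height to DBH, apply allometry, grid at 30 m.

Emits the edge-filtered grid-cell AGB sample table (g/m^2) used to train
the satellite estimator.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("samples", cfg)
    print(f"{m['n_samples']} clean samples, {m['n_edge']} edge-flagged "
          f"cells removed, {m['n_inversion_flagged']} trees outside the "
          f"inversion domain, {m['n_trees_outside_stands']} trees outside "
          f"all stands")


if __name__ == "__main__":
    main()
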