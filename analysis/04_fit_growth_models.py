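"""Fit the four height-DBH growth models per species and select by AIC.

Simulated field (H, D) pairs (n=200 per species, 0.5 m height noise) play
the role of the calipered plot data; the AIC-best form per species is
written to the growth-model registry used for DBH inversion.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("fit-hd", cfg)
    for species, entry in m["models"].items():
        print(f"{species}: {entry['selected_form']} "
              f"(a={entry['a']:.3f}, b={entry['b']:.3f}, "
              f"R2={entry['r2']:.3f})")


if __name__ == "__main__":
    main()
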