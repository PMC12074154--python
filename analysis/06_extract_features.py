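"""Assemble the 26-variable predictor stack on the 30-m grid.

Nine spectral bands, eleven vegetation indices, three tasseled-cap
components and three terrain variables, all nearest-neighbor resampled to
the common sample grid.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("features", cfg)
    missing = {k: v for k, v in m["missing_counts"].items() if v}
    print(f"{m['n_layers']} layers assembled; missing-value counts: "
          f"{missing or 'none'}")


if __name__ == "__main__":
    main()
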