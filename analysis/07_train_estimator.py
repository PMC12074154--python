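"""Grid-search and train the gradient-boosted AGB regressor.

Single 80/20 split; learning rate {0.005, 0.010, 0.050, 0.001} x ntree
100..800 scored by held-out R^2; reports the winner, both metric sets and
the top of the variable-importance ranking.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    m = run_stage("train", cfg)
    print(f"best pair: ntree={m['best_ntree']} "
          f"shrinkage={m['best_shrinkage']}")
    print(f"train   R2={m['train']['r2']:.3f} RMSE={m['train']['rmse']:.0f} g/m^2")
    print(f"heldout R2={m['valid']['r2']:.3f} RMSE={m['valid']['rmse']:.0f} g/m^2")
    top = sorted(m["importance"].items(), key=lambda p: -p[1])[:5]
    print("top-5 importance:",
          ", ".join(f"{k} ({v:.2f})" for k, v in top))


if __name__ == "__main__":
    main()
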