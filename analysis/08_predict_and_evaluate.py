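"""Predict the wall-to-wall AGB raster and score everything against truth.

Compares the grid samples and the predicted raster with the generator's
true cell biomass, the quantities the synthetic experiment is designed to
recover.
"""

from experiment_config import parse_args
from standagb.pipeline import run_stage


def main():
    cfg = parse_args(__doc__)
    run_stage("predict", cfg)
    m = run_stage("evaluate", cfg)
    print(f"samples vs truth: R2={m['sample_vs_truth_r2']:.3f} "
          f"RMSE={m['sample_vs_truth_rmse_g_m2']:.0f} g/m^2 over "
          f"{m['n_samples']} cells")
    print(f"cells with >=3 trees: median rel err "
          f"{m['cell_rel_err_median']:.3f}, max {m['cell_rel_err_max']:.3f}")
    print(f"prediction vs truth: R2={m['pred_vs_truth_r2']:.3f} "
          f"RMSE={m['pred_vs_truth_rmse_g_m2']:.0f} g/m^2")


if __name__ == "__main__":
    main()
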