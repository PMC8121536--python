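#!/usr/bin/env python
"""Mixed-model comparison of discounting structure, plus pleasantness.

Transforms normalized indifference points to the log-odds scale and compares
by maximum likelihood: the null model (per-participant means), the
hyperbolic model (log-delay offset with unit coefficient), and the logistic
model (random intercepts and slopes).  Also fits the pleasantness mixed
model (occlusion as fixed and random effect) against its null.
"""

from pathlib import Path

import pandas as pd

from discountlab.lmm import compare_lmm, fit_pleasantness
from discountlab.pipeline import lmm_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    points = pd.read_csv(ROOT / "study" / "indifference_points.csv")
    for kind in ("experiential", "hypothetical"):
        rep = lmm_report(points, kind, boundary="drop")
        rep["comparison"].to_csv(ROOT / f"lmm_comparison_{kind}.csv", index=False)
        rep["lrt"].to_csv(ROOT / f"lmm_lrt_{kind}.csv", index=False)
        print(f"\n{kind} task ({rep['n_obs']} transformed points):")
        cols = ["model", "aic", "bic", "marginal_r2", "conditional_r2"]
        print(rep["comparison"][cols].round(2).to_string(index=False))
        logi = rep["comparison"].set_index("model").loc["logistic"]
        print(f"logistic fixed effects: intercept {logi.fixed_intercept:.1f} "
              f"(SE {logi.se_intercept:.1f}), slope {logi.fixed_log_delay:.1f} "
              f"(SE {logi.se_log_delay:.1f})")
        lrt = rep["lrt"].iloc[1]
        print(f"logistic vs hyperbolic: chi2({lrt.df:.0f}) = {lrt.chi2:.1f}, "
              f"p = {lrt.p:.2g}")

    ratings = pd.read_csv(ROOT / "study" / "ratings.csv")
    full = fit_pleasantness(ratings, random_slope=True)
    null = fit_pleasantness(ratings, null=True)
    lrt = compare_lmm(null, full)
    print(f"\npleasantness: occlusion slope "
          f"{full.fixed_effects['occlusion_level']:.3f} "
          f"(SE {full.fixed_se['occlusion_level']:.3f}); "
          f"vs null chi2({lrt.df}) = {lrt.chi2:.0f}, p = {lrt.p:.2g}")


if __name__ == "__main__":
    main()
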