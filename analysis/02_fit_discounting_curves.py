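#!/usr/bin/env python
"""Per-participant discounting-curve fits and model-based AUC.

Fits the hyperbolic and two-parameter logistic curves to every participant's
normalized indifference points (least squares, both staircase runs as
separate observations), integrates the logistic fit into a model-based AUC,
and prints the RMSE / R-squared summaries by task and model.
"""

from pathlib import Path

import pandas as pd

from discountlab.pipeline import auc_table, participant_curve_fits

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    points = pd.read_csv(ROOT / "study" / "indifference_points.csv")
    fits = participant_curve_fits(points)
    fits.to_csv(ROOT / "curve_fits.csv", index=False)
    aucs = auc_table(points)
    aucs.to_csv(ROOT / "auc.csv", index=False)

    for (kind, model), sub in fits.groupby(["task_kind", "model"]):
        worse_than_mean = (sub.r2 <= 0).sum()
        print(f"{kind:13s} {model:10s} mean RMSE {sub.rmse.mean():.3f} "
              f"(SD {sub.rmse.std(ddof=1):.3f}), median R2 {sub.r2.median():.3f}, "
              f"{worse_than_mean}/{len(sub)} fit worse than the mean")
    for kind, sub in aucs.groupby("task_kind"):
        print(f"AUC {kind:13s} mean {sub.auc.mean():.3f} "
              f"range [{sub.auc.min():.3f}, {sub.auc.max():.3f}]")
    print(f"wrote {ROOT/'curve_fits.csv'} and {ROOT/'auc.csv'}")


if __name__ == "__main__":
    main()
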