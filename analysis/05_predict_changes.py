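"""Random-forest sweep: predict each PVI change from baseline factors.

For every vulnerability index, sweeps all 511 predictor subsets with a
50-tree forest under repeated five-fold cross-validation, reports the best
single predictor and best combination (accuracy-ranked), and summarizes
the accuracy improvement of combinations over single predictors.

Repeats are reduced from the reference protocol's 100 to keep the sweep
tractable on one CPU; the seed fixes partitions and forests.
"""

from pathlib import Path

import pandas as pd

from capmech import predict
from capmech.pipeline import feature_table
from capmech.pvi import INDEX_NAMES

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7
N_REPEATS = 5


def main() -> None:
    morph = pd.read_csv(OUT / "morphology.csv", index_col=[0, 1])
    mech = pd.read_csv(OUT / "mechanics.csv", index_col=[0, 1])
    records = pd.read_csv(OUT / "pvi.csv", index_col=0)

    per_index = {}
    summary_rows = []
    for name in INDEX_NAMES:
        outcomes = records[f"{name}_binary"]
        if outcomes.nunique() < 2 or outcomes.value_counts().min() < 2:
            print(f"{name}: outcome classes too sparse; skipped")
            continue
        table = feature_table(morph, mech, records, name)
        results = predict.sweep_combinations(
            table, n_trees=50, n_repeats=N_REPEATS, seed=SEED
        )
        pd.DataFrame(
            [{"predictors": "+".join(r.predictor_subset), "acc": r.acc,
              "sen": r.sen, "spe": r.spe, "sen_plus_spe": r.sen_plus_spe,
              "auc": r.auc} for r in results]
        ).to_csv(OUT / f"sweep_{name}.csv", index=False)
        single, combo = predict.best_single_and_combination(results)
        per_index[name] = (100 * combo.acc, 100 * single.acc, combo.auc)
        summary_rows.append(
            {"index": name,
             "best_single": "+".join(single.predictor_subset),
             "single_acc": round(single.acc, 3),
             "best_combination": "+".join(combo.predictor_subset),
             "combo_acc": round(combo.acc, 3),
             "combo_auc": round(combo.auc, 3)}
        )
        print(f"{name}: best single {single.predictor_subset} acc "
              f"{single.acc:.3f} | best combo {combo.predictor_subset} "
              f"acc {combo.acc:.3f} auc {combo.auc:.3f}")

    report = predict.improvement_report(per_index)
    pd.DataFrame(summary_rows).to_csv(OUT / "prediction_summary.csv", index=False)
    print("accuracy improvement of combination over single (points):",
          report["improvement_points"])
    print("mean improvement:", report["mean_improvement_points"],
          "| mean AUC:", report["mean_auc"])


if __name__ == "__main__":
    main()
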