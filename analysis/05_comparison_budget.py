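"""How many paired comparisons place a listener in the right cluster?

Restricts each participant's responses to the reduced six-level design
(0, 7, 8, 9, 10, 18 dB; 20 weighted ordered pairs, 40-trial pool), then for
budgets 5..40 resamples that many comparisons without replacement 500 times
and classifies the drawn win profile to the nearest full-design cluster
centroid.  Writes the per-participant probability-of-correct-cluster table
to results/budget.csv and prints the budget at which the median participant
crosses 80%.
"""

import json
import pathlib
import sys
from collections import defaultdict

import numpy as np
import pandas as pd

from prefnr import comparison_budget as cb
from prefnr import trial_design as td

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 42
REPLICATES = 500


def main() -> None:
    trials, _ = td.read_trials(ROOT / "data" / "trials.csv")
    with open(ROOT / "clusters.json") as fh:
        clusters = json.load(fh)

    reduced = cb.build_reduced_design()
    centroids_full = {
        int(c): {"levels": clusters["levels"], "mean": np.array(info["mean"])}
        for c, info in clusters["centroids"].items()
    }
    centroids = cb.restrict_centroids(centroids_full, reduced.levels)

    by_pid: dict[str, list[td.Trial]] = defaultdict(list)
    for t in trials:
        by_pid[t.participant_id].append(t)

    rows = []
    for pid, ts in by_pid.items():
        pool = cb.reduced_trial_pool(ts, reduced)
        true_cluster = clusters["labels"][pid]
        curve = cb.budget_curve(pool, centroids, true_cluster,
                                replicates=REPLICATES, seed=SEED)
        for n, p in zip(curve.budgets, curve.p_correct):
            rows.append({"participant_id": pid, "true_cluster": true_cluster,
                         "budget": n, "p_correct": p})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "budget.csv", index=False)

    med = df.groupby("budget")["p_correct"].median()
    print("median probability of correct cluster by budget:")
    print(med.round(3).to_string())
    crossing = med[med >= 0.8]
    if len(crossing):
        print(f"median participant crosses 80% at a budget of {crossing.index[0]} comparisons")
    frac20 = (df[df.budget == 20]["p_correct"] >= 0.8).mean()
    print(f"fraction of participants at >= 80% with 20 comparisons: {frac20:.2f}")
    print(f"wrote {ROOT}/budget.csv")


if __name__ == "__main__":
    sys.exit(main())
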