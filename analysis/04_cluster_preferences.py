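"""Data-driven clustering of win-count profiles.

Builds each participant's win-fraction profile from the cohort trials, runs
Manhattan-distance Ward (unsquared) agglomeration, ranks cluster counts by
dendrogram lifetime, cuts at the chosen k, and writes the merge table,
stability ranking, labels, and per-cluster centroid profiles to
results/clusters.json (+ centroids.csv, merges.tsv).
"""

import json
import pathlib
import sys
from collections import defaultdict

import pandas as pd

from prefnr import preference_clustering as pc
from prefnr import trial_design as td

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials, _ = td.read_trials(ROOT / "data" / "trials.csv")
    by_pid: dict[str, list[td.Trial]] = defaultdict(list)
    for t in trials:
        by_pid[t.participant_id].append(t)
    pids = list(by_pid)
    profiles = [td.win_profile(by_pid[p], td.STUDY_DESIGN) for p in pids]

    link = pc.ward_linkage(pc.manhattan_matrix(profiles))
    ranked = pc.stable_solutions(link)
    # the study's focal solution: three clusters (none / intermediate / strong)
    k = 3
    labels = pc.cut_tree(link, k)
    cents = pc.cluster_centroids(labels, profiles)

    payload = {
        "k": k,
        "levels": list(td.STUDY_LEVELS),
        "labels": {p: int(l) for p, l in zip(pids, labels)},
        "stability": [{"k": kk, "lifetime": lt} for kk, lt in ranked[:6]],
        "centroids": {str(c): {"mean": i["mean"].tolist(), "sd": i["sd"].tolist(),
                               "n": i["n"]} for c, i in cents.items()},
    }
    with open(ROOT / "clusters.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    pd.DataFrame(
        [{"child_a": a, "child_b": b, "height": h, "size": s} for a, b, h, s in link.merges]
    ).to_csv(ROOT / "merges.tsv", sep="\t", index=False)
    rows = []
    for c, info in cents.items():
        for lv, m, s in zip(info["levels"], info["mean"], info["sd"]):
            rows.append({"cluster": c, "level_db": lv, "mean_win_fraction": m, "sd": s})
    pd.DataFrame(rows).to_csv(ROOT / "centroids.csv", index=False)

    print("cluster-count stability (top lifetimes):")
    for kk, lt in ranked[:4]:
        print(f"  k = {kk:2d}  lifetime = {lt:.2f}")
    sizes = {c: info["n"] for c, info in cents.items()}
    print(f"k = {k} cluster sizes: {sizes}")
    import numpy as np
    for c, info in cents.items():
        peak = info["levels"][int(np.argmax(info["mean"]))]
        print(f"  cluster {c} (n={info['n']}): preferred strength peaks at {peak:g} dB")
    print(f"wrote {ROOT}/clusters.json, centroids.csv, merges.tsv")


if __name__ == "__main__":
    sys.exit(main())
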