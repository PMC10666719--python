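"""Fit the QUL preference model to every participant of the cohort.

Reads results/data/trials.csv (run 01_simulate_cohort.py first), fits the
quadratic-utility-logistic model per participant, and writes the fitted
coefficients, preferred strengths, and diagnostics to results/fits.csv,
reporting how well the fits recover the generative truth.
"""

import pathlib
import sys
from collections import defaultdict

import pandas as pd

from prefnr import qul_model as qm
from prefnr import trial_design as td

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials, _ = td.read_trials(ROOT / "data" / "trials.csv", ROOT / "data" / "meta.csv")
    by_pid: dict[str, list[td.Trial]] = defaultdict(list)
    for t in trials:
        by_pid[t.participant_id].append(t)
    rows = []
    for pid, ts in by_pid.items():
        fit = qm.fit_qul(ts, clamp=(0.0, 18.0))
        rows.append({
            "participant_id": pid, "a": fit.a, "b": fit.b,
            "se_a": fit.se_a, "se_b": fit.se_b, "g_opt": fit.g_opt,
            "at_boundary": fit.at_boundary, "separated": fit.separated,
            "converged": fit.converged, "loglik": fit.log_likelihood,
        })
    fits = pd.DataFrame(rows)
    fits.to_csv(ROOT / "fits.csv", index=False)

    truth = pd.read_csv(ROOT / "data" / "truth.csv")
    merged = fits.merge(truth, on="participant_id", suffixes=("_fit", "_true"))
    err = (merged["g_opt_fit"].clip(0, 18) - merged["g_opt_true"].clip(0, 18)).abs()
    print(f"fitted {len(fits)} participants -> {ROOT / 'fits.csv'}")
    print(f"median |g_opt error|: {err.median():.2f} dB  (max {err.max():.2f} dB)")
    print("fitted preferred strength (dB) medians by group:")
    print(merged.groupby("group").agg(g_opt_median=("g_opt_fit", "median")).round(2).to_string())


if __name__ == "__main__":
    sys.exit(main())
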