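"""Generate the synthetic study cohort.

Three hearing-status groups of ten listeners (normal hearing, mild loss,
moderate loss) with group preferred-strength medians 8.2 / 11.6 / 15.7 dB,
each completing the full 180-trial paired-comparison design.  Writes
trials.csv, meta.csv, and the generative truth table under results/data/.
"""

import pathlib
import sys

import pandas as pd

from prefnr import synthetic_cohort as sc
from prefnr import trial_design as td

SEED = 42
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    cohort = sc.generate_cohort(sc.DEFAULT_SPEC, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    td.write_trials(cohort.trials, cohort.metadata, OUT / "trials.csv", OUT / "meta.csv")
    pd.DataFrame(cohort.truth).to_csv(OUT / "truth.csv", index=False)
    truth = pd.DataFrame(cohort.truth)
    print(f"cohort of {len(cohort.metadata)} participants, {len(cohort.trials)} trials (seed {SEED})")
    print("true preferred strengths (dB) by group:")
    print(truth.groupby("group")["g_opt"].median().round(2).to_string())
    print(f"wrote {OUT}/trials.csv, meta.csv, truth.csv")


if __name__ == "__main__":
    sys.exit(main())
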