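"""Generate the working cohort: 60 subjects from the two-class study scenario.

Thirty subjects are labelled PD and thirty control, with the label drawn
independently of latent class; each subject contributes four cell counts
(two Tower-of-London problems per cell) plus a screening-score covariate
shifted downward for the search-depth-impaired class.

Writes results/cohort.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from tolmpt import study_scenario, simulate, write_dataset

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    out = simulate(study_scenario(seed=SEED))
    RESULTS.mkdir(exist_ok=True)
    write_dataset(out.dataset, RESULTS / "cohort.csv")
    n_floor = int(np.sum(out.true_classes == 1))
    print(f"simulated N={out.dataset.N} subjects (seed {SEED})")
    print(f"  true class split: {out.dataset.N - n_floor} SD+ / {n_floor} SD-")
    print(f"  group split: {int(np.sum(out.dataset.group == 'PD'))} PD / "
          f"{int(np.sum(out.dataset.group == 'control'))} control")
    print(f"  mean correct per cell: {np.round(out.dataset.counts.mean(axis=0), 2)} (LL, GA, SD, HH)")
    print(f"wrote {RESULTS / 'cohort.csv'}")


if __name__ == "__main__":
    main()
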