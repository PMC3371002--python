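"""Is latent-class membership associated with the PD diagnosis?

Assigns each subject to the class with the highest posterior probability,
cross-tabulates assignment against the manifest PD/control label, and runs
the Pearson chi-square (no continuity correction) and two-tailed Fisher
tests.  Also evaluates the published 7/23 vs 9/21 split for reference.

Reads results/cohort.csv; writes results/association.json.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from tolmpt import assign_classes, association_tests, em_fit, read_dataset

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 53


def main() -> None:
    ds = read_dataset(RESULTS / "cohort.csv")
    fit = em_fit(ds, 2, n_starts=12, seed=SEED)
    labels = assign_classes(fit)
    table = np.zeros((2, 2), dtype=int)
    for gi, g in enumerate(("PD", "control")):
        mask = ds.group == g
        table[gi] = [int(np.sum(mask & (labels == 1))), int(np.sum(mask & (labels == 0)))]
    result = association_tests(table)
    print("cohort class-by-diagnosis table (SD- / SD+):")
    print(f"  PD:      {table[0, 0]:2d} / {table[0, 1]:2d}")
    print(f"  control: {table[1, 0]:2d} / {table[1, 1]:2d}")
    print(
        f"  chi2(df=1) = {result.chi2:.3f}, p = {result.p_value:.3f}; "
        f"Fisher two-tailed p = {result.fisher_p_two_tailed:.3f}"
    )

    published = association_tests([[7, 23], [9, 21]])
    print(
        f"published 7/23 vs 9/21 split: chi2(df=1) = {published.chi2:.3f}, "
        f"p = {published.p_value:.3f}"
    )

    payload = {
        "cohort": {
            "table_sd_minus_sd_plus": table.tolist(),
            "chi2": result.chi2,
            "p": result.p_value,
            "fisher_p": result.fisher_p_two_tailed,
        },
        "published_split": {
            "table_sd_minus_sd_plus": [[7, 23], [9, 21]],
            "chi2": published.chi2,
            "p": published.p_value,
        },
    }
    with open(RESULTS / "association.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"wrote {RESULTS / 'association.json'}")


if __name__ == "__main__":
    main()
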