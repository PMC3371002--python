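"""Which parameter separates the two latent classes?

Refits the selected two-class model with each parameter (b, g, s) in turn
constrained to be equal across classes and compares by likelihood ratio.
Only the search-depth parameter s should produce a substantial loss of fit.

Reads results/cohort.csv; writes results/restriction_tests.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from tolmpt import Restriction, em_fit, lr_test, read_dataset

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 37


def main() -> None:
    ds = read_dataset(RESULTS / "cohort.csv")
    full = em_fit(ds, 2, n_starts=12, seed=SEED)
    rows = []
    for name in ("b", "g", "s"):
        restricted = em_fit(ds, 2, n_starts=12, seed=SEED, restriction=Restriction(name))
        test = lr_test(full, restricted)
        verdict = "significant loss" if test.p_value < 0.01 else "no significant loss"
        print(
            f"equality of {name}: delta_l(df={test.df}) = {test.delta_l:.2f}, "
            f"p = {test.p_value:.4f} -> {verdict}"
        )
        rows.append(
            {"parameter": name, "delta_l": test.delta_l, "df": test.df, "p": test.p_value}
        )
    pd.DataFrame(rows).to_csv(RESULTS / "restriction_tests.csv", index=False)
    print(f"wrote {RESULTS / 'restriction_tests.csv'}")


if __name__ == "__main__":
    main()
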