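"""Power analysis for the goodness-of-fit tests.

For each relevant degrees-of-freedom value, computes the central chi-square
critical value at alpha = .01 and the smallest detectable noncentrality at
alpha = beta = .01, converted to Cohen's effect size w for the study's 480
problem trials (60 subjects x 8 problems).

Writes results/power.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from tolmpt import PowerSpec, chi2_critical, detectable_effect

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
N_TRIALS = 480


def main() -> None:
    rows = []
    for df in (1, 3, 7):
        crit = chi2_critical(df, 0.01)
        spec = detectable_effect(PowerSpec(alpha=0.01, beta=0.01, df=df, n_observations=N_TRIALS))
        print(
            f"df={df}: chi2_crit = {crit:.2f}; detectable noncentrality = "
            f"{spec.noncentrality:.2f}, Cohen w = {spec.w:.3f} ({spec.classification})"
        )
        rows.append(
            {
                "df": df,
                "alpha": 0.01,
                "beta": 0.01,
                "chi2_crit": round(crit, 2),
                "noncentrality": spec.noncentrality,
                "cohen_w": spec.w,
                "classification": spec.classification,
            }
        )
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "power.csv", index=False)
    print(f"wrote {RESULTS / 'power.csv'}")


if __name__ == "__main__":
    main()
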