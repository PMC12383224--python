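#!/usr/bin/env python
"""Run the four-framework analysis chain on the simulated cohort.

Screens, scores the scales, estimates traditional / process-dissociation /
CNI / CAN parameters per participant, and correlates chronic stress (PSS-10)
with every decision parameter, adjusting for gender, age, and social
desirability.  On the null cohort every association should be small and
non-significant.  Tables land in results/replication/.
"""

from pathlib import Path

import pandas as pd

from moraldm import run_replication_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "cohort"
    responses = pd.read_csv(data / "responses.csv")
    covariates = pd.read_csv(data / "covariates.csv")
    report = run_replication_pipeline(responses, covariates)
    report.to_dir(ROOT / "replication")

    t = report.tallies
    print(f"analyzed {t['n_analyzed']}/{t['n_input']} participants "
          f"({t['n_cni_excluded']} excluded by CNI model fit)")
    print("\nparameter summaries (M ± SD):")
    print(report.summary.round(3).to_string(index=False))
    print("\nstress-parameter partial correlations (gender, age, social desirability controlled):")
    print(report.correlations[["parameter", "r", "p", "d_equiv", "power", "n"]]
          .round(3).to_string(index=False))
    sig = report.correlations.query("p < 0.05")
    if sig.empty:
        print("\nno stress-parameter association reaches p < 0.05 "
              "(consistent with the null generating regime)")
    else:
        print(f"\n{len(sig)} association(s) at p < 0.05: {list(sig['parameter'])}")


if __name__ == "__main__":
    main()
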