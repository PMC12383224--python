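#!/usr/bin/env python
"""Simulate the reference null cohort used by the downstream analyses.

208 participants, 24-item battery, zero stress-parameter coupling: the
regime in which chronic stress has no effect on moral decision parameters.
Writes the dataset CSVs under results/cohort/.
"""

from pathlib import Path

from moraldm import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20250806


def main() -> None:
    config = SimConfig(seed=SEED)
    cohort = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    responses = cohort["responses_likert"].merge(
        cohort["responses_binary"][["participant_id", "item_id", "accept"]],
        on=["participant_id", "item_id"],
    )
    responses.to_csv(OUT / "responses.csv", index=False)
    cohort["records"].to_csv(OUT / "covariates.csv", index=False)
    cohort["truth"].to_csv(OUT / "truth.csv", index=False)
    cohort["battery"].to_csv(OUT / "battery.csv", index=False)
    print(f"simulated n={config.n_participants} null-coupling cohort (seed {SEED})")
    print(f"PSS-10 total: M={cohort['truth']['pss_total'].mean():.2f}, "
          f"SD={cohort['truth']['pss_total'].std(ddof=1):.2f}")
    print(f"wrote {len(responses)} responses -> {OUT}")


if __name__ == "__main__":
    main()
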