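#!/usr/bin/env python
"""Monte-Carlo calibration of the comparison family.

Two simulations over fresh synthetic populations (n = 5000 each):

* null scenario (identical indicator probabilities in every group) —
  the familywise rejection rate of the nine-domain Bonferroni family at
  alpha = 0.05 should stay at or below the nominal level;
* effect scenario (a 30-point inclusion shift in the education domain for
  the moderate class) — the family should flag education essentially
  always.

Replicate counts here are sized for a quick desk run; the acceptance
script runs the full 500-replicate version.
"""

import json
from pathlib import Path

from inclusion_monitor.reporting import simulate_family_rejections
from inclusion_monitor.synthetic_data import default_scenario, effect_scenario, null_scenario

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 2019


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    base = null_scenario(default_scenario(n_respondents=5000))

    null_report = simulate_family_rejections(base, n_reps=200, alpha=0.05, seed=SEED)
    print(f"null scenario, 200 replicates: familywise rejection rate "
          f"{null_report['familywise_rate']:.3f} (nominal 0.05)")

    eff = effect_scenario(base, "education", shift=0.30)
    power_report = simulate_family_rejections(eff, n_reps=50, alpha=0.05, seed=SEED + 1)
    power = power_report["per_domain_rate"].get("education", 0.0)
    print(f"effect scenario, 50 replicates: education detected in {power:.0%} of runs")

    report = {
        "null": null_report,
        "effect": power_report,
        "education_power": power,
    }
    (RESULTS / "simulation_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(f"report written to {RESULTS / 'simulation_report.json'}")


if __name__ == "__main__":
    main()
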