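#!/usr/bin/env python
"""Integrated-management scenarios: predation rates vs required culling.

Sweeps the ant predation rates (alpha on adults, delta on immatures) and
reports, for each scenario, the eradication mortality mu* and the minimum
number of adult borers that other control measures (traps, targeted
spraying) must kill per day: ceil(A_max * mu*) with A_max = omega*q/0.03.
Writes results/management_sweep.csv and results/management_report.json.
"""

import json
from pathlib import Path

from cbb_ants import baseline_params, no_predation_requirement, sweep

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    p = baseline_params()
    pairs = [(0.01, 0.01), (0.011, 0.01), (0.01, 0.011), (0.011, 0.011)]
    table = sweep(p, pairs, mu_ref=0.03)
    frame = table.to_frame()
    frame.to_csv(RESULTS / "management_sweep.csv", index=False)
    print("management scenarios (mu_ref = 0.03):")
    print(frame.round(4).to_string(index=False))

    baseline_deaths = table.rows[0].required_deaths
    no_pred = no_predation_requirement(p, mu_ref=0.03)
    report = {
        "mu_ref": table.mu_ref,
        "rows": [r.__dict__ for r in table.rows],
        "no_predation_requirement": no_pred,
        "note": (
            "mu* follows the closed form phi*omega/(k*delta+theta+omega) - k*alpha; "
            "published tabulations of the two asymmetric scenarios interchange the "
            "alpha/delta columns relative to this formula."
        ),
    }
    (RESULTS / "management_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(
        f"\nFinding: with ants predating at the baseline rates the grower must kill "
        f"only {baseline_deaths} adult borers per day by other means to eradicate the "
        f"pest, versus {no_pred} per day without any predation — and a 10% increase "
        f"of both predation rates cuts the figure to {table.rows[3].required_deaths}."
    )


if __name__ == "__main__":
    main()
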