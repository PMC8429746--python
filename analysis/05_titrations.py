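"""Dissociation constants from simulated amplitude titrations.

For each construct/agonist scenario, simulates the decay of the summed
sub-ms relaxation amplitude over an 8-point concentration series spanning
0.1-100x K_d with 5% amplitude noise, fits the binding isotherm, and
writes results/titrations.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from petfcs import TitrationSeries, fit_titration, fraction_bound
from petfcs.datasets import KD_MOLAR

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026
A_UNBOUND = 0.5  # summed sub-ms amplitude of the apo state
A_BOUND = 0.05   # residual fast amplitude in the bound state


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    rows = []
    for i, (label, kd) in enumerate(KD_MOLAR.items()):
        conc = np.geomspace(0.1 * kd, 100 * kd, 8)
        truth = A_UNBOUND + (A_BOUND - A_UNBOUND) * fraction_bound(conc, kd)
        rng = np.random.default_rng(SEED + i)
        amp = truth * (1 + rng.normal(0, 0.05, conc.size))
        fit = fit_titration(TitrationSeries(conc, amp), seed=SEED + i)
        rows.append({"scenario": label, "kd_true_uM": kd * 1e6,
                     "kd_fit_uM": round(fit.kd * 1e6, 2),
                     "kd_se_uM": round((fit.kd_se or float("nan")) * 1e6, 2),
                     "a_unbound": round(fit.a_unbound, 3),
                     "a_bound": round(fit.a_bound, 3),
                     "converged": fit.converged})
        print(f"{label}: K_d = {fit.kd * 1e6:.2f} uM "
              f"(truth {kd * 1e6:.1f} uM)")
    pd.DataFrame(rows).to_csv(ROOT / "titrations.csv", index=False)
    print(f"\ntable -> {ROOT / 'titrations.csv'}")


if __name__ == "__main__":
    main()
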