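"""Stall-scan verdicts per construct family.

For each LBD family (GluA2 monomer, GluK1 monomer, GluN1 monomer, GluA2
dimer, GluN1/GluN2A hetero-dimer, Y535S hetero-dimer) the family's apo
condition is the reference; every other condition is classified phase by
phase as matched / stalled / emergent.  Also reports the dimerization
effect (tau and amplitude ratios) for the monomer-versus-dimer apo pairs.
Writes results/stall_verdicts.csv and results/dimerization_effect.csv.
"""

from pathlib import Path

import pandas as pd

from petfcs import (Condition, ConditionSet, StallScanConfig,
                    dimerization_report, run_stall_scan)
from petfcs.io import read_curve

ROOT = Path(__file__).resolve().parents[1] / "results"

FAMILIES = {
    "GluA2 monomer": ["apo", "quisqualate", "glutamate", "willardiine",
                      "5-iodo-willardiine", "kainate"],
    "GluK1 monomer": ["apo", "glutamate"],
    "GluN1 monomer": ["apo", "glycine"],
    "GluA2 dimer": ["apo", "Glu"],
    "GluN1/GluN2A dimer": ["apo", "Gly", "Glu-on-partner"],
    "GluN1-Y535S/GluN2A dimer": ["apo", "Gly", "Glu-on-partner"],
}

DIMER_PAIRS = [("GluA2 monomer apo", "GluA2 dimer apo"),
               ("GluN1 monomer apo", "GluN1/GluN2A dimer apo")]


def slug(label: str) -> str:
    return label.replace("/", "-").replace(" ", "_").lower()


def load(label: str):
    return read_curve(ROOT / "curves" / f"{slug(label)}.csv")


def main() -> None:
    config = StallScanConfig(seed=2026)
    verdict_frames = []
    fits = {}
    for family, conditions in FAMILIES.items():
        cset = ConditionSet(
            [Condition(c, load(f"{family} {c}")) for c in conditions],
            reference="apo")
        report = run_stall_scan(cset, config)
        fits.update({f"{family} {k}": v for k, v in report.fits.items()})
        frame = report.verdicts.copy()
        frame.insert(0, "family", family)
        verdict_frames.append(frame)
        for _, row in frame.iterrows():
            print(f"{family} | {row['condition']}: "
                  f"{row['n_stalled_vs_reference']} phase(s) stalled, "
                  f"residual fast phase: {row['residual_fast_phase']}")
    verdicts = pd.concat(verdict_frames, ignore_index=True)
    verdicts.to_csv(ROOT / "stall_verdicts.csv", index=False)

    rows = []
    for mono, dim in DIMER_PAIRS:
        table = dimerization_report(fits[mono.replace(" apo", "") + " apo"],
                                    fits[dim.replace(" apo", "") + " apo"])
        table.insert(0, "pair", f"{mono} vs {dim}")
        rows.append(table)
        slowed = table["slowed"].sum()
        damped = table["damped"].sum()
        print(f"{mono} -> {dim}: {slowed} phase(s) slowed, {damped} damped")
    pd.concat(rows, ignore_index=True).to_csv(
        ROOT / "dimerization_effect.csv", index=False)
    print(f"\nverdicts -> {ROOT / 'stall_verdicts.csv'}")


if __name__ == "__main__":
    main()
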