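"""Fit every condition curve with nested model selection.

Reads the curves written by 01_simulate_conditions.py, runs the F-test
ladder with sanity filters per condition, and writes (i) a JSON selection
report per condition and (ii) a flat amplitude/time-constant table
(results/kinetics_table.csv) in the layout of a per-condition kinetics
table: one column per condition, a_n / tau_n row pairs sorted slowest
first.
"""

from pathlib import Path

from petfcs import select_model
from petfcs.io import fits_to_table, read_curve, write_fit_json

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def main() -> None:
    curves = sorted((ROOT / "curves").glob("*.csv"))
    if not curves:
        raise SystemExit("no curves found; run 01_simulate_conditions.py first")
    (ROOT / "fits").mkdir(exist_ok=True)
    fits = {}
    for path in curves:
        curve = read_curve(path)
        label = curve.provenance.split("|")[0].strip() or path.stem
        report = select_model(curve, seed=SEED)
        fits[label] = report.selected
        write_fit_json(report, ROOT / "fits" / f"{path.stem}.json")
        print(f"{label}: selected {report.selected.n_exp} exponential(s), "
              f"chi2/dof = {report.selected.chi2 / report.selected.dof:.2f}")
    table = fits_to_table(fits)
    table.to_csv(ROOT / "kinetics_table.csv")
    print(f"\nkinetics table with {table.shape[1]} conditions -> "
          f"{ROOT / 'kinetics_table.csv'}")


if __name__ == "__main__":
    main()
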