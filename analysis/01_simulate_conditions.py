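"""Generate the synthetic study conditions.

Draws one noisy correlation curve per condition of the design matrix
(three iGluR LBD subtypes, apo and agonist-bound, monomer and dimer,
hetero-dimer allostery controls) on the default multi-tau grid with the
default 10-minute noise level, and writes them as curve CSVs under
results/curves/.
"""

from pathlib import Path

from petfcs import default_lag_grid, synth_acf
from petfcs.datasets import DEFAULT_DIFFUSION, design_matrix
from petfcs.io import write_curve

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "curves"


def slug(label: str) -> str:
    return label.replace("/", "-").replace(" ", "_").lower()


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = default_lag_grid()
    matrix = design_matrix()
    for i, (label, phases) in enumerate(matrix.items()):
        curve = synth_acf(DEFAULT_DIFFUSION, phases, grid,
                          noise_scale=0.01, duration=600.0, seed=SEED + i)
        curve.provenance = f"{label} | " + curve.provenance
        write_curve(curve, OUT / f"{slug(label)}.csv")
        print(f"wrote {slug(label)}.csv  ({len(phases)} kinetic phases)")
    print(f"\n{len(matrix)} condition curves under {OUT}")


if __name__ == "__main__":
    main()
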