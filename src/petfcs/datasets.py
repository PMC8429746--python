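"""Literature inputs and generator defaults for iGluR LBD clamshell dynamics.

Reported sub-ms kinetic parameters, hydrodynamic radii and dissociation
constants for isolated ionotropic-glutamate-receptor ligand-binding
domains measured by PET-FCS.  These printed values serve as inputs: they
parameterize the synthetic-data generator (the study conditions the
analysis pipeline is exercised under) and the worked examples.  Values
marked *representative* were read from bar-graph scale only and are
order-of-magnitude placeholders, not printed numbers.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .acf_models import DiffusionComponent, KineticPhase

__all__ = [
    "GLUA2_KINETICS", "GLUN1_KINETICS", "GLUK1_KINETICS", "DIMER_KINETICS",
    "DEFAULT_DIFFUSION", "RH_FCS_NM", "RH_XRAY_NM", "MONOMER_DIMER_PAIRS",
    "KD_MOLAR", "design_matrix",
]

#: Curves in the figures are normalized to the mean number of molecules,
#: so the canonical synthetic conditions use N = 1 and an LBD-scale
#: diffusion time of 0.5 ms.
DEFAULT_DIFFUSION = DiffusionComponent(n_molecules=1.0, tau_d=0.5e-3)


def _phases(pairs: List[Tuple[float, float]]) -> List[KineticPhase]:
    return [KineticPhase(amplitude=a, tau=t) for a, t in pairs]


#: GluA2 LBD (G446C-T685W reporter) sub-ms kinetics per agonist:
#: (amplitude, time constant in s), slowest first.  Printed values
#: (mean of three measurements).
GLUA2_KINETICS: Dict[str, List[KineticPhase]] = {
    "apo": _phases([(0.17, 113e-6), (0.25, 6e-6), (0.48, 320e-9)]),
    "quisqualate": _phases([(0.06, 4e-6), (0.22, 180e-9)]),
    "glutamate": _phases([(0.20, 300e-9)]),
    "willardiine": _phases([(0.17, 290e-9)]),
    "5-iodo-willardiine": _phases([(0.05, 7e-6), (0.22, 116e-9)]),
    "kainate": _phases([(0.15, 190e-9)]),
}

#: GluN1 LBD (A480C reporter), representative values: three apo modes on
#: the ~100 µs / ~10 µs / ~1 µs scales; glycine leaves only a minor
#: few-µs residual below the 10% assignment threshold.
GLUN1_KINETICS: Dict[str, List[KineticPhase]] = {
    "apo": _phases([(0.15, 100e-6), (0.20, 10e-6), (0.30, 1e-6)]),
    "glycine": _phases([(0.07, 5e-6)]),
}

#: GluK1 LBD (K503C-K734W reporter), representative values: four apo
#: modes; glutamate stalls the µs modes while the ~200-ns amplitude grows.
GLUK1_KINETICS: Dict[str, List[KineticPhase]] = {
    "apo": _phases([(0.10, 150e-6), (0.15, 15e-6), (0.20, 2e-6), (0.25, 200e-9)]),
    "glutamate": _phases([(0.45, 200e-9)]),
}

#: Dimer scenarios (representative): dimerization slows all sub-ms
#: relaxations (τ up) and damps their amplitudes; agonist binding stalls
#: the µs modes in dimers as in monomers.  The hetero-dimer rows encode
#: the allosteric pattern: glutamate on the partner LBD stalls the
#: glycine-site LBD unless the interface tyrosine is removed (Y535S).
DIMER_KINETICS: Dict[str, List[KineticPhase]] = {
    "GluA2 dimer apo": _phases([(0.12, 226e-6), (0.15, 12e-6), (0.29, 640e-9)]),
    "GluA2 dimer Glu": _phases([(0.15, 300e-9)]),
    "GluN1/GluN2A dimer apo": _phases([(0.12, 200e-6), (0.14, 20e-6), (0.18, 2e-6)]),
    "GluN1/GluN2A dimer Gly": _phases([(0.06, 5e-6)]),
    "GluN1/GluN2A dimer Glu-on-partner": _phases([(0.06, 5e-6)]),
    "GluN1-Y535S/GluN2A dimer apo": _phases([(0.12, 200e-6), (0.14, 20e-6), (0.18, 2e-6)]),
    "GluN1-Y535S/GluN2A dimer Gly": _phases([(0.06, 5e-6)]),
    "GluN1-Y535S/GluN2A dimer Glu-on-partner":
        _phases([(0.12, 200e-6), (0.14, 20e-6), (0.18, 2e-6)]),
}

#: FCS hydrodynamic radii (nm, mean ± s.d. of three measurements).
RH_FCS_NM: Dict[str, Tuple[float, float]] = {
    "GluA2 monomer apo": (2.9, 0.1),
    "GluA2 monomer Glu": (2.7, 0.1),
    "GluA2 dimer apo": (3.8, 0.2),
    "GluA2 dimer Glu": (3.3, 0.2),
    "GluN1 monomer apo": (2.6, 0.2),
    "GluN1 monomer Gly": (2.4, 0.1),
    "GluN1/GluN2A dimer apo": (3.5, 0.3),
    "GluN1/GluN2A dimer Gly/Glu": (3.2, 0.4),
}

#: Crystal-structure radii (nm) via the sphere law, where structures exist.
RH_XRAY_NM: Dict[str, float] = {
    "GluA2 monomer apo": 2.5,
    "GluA2 monomer Glu": 2.4,
    "GluA2 dimer apo": 3.1,
    "GluA2 dimer Glu": 3.0,
    "GluN1 monomer apo": 2.6,
    "GluN1 monomer Gly": 2.5,
    "GluN1/GluN2A dimer Gly/Glu": 3.2,
}

#: The four printed monomer/dimer pairs entering the dimerization-effect
#: arithmetic on Rh(FCS).
MONOMER_DIMER_PAIRS: List[Tuple[str, str]] = [
    ("GluA2 monomer apo", "GluA2 dimer apo"),
    ("GluA2 monomer Glu", "GluA2 dimer Glu"),
    ("GluN1 monomer apo", "GluN1/GluN2A dimer apo"),
    ("GluN1 monomer Gly", "GluN1/GluN2A dimer Gly/Glu"),
]

#: Equilibrium dissociation constants (molar) from the amplitude
#: titrations, used as scenario ground truths for K_d recovery.
KD_MOLAR: Dict[str, float] = {
    "GluA2/Glu": 2.4e-6,
    "GluK1/Glu": 7e-6,
    "GluN1/Gly": 13e-6,
}


def design_matrix() -> Dict[str, List[KineticPhase]]:
    """The full set of synthetic study conditions: monomers of the three
    subtypes ± agonist, the GluA2 homo-dimer, the GluN1/GluN2A hetero-dimer
    with its allostery controls, and the Y535S uncoupling mutant."""
    out: Dict[str, List[KineticPhase]] = {}
    for cond, phases in GLUA2_KINETICS.items():
        out[f"GluA2 monomer {cond}"] = phases
    for cond, phases in GLUN1_KINETICS.items():
        out[f"GluN1 monomer {cond}"] = phases
    for cond, phases in GLUK1_KINETICS.items():
        out[f"GluK1 monomer {cond}"] = phases
    out.update(DIMER_KINETICS)
    return out
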