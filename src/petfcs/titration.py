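"""Equilibrium dissociation constants from FCS amplitude titrations.

With increasing agonist concentration the sub-ms relaxation amplitude of
the ACF decays from its unbound value ``a_u`` towards the bound value
``a_b`` following a 1:1 binding isotherm (P + L ⇌ PL):

    a([L]) = a_u + (a_b - a_u) · [L]/([L] + K_d)

At the ~1 nM labelled-protein concentrations typical of FCS the free
ligand concentration equals the total to high accuracy;
:func:`free_ligand_correction` quantifies that approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import lmfit
import numpy as np

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "fraction_bound",
    "fit_titration",
    "free_ligand_correction",
]


@dataclass
class TitrationSeries:
    """Ligand concentrations (molar) and observed relaxation amplitudes."""

    ligand_conc: np.ndarray
    amplitude: np.ndarray
    amplitude_se: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.ligand_conc.shape != self.amplitude.shape:
            raise ValueError("ligand_conc and amplitude must have equal length")
        if np.any(self.ligand_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.amplitude_se is not None:
            self.amplitude_se = np.asarray(self.amplitude_se, dtype=float)
            if self.amplitude_se.shape != self.amplitude.shape:
                raise ValueError("amplitude_se must match amplitude")
            if np.any(self.amplitude_se <= 0):
                raise ValueError("amplitude_se must be positive")

    @property
    def n_distinct(self) -> int:
        return np.unique(self.ligand_conc).size


@dataclass
class BindingFit:
    kd: float
    a_unbound: float
    a_bound: float
    kd_se: Optional[float]
    a_unbound_se: Optional[float]
    a_bound_se: Optional[float]
    chi2: float
    converged: bool
    seed: int = 0


def fraction_bound(ligand_conc, kd: float):
    """Bound fraction ``[L]/([L] + K_d)`` of the 1:1 isotherm."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc = np.asarray(ligand_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand_conc must be non-negative")
    f = conc / (conc + kd)
    return f if f.ndim else float(f)


def fit_titration(series: TitrationSeries, seed: int = 0) -> BindingFit:
    """Weighted nonlinear fit of (K_d, a_u, a_b) to an amplitude titration.

    Multistart over K_d on a log grid spanning [min positive conc/10,
    max conc·10]; deterministic given the seed (recorded; no randomness in
    the procedure).  A series whose amplitudes carry no concentration
    dependence yields an unidentifiable K_d and is returned flagged
    ``converged=False``.
    """
    if series.n_distinct < 4:
        raise ValueError("need at least 4 distinct ligand concentrations")
    if np.ptp(series.amplitude) == 0:
        raise ValueError("amplitudes are all equal; binding is unidentifiable")
    conc = series.ligand_conc
    amp = series.amplitude
    w = 1.0 / series.amplitude_se if series.amplitude_se is not None else np.ones_like(amp)

    pos = conc[conc > 0]
    kd_lo, kd_hi = pos.min() / 10.0, conc.max() * 10.0

    def residual(params):
        kd = params["kd"].value
        a_u = params["a_u"].value
        a_b = params["a_b"].value
        model = a_u + (a_b - a_u) * conc / (conc + kd)
        return (model - amp) * w

    best = None
    for kd0 in np.geomspace(kd_lo, kd_hi, 7):
        params = lmfit.Parameters()
        params.add("kd", value=kd0, min=kd_lo / 10.0, max=kd_hi * 10.0)
        params.add("a_u", value=float(amp[np.argmin(conc)]))
        params.add("a_b", value=float(amp[np.argmax(conc)]))
        try:
            res = lmfit.minimize(residual, params, method="least_squares",
                                 nan_policy="raise")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all titration fit starts failed")

    p = best.params
    kd_se = p["kd"].stderr
    # unidentifiable plateau: K_d pinned at a bound or errors unbounded
    at_bound = (p["kd"].value <= kd_lo / 9.0) or (p["kd"].value >= kd_hi * 9.0)
    unbounded = kd_se is not None and np.isfinite(kd_se) and kd_se > 10 * p["kd"].value
    converged = bool(best.success) and not at_bound and not unbounded
    return BindingFit(
        kd=float(p["kd"].value), a_unbound=float(p["a_u"].value),
        a_bound=float(p["a_b"].value),
        kd_se=kd_se, a_unbound_se=p["a_u"].stderr, a_bound_se=p["a_b"].stderr,
        chi2=float(best.chisqr), converged=converged, seed=seed)


def free_ligand_correction(total_ligand: float, protein_total: float, kd: float) -> float:
    """Free ligand concentration from the quadratic mass balance.

    Solves ``L² + (K_d + P_t - L_t)·L - K_d·L_t = 0`` for the free ligand.
    Equals the total within 0.1% whenever ``P_t ≤ K_d/100`` — the regime of
    ~1 nM labelled protein that justifies using total concentrations on the
    titration axis.
    """
    if total_ligand < 0 or protein_total < 0:
        raise ValueError("concentrations must be non-negative")
    if kd <= 0:
        raise ValueError("kd must be positive")
    if total_ligand == 0:
        return 0.0
    b = kd + protein_total - total_ligand
    free = (-b + np.sqrt(b * b + 4.0 * kd * total_ligand)) / 2.0
    return float(free)
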