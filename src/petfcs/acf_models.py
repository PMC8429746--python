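"""Closed-form fluorescence correlation models for PET-FCS.

The observable is the (cross-)correlation function G(τ) of fluorescence
intensity fluctuations of labelled molecules diffusing through a confocal
detection focus.  Two ingredients are modelled:

* translational diffusion through an effectively two-dimensional Gaussian
  focus, giving ``G(τ) = (1/N) (1 + τ/τ_D)^-1`` where ``N`` is the mean
  number of molecules in the focus and ``τ_D`` the diffusion time;
* quencher-gated conformational exchange.  A fluorophore that is quenched
  on contact with a tryptophan side chain converts a two-state
  conformational equilibrium into a bright/dim telegraph process, which
  multiplies the diffusive decay by ``(1 + a·exp(-τ/τ_rel))``.  Several
  independent exchange processes multiply in as a sum of exponentials
  inside one bracket.

G is represented *without* the +1 baseline throughout the package;
instrument files carrying a baseline must be read through
:func:`petfcs.io.read_alv_asc`, which subtracts it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DiffusionComponent",
    "KineticPhase",
    "TwoStateScheme",
    "diffusion_acf",
    "full_acf",
    "scheme_to_phase",
    "phase_to_rates",
    "max_amplitude",
]


@dataclass(frozen=True)
class DiffusionComponent:
    """Diffusive part of the ACF.

    Parameters
    ----------
    n_molecules:
        Mean number of molecules in the detection focus (dimensionless, > 0).
    tau_d:
        Diffusion time constant in seconds (> 0); the mean dwell time of a
        molecule in the focus, ``τ_D = w²/(4D)`` for a planar Gaussian focus
        of 1/e² radius ``w``.
    """

    n_molecules: float
    tau_d: float
    n_molecules_se: Optional[float] = None
    tau_d_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n_molecules) and self.n_molecules > 0):
            raise ValueError(f"n_molecules must be positive, got {self.n_molecules}")
        if not (np.isfinite(self.tau_d) and self.tau_d > 0):
            raise ValueError(f"tau_d must be positive, got {self.tau_d}")


@dataclass(frozen=True)
class KineticPhase:
    """One exponential relaxation of the ACF: amplitude ``a`` and time
    constant ``τ`` (seconds) of a two-state conformational exchange."""

    amplitude: float
    tau: float
    amplitude_se: Optional[float] = None
    tau_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        for name in ("amplitude_se", "tau_se"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative if given, got {v}")


@dataclass(frozen=True)
class TwoStateScheme:
    """Microscopic bright/dim two-state exchange.

    ``k_bright_to_dim`` and ``k_dim_to_bright`` are the microscopic rate
    constants (s⁻¹) of the telegraph process; ``brightness_ratio`` is
    q = (dim-state brightness)/(bright-state brightness) in [0, 1].
    q = 0 means full quenching in the dim state.
    """

    k_bright_to_dim: float
    k_dim_to_bright: float
    brightness_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_bright_to_dim) and self.k_bright_to_dim > 0):
            raise ValueError("k_bright_to_dim must be positive")
        if not (np.isfinite(self.k_dim_to_bright) and self.k_dim_to_bright > 0):
            raise ValueError("k_dim_to_bright must be positive")
        if not (0.0 <= self.brightness_ratio <= 1.0):
            raise ValueError("brightness_ratio must lie in [0, 1]")

    @property
    def relaxation_time(self) -> float:
        """Relaxation time 1/(k12 + k21) in seconds."""
        return 1.0 / (self.k_bright_to_dim + self.k_dim_to_bright)

    @property
    def p_bright(self) -> float:
        """Equilibrium population of the bright state."""
        return self.k_dim_to_bright / (self.k_bright_to_dim + self.k_dim_to_bright)


def _check_lag(lag) -> np.ndarray:
    lag = np.asarray(lag, dtype=float)
    if not np.all(np.isfinite(lag)):
        raise ValueError("lag must be finite")
    if np.any(lag < 0):
        raise ValueError("lag must be non-negative")
    return lag


def diffusion_acf(lag, comp: DiffusionComponent):
    """Planar-diffusion ACF ``(1/N)·(1 + τ/τ_D)^-1``.

    Accepts a scalar or array of lag times (seconds, ≥ 0); returns the
    dimensionless baseline-free correlation amplitude.
    """
    lag = _check_lag(lag)
    g = (1.0 / comp.n_molecules) / (1.0 + lag / comp.tau_d)
    return g if g.ndim else float(g)


def full_acf(lag, comp: DiffusionComponent, phases: Sequence[KineticPhase] = ()):
    """Diffusion ACF multiplied by ``1 + Σ aₙ·exp(-τ/τₙ)``.

    With an empty phase list this reduces exactly to :func:`diffusion_acf`.
    """
    lag = _check_lag(lag)
    kin = np.ones_like(lag)
    for ph in phases:
        kin = kin + ph.amplitude * np.exp(-lag / ph.tau)
    g = (1.0 / comp.n_molecules) / (1.0 + lag / comp.tau_d) * kin
    return g if g.ndim else float(g)


def scheme_to_phase(scheme: TwoStateScheme) -> KineticPhase:
    """Map microscopic two-state quenching kinetics to the observable
    exponential phase.

    The relaxation time is ``τ = 1/(k12 + k21)``.  With equilibrium
    populations ``p_B = k21/(k12+k21)``, ``p_D = 1 - p_B`` and relative dim
    brightness ``q``, the reaction term of the correlation function of the
    brightness telegraph signal has amplitude

        a = p_B·p_D·(1 - q)² / (p_B + p_D·q)²

    (the standard two-state reaction-FCS result; only the brightness *ratio*
    matters, not the absolute brightnesses).
    """
    tau = scheme.relaxation_time
    p_b = scheme.p_bright
    p_d = 1.0 - p_b
    q = scheme.brightness_ratio
    mean_brightness = p_b + p_d * q
    if mean_brightness == 0.0:  # unreachable for valid schemes (p_b > 0)
        raise ValueError("mean brightness is zero")
    amplitude = p_b * p_d * (1.0 - q) ** 2 / mean_brightness**2
    return KineticPhase(amplitude=amplitude, tau=tau)


def max_amplitude(q: float) -> float:
    """Largest reaction amplitude achievable at dim/bright brightness ratio q.

    For q = 0 the amplitude ``a = p_D/p_B`` is unbounded (returns ``inf``);
    for q > 0 the maximum over the bright-state population is attained at
    ``p_B = q/(1+q)`` giving ``(1-q)²/(4q)``.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if q == 0.0:
        return math.inf
    if q == 1.0:
        return 0.0
    return (1.0 - q) ** 2 / (4.0 * q)


def phase_to_rates(phase: KineticPhase, q: float = 0.0) -> TwoStateScheme:
    """Invert :func:`scheme_to_phase`: recover microscopic rates from an
    observed (amplitude, τ) pair at brightness ratio q.

    The amplitude equation is quadratic in the bright-state population; when
    two roots are feasible the dim-majority branch (p_D ≥ p_B) is returned by
    convention.  Raises a ``ValueError`` naming the feasible maximum when the
    requested amplitude cannot be produced at this q.
    """
    a, tau = phase.amplitude, phase.tau
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if a <= 0:
        raise ValueError("amplitude must be positive to identify rates")
    a_max = max_amplitude(q)
    if a > a_max * (1 + 1e-12):
        raise ValueError(
            f"amplitude {a} infeasible at brightness ratio q={q}; "
            f"maximum achievable is {a_max:.6g}"
        )
    if q == 0.0:
        # a = p_D/p_B  ->  p_B = 1/(1+a), unique root
        p_b = 1.0 / (1.0 + a)
    else:
        # (1-q)² (1+a) p² - [(1-q)² - 2aq(1-q)] p + a q² = 0, p = p_B
        one_m_q = 1.0 - q
        A = one_m_q**2 * (1.0 + a)
        B = -(one_m_q**2 - 2.0 * a * q * one_m_q)
        C = a * q**2
        disc = max(B * B - 4.0 * A * C, 0.0)
        sq = math.sqrt(disc)
        # numerically stable root pair (avoids cancellation for small C)
        if B >= 0:
            r1 = (-B - sq) / (2 * A)
        else:
            r1 = (-B + sq) / (2 * A)
        r2 = (C / (A * r1)) if r1 != 0 else 0.0
        roots = sorted((r1, r2))
        feasible = [p for p in roots if 0.0 < p < 1.0]
        if not feasible:
            raise ValueError(
                f"amplitude {a} infeasible at q={q}; maximum is {a_max:.6g}"
            )
        # dim-majority convention: smallest feasible p_B
        p_b = feasible[0]
    k_sum = 1.0 / tau
    return TwoStateScheme(
        k_bright_to_dim=(1.0 - p_b) * k_sum,
        k_dim_to_bright=p_b * k_sum,
        brightness_ratio=q,
    )
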