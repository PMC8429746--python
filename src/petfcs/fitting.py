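"""Weighted nonlinear fitting of correlation curves and nested model selection.

The fitting model is the planar-diffusion ACF multiplied by a sum of 0–5
exponential relaxations.  Model complexity (the number of exponentials) is
chosen by a nested ladder: an additional exponential is accepted only if a
nested F-test on the weighted residual sums is significant *and* the
enlarged fit passes sanity filters that operationalize "physically
unreasonable fitting parameters" (vanishing amplitudes, exploding standard
errors, indistinguishable or out-of-window time constants).

Time constants are fitted in log-space for conditioning across the five
decades a multi-tau grid spans; reported values, uncertainties and the
covariance are transformed back to natural units.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .acf_models import DiffusionComponent, KineticPhase
from .synthetic import CorrelationCurve

__all__ = [
    "ACFModelFit",
    "SelectionReport",
    "PhaseComparison",
    "fit_acf",
    "select_model",
    "assign_phases",
    "compare_conditions",
]


@dataclass
class ACFModelFit:
    """Result of fitting the diffusion × multi-exponential model."""

    diffusion: DiffusionComponent
    phases: List[KineticPhase]  # sorted by decreasing tau
    n_exp: int
    chi2: float
    dof: int
    residuals: np.ndarray
    covariance: Optional[np.ndarray]
    converged: bool
    seed: int
    lag_min: float
    lag_max: float
    weighted: bool

    def __post_init__(self) -> None:
        if self.n_exp != len(self.phases):
            raise ValueError("n_exp must equal the number of phases")
        taus = [p.tau for p in self.phases]
        if taus != sorted(taus, reverse=True):
            raise ValueError("phases must be sorted by decreasing tau")

    def model(self, lag) -> np.ndarray:
        from .acf_models import full_acf

        return full_acf(lag, self.diffusion, self.phases)

    @property
    def parameters(self) -> Dict[str, float]:
        out = {"n_molecules": self.diffusion.n_molecules,
               "tau_d": self.diffusion.tau_d}
        for i, p in enumerate(self.phases, start=1):
            out[f"a{i}"] = p.amplitude
            out[f"tau{i}"] = p.tau
        return out

    def to_dict(self) -> dict:
        d = self.diffusion
        return {
            "n_molecules": d.n_molecules, "n_molecules_se": d.n_molecules_se,
            "tau_d": d.tau_d, "tau_d_se": d.tau_d_se,
            "phases": [
                {"amplitude": p.amplitude, "amplitude_se": p.amplitude_se,
                 "tau": p.tau, "tau_se": p.tau_se}
                for p in self.phases
            ],
            "n_exp": self.n_exp, "chi2": self.chi2, "dof": self.dof,
            "converged": self.converged, "seed": self.seed,
            "lag_min": self.lag_min, "lag_max": self.lag_max,
            "weighted": self.weighted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ACFModelFit":
        phases = [KineticPhase(p["amplitude"], p["tau"],
                               p.get("amplitude_se"), p.get("tau_se"))
                  for p in d["phases"]]
        return cls(
            diffusion=DiffusionComponent(d["n_molecules"], d["tau_d"],
                                         d.get("n_molecules_se"), d.get("tau_d_se")),
            phases=phases, n_exp=d["n_exp"], chi2=d["chi2"], dof=d["dof"],
            residuals=np.array([]), covariance=None,
            converged=d["converged"], seed=d.get("seed", 0),
            lag_min=d["lag_min"], lag_max=d["lag_max"],
            weighted=d.get("weighted", True),
        )


# ---------------------------------------------------------------------------
# core least-squares machinery


def _unpack(theta: np.ndarray, n_exp: int, fixed_n: Optional[float]):
    """theta layout: [N (unless fixed), log tau_d, (a_i, log tau_i)*n]."""
    i = 0
    if fixed_n is None:
        n_mol = theta[0]
        i = 1
    else:
        n_mol = fixed_n
    tau_d = math.exp(theta[i]); i += 1
    amps = theta[i::2][:n_exp]
    taus = np.exp(theta[i + 1::2][:n_exp])
    return n_mol, tau_d, amps, taus


def _model(theta, lags, n_exp, fixed_n):
    n_mol, tau_d, amps, taus = _unpack(theta, n_exp, fixed_n)
    kin = 1.0 + (np.exp(-lags[:, None] / taus[None, :]) @ amps if n_exp else 0.0)
    return (1.0 / n_mol) / (1.0 + lags / tau_d) * kin


def _pack(n_mol, tau_d, amps, taus, fixed_n):
    head = [] if fixed_n is not None else [n_mol]
    tail = []
    for a, t in zip(amps, taus):
        tail += [a, math.log(t)]
    return np.array(head + [math.log(tau_d)] + tail)


def fit_acf(
    curve: CorrelationCurve,
    n_exp: int,
    fix_n_molecules: Optional[float] = None,
    seed: int = 0,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> ACFModelFit:
    """Weighted least-squares fit with multistart initialization.

    Minimizes ``Σ w_k (g_k - model_k)²`` with ``w_k = 1/g_se_k²`` when the
    curve carries per-lag uncertainties, unweighted otherwise.  Time
    constants start on a 5-point log grid over the lag window, explored
    combinatorially (τ descending); the best-of-starts solution is returned
    with covariance-derived standard errors.  Deterministic given the seed
    (the seed is recorded; the procedure itself has no randomness).

    ``fix_n_molecules=1`` supports curves pre-normalized to the mean number
    of molecules.  ``extra_starts`` injects additional start vectors in the
    internal parameterization (used by :func:`select_model` to warm-start
    the nested ladder).
    """
    lags = curve.lags
    g = curve.g
    n_par = 2 + 2 * n_exp
    if fix_n_molecules is not None and fix_n_molecules <= 0:
        raise ValueError("fix_n_molecules must be positive")
    if lags.size < n_par + 1:
        raise ValueError(
            f"curve has {lags.size} lags; need at least {n_par + 1} for n_exp={n_exp}")
    if np.ptp(g) == 0:
        raise ValueError("degenerate curve: g is constant")
    if n_exp < 0:
        raise ValueError("n_exp must be >= 0")

    weighted = curve.g_se is not None
    w = 1.0 / curve.g_se if weighted else np.ones_like(g)

    def residual(theta):
        return (_model(theta, lags, n_exp, fix_n_molecules) - g) * w

    lag_min, lag_max = float(lags[0]), float(lags[-1])
    # starting values per the default initialization policy
    g0 = g[0] if g[0] > 0 else max(g.max(), 1e-6)
    n_start = 1.0 / g0
    below = np.nonzero(g <= 0.5 * g0)[0]
    tau_d_start = float(lags[below[0]]) if below.size else math.sqrt(lag_min * lag_max)
    tau_d_start = min(max(tau_d_start, lag_min), 100 * lag_max)

    tau_grid = np.geomspace(lag_min, lag_max, 5)
    starts: List[np.ndarray] = []
    if n_exp == 0:
        starts.append(_pack(n_start, tau_d_start, [], [], fix_n_molecules))
    else:
        for combo in itertools.combinations(range(5), n_exp):
            taus = tau_grid[list(combo)][::-1]  # descending
            amps = [0.2] * n_exp
            starts.append(_pack(n_start, tau_d_start, amps, taus, fix_n_molecules))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    lo, hi = [], []
    if fix_n_molecules is None:
        lo.append(1e-12); hi.append(np.inf)
    lo.append(math.log(lag_min)); hi.append(math.log(100 * lag_max))
    for _ in range(n_exp):
        lo += [0.0, math.log(lag_min / 2)]
        hi += [10.0, math.log(lag_max)]
    lo = np.array(lo); hi = np.array(hi)

    best = None
    converged = False
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = optimize.least_squares(
                residual, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000 * len(theta0))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        converged = converged or bool(res.success)
    if best is None:
        raise RuntimeError("all fit starts failed")

    chi2 = float(2.0 * best.cost)
    dof = lags.size - n_par
    # covariance in internal coordinates, scaled by reduced chi2 so that the
    # reported errors are meaningful for relative weights too
    cov_int = None
    try:
        jtj = best.jac.T @ best.jac
        cov_int = np.linalg.inv(jtj) * (chi2 / dof if dof > 0 else np.nan)
    except np.linalg.LinAlgError:
        cov_int = None

    n_mol, tau_d, amps, taus = _unpack(best.x, n_exp, fix_n_molecules)
    # jacobian of external params w.r.t. internal ones (log taus)
    se = [None] * len(best.x)
    cov_ext = None
    if cov_int is not None and np.all(np.isfinite(cov_int)):
        deriv = np.ones(len(best.x))
        idx = 0
        if fix_n_molecules is None:
            idx = 1
        deriv[idx] = tau_d
        for k in range(n_exp):
            deriv[idx + 2 + 2 * k] = taus[k]
        cov_ext = cov_int * np.outer(deriv, deriv)
        diag = np.diag(cov_ext)
        se = [math.sqrt(d) if d >= 0 else None for d in diag]

    i = 0
    if fix_n_molecules is None:
        n_se = se[0]; i = 1
    else:
        n_se = 0.0
    tau_d_se = se[i]
    phases = []
    for k in range(n_exp):
        phases.append(KineticPhase(
            amplitude=float(amps[k]), tau=float(taus[k]),
            amplitude_se=se[i + 1 + 2 * k], tau_se=se[i + 2 + 2 * k]))
    order = np.argsort([-p.tau for p in phases], kind="stable")
    phases = [phases[int(o)] for o in order]

    return ACFModelFit(
        diffusion=DiffusionComponent(float(n_mol), float(tau_d), n_se, tau_d_se),
        phases=phases, n_exp=n_exp, chi2=chi2, dof=dof,
        residuals=best.fun.copy(), covariance=cov_ext, converged=converged,
        seed=seed, lag_min=lag_min, lag_max=lag_max, weighted=weighted)


# ---------------------------------------------------------------------------
# nested model selection


def _sanity_flags(fit: ACFModelFit, min_amplitude: float = 0.01,
                  max_rel_se: float = 1.0, min_tau_ratio: float = 3.0) -> Dict[str, bool]:
    """Physical-plausibility filters on a fitted model (True = pass)."""
    flags = {}
    flags["amplitudes_substantial"] = all(
        p.amplitude >= min_amplitude for p in fit.phases)

    def rel_ok(value, stderr):
        if stderr is None or not np.isfinite(stderr):
            return False
        return stderr < max_rel_se * abs(value)

    ok = rel_ok(fit.diffusion.tau_d, fit.diffusion.tau_d_se)
    if fit.diffusion.n_molecules_se != 0.0:  # se of exactly 0 marks a fixed N
        ok = ok and rel_ok(fit.diffusion.n_molecules, fit.diffusion.n_molecules_se)
    for p in fit.phases:
        ok = ok and rel_ok(p.amplitude, p.amplitude_se) and rel_ok(p.tau, p.tau_se)
    flags["errors_bounded"] = bool(ok)

    taus = [p.tau for p in fit.phases]
    flags["taus_separated"] = all(
        taus[i] / taus[i + 1] >= min_tau_ratio for i in range(len(taus) - 1))
    flags["taus_in_window"] = all(
        fit.lag_min < p.tau < fit.lag_max for p in fit.phases)
    return flags


@dataclass
class SelectionReport:
    """Record of the nested model-selection ladder."""

    per_n: pd.DataFrame
    selected: ACFModelFit
    rationale: Dict[int, str]
    fits: Dict[int, ACFModelFit] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected_n_exp": self.selected.n_exp,
            "selected": self.selected.to_dict(),
            "per_n": self.per_n.to_dict(orient="records"),
            "rationale": {int(k): v for k, v in self.rationale.items()},
        }


def select_model(
    curve: CorrelationCurve,
    n_max: int = 5,
    alpha: float = 0.01,
    seed: int = 0,
    fix_n_molecules: Optional[float] = None,
    criterion: str = "ftest",
) -> SelectionReport:
    """Nested selection of the number of exponential relaxations.

    Fits n = 0..n_max exponentials; n+1 is preferred over n only if the
    nested F-test on the weighted residual sums has p < ``alpha`` (or, with
    ``criterion='aic'``/``'bic'``, the information criterion improves) *and*
    the enlarged fit passes the sanity filters.  The ladder stops at the
    first failure; ties favour fewer exponentials.  Each fit is warm-started
    from the previous one (with a zero-amplitude extra phase), which makes
    the weighted residual sum non-increasing in n.
    """
    if criterion not in ("ftest", "aic", "bic"):
        raise ValueError("criterion must be 'ftest', 'aic' or 'bic'")
    rows = []
    rationale: Dict[int, str] = {}
    fits: Dict[int, ACFModelFit] = {}
    n_pts = len(curve)

    def ic(fit: ACFModelFit, kind: str) -> float:
        k = 2 + 2 * fit.n_exp
        if fit.weighted:
            base = fit.chi2
        else:
            base = n_pts * math.log(max(fit.chi2, 1e-300) / n_pts)
        return base + (2 * k if kind == "aic" else k * math.log(n_pts))

    fit_prev = fit_acf(curve, 0, fix_n_molecules=fix_n_molecules, seed=seed)
    fits[0] = fit_prev
    selected = fit_prev
    rows.append({"n_exp": 0, "chi2": fit_prev.chi2, "p_value": np.nan,
                 "sanity_ok": True, "selected": True})

    for n in range(1, n_max + 1):
        if n_pts - (2 + 2 * n) <= 0:
            rationale[n] = "not enough lags for this many parameters"
            break
        # warm start: previous solution plus a zero-amplitude phase at the
        # geometric mid-lag
        prev_theta = _refit_theta(fit_prev, fix_n_molecules)
        mid = math.sqrt(fit_prev.lag_min * fit_prev.lag_max)
        warm = np.concatenate([prev_theta, [0.0, math.log(mid)]])
        try:
            fit_n = fit_acf(curve, n, fix_n_molecules=fix_n_molecules,
                            seed=seed, extra_starts=[warm])
        except Exception as exc:  # pragma: no cover - defensive
            rationale[n] = f"fit failed: {exc}"
            break
        fits[n] = fit_n

        tiny = n_pts * 1e-22
        if fit_prev.chi2 <= tiny:
            p_val = 1.0
            reason = "smaller model already fits at machine precision"
        elif fit_n.chi2 >= fit_prev.chi2:
            p_val = 1.0
            reason = "no reduction of the residual sum"
        else:
            f_stat = ((fit_prev.chi2 - fit_n.chi2) / 2.0) / (fit_n.chi2 / fit_n.dof)
            p_val = float(stats.f.sf(f_stat, 2, fit_n.dof))
            reason = f"F-test p = {p_val:.3g}"
        flags = _sanity_flags(fit_n)
        sanity_ok = all(flags.values())
        if criterion == "ftest":
            significant = p_val < alpha
        else:
            significant = ic(fit_n, criterion) < ic(fit_prev, criterion)
        accept = significant and sanity_ok
        rows.append({"n_exp": n, "chi2": fit_n.chi2, "p_value": p_val,
                     "sanity_ok": sanity_ok, "selected": accept})
        if not accept:
            failed = [k for k, v in flags.items() if not v]
            if not significant:
                rationale[n] = f"no significant improvement ({reason})"
            else:
                rationale[n] = "over-fitting: failed sanity filters " + ", ".join(failed)
            break
        selected = fit_n
        fit_prev = fit_n

    per_n = pd.DataFrame(rows)
    per_n["selected"] = per_n["n_exp"] == selected.n_exp
    return SelectionReport(per_n=per_n, selected=selected,
                           rationale=rationale, fits=fits)


def _refit_theta(fit: ACFModelFit, fixed_n: Optional[float]) -> np.ndarray:
    head = [] if fixed_n is not None else [fit.diffusion.n_molecules]
    tail = []
    for p in fit.phases:
        tail += [p.amplitude, math.log(p.tau)]
    return np.array(head + [math.log(fit.diffusion.tau_d)] + tail)


# ---------------------------------------------------------------------------
# phase assignment and condition comparison


def assign_phases(fit: ACFModelFit, amplitude_threshold: float = 0.10) -> List[KineticPhase]:
    """Phases with amplitude at or above the assignment threshold.

    Relaxations below ~10% amplitude are considered too small to reliably
    assign a conformational motion; order (decreasing τ) is preserved.
    """
    if not fit.converged:
        raise ValueError("cannot assign phases of a non-converged fit")
    return [p for p in fit.phases if p.amplitude >= amplitude_threshold]


@dataclass
class PhaseComparison:
    """Classification of the assigned phases of condition A against B."""

    condition_a: str
    condition_b: str
    matched: List[Tuple[KineticPhase, KineticPhase]]
    stalled: List[KineticPhase]   # present in A, absent in B
    emergent: List[KineticPhase]  # present in B, absent in A
    amplitude_threshold: float
    match_factor: float

    def to_dict(self) -> dict:
        ph = lambda p: {"amplitude": p.amplitude, "tau": p.tau}
        return {
            "condition_a": self.condition_a, "condition_b": self.condition_b,
            "matched": [[ph(a), ph(b)] for a, b in self.matched],
            "stalled": [ph(p) for p in self.stalled],
            "emergent": [ph(p) for p in self.emergent],
            "amplitude_threshold": self.amplitude_threshold,
            "match_factor": self.match_factor,
        }


def compare_conditions(
    fit_a: ACFModelFit,
    fit_b: ACFModelFit,
    match_factor: float = 3.0,
    amplitude_threshold: float = 0.10,
    condition_a: str = "A",
    condition_b: str = "B",
) -> PhaseComparison:
    """Greedy matching of assigned phases between two conditions.

    Phases are matched by smallest log-τ distance subject to the τ ratio not
    exceeding ``match_factor``.  Unmatched phases of A are reported as
    *stalled* (the motion is lost in B); unmatched phases of B as
    *emergent*.
    """
    pa = assign_phases(fit_a, amplitude_threshold)
    pb = assign_phases(fit_b, amplitude_threshold)
    free_a = list(range(len(pa)))
    free_b = list(range(len(pb)))
    matched: List[Tuple[KineticPhase, KineticPhase]] = []
    log_cut = math.log(match_factor)
    while free_a and free_b:
        pairs = [(abs(math.log(pa[i].tau / pb[j].tau)), i, j)
                 for i in free_a for j in free_b]
        d, i, j = min(pairs)
        if d > log_cut + 1e-12:
            break
        matched.append((pa[i], pb[j]))
        free_a.remove(i)
        free_b.remove(j)
    return PhaseComparison(
        condition_a=condition_a, condition_b=condition_b,
        matched=matched,
        stalled=[pa[i] for i in free_a],
        emergent=[pb[j] for j in free_b],
        amplitude_threshold=amplitude_threshold, match_factor=match_factor)
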