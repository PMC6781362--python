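"""Tumor-immune-pembrolizumab dynamics.

The core of the package is a deliberately skeletal three-compartment ODE
system describing an advanced melanoma lesion burden interacting with the
cellular immune arm under anti-PD-1 therapy:

* ``A_pc`` -- functional antigen-presenting cells (APCs), stimulated by the
  tumor with Michaelis-Menten saturation and dying at a constant rate;
* ``T_il`` -- effector CD8+ tumor-infiltrating lymphocytes, activated by
  APCs and lost to exhaustion;
* ``M_el`` -- melanoma cells, growing exponentially at a net rate
  ``gamma_mel`` and killed by effectors with saturating per-cell efficacy.

Pembrolizumab acts as a step change applied from the treatment start
``t1`` onward: it multiplies the effector activation rate by ``a_pem``
(dimensionless, >= 1 for an active drug) and scales the exhaustion rate by
``b_pem`` (< 1, i.e. reduced exhaustion).  Before ``t1`` the same vector
field with ``a_pem = b_pem = 1`` describes the untreated host.  There is no
pharmacokinetic submodel: drug effect is constant for the whole treated
phase.

Tumor burden is a cell count internally; clinical observations are sums of
target-lesion diameters (SOD, mm).  :class:`CellSodConversion` maps between
the two by spreading the burden over equal spherical lesions of a fixed
effective cell density.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigError, DomainError, IntegrationError

__all__ = [
    "GAMMA_SLOW",
    "GAMMA_FAST",
    "A_PEM_BOUNDS",
    "B_PEM_TREATED",
    "ModelParameters",
    "SystemState",
    "CellSodConversion",
    "SimulationConfig",
    "Trajectory",
    "derivatives",
    "simulate",
    "growth_rate_from_doubling_time",
    "cells_to_sod",
    "sod_to_cells",
    "untreated_equilibrium_immune",
]

#: Dichotomized net tumor growth rates (1/day): the slow value is the lower
#: end of the melanoma doubling-time range, the fast value the one used for
#: aggressive tumors.
GAMMA_SLOW = 0.003269
GAMMA_FAST = 0.005

#: Personalization range for the drug activation-boost factor.
A_PEM_BOUNDS = (10.0, 1.0e4)

#: Exhaustion-reduction factor during treatment (fixed, not personalized).
B_PEM_TREATED = 0.9


@dataclass(frozen=True)
class ModelParameters:
    """The ten constants of the ODE system.

    Fixed (population) parameters default to literature estimates; the
    three that are only known as ranges (``alpha_im``, ``b``, ``g``)
    default to the geometric midpoint of the published range.  The two
    personal parameters are ``a_pem`` and ``gamma_mel``.  Defaults describe
    the *untreated* host (``a_pem = b_pem = 1``); use
    :meth:`personalized` to obtain a treated parameterization.
    """

    alpha_im: float = 1862.0      # APC activation rate, cells/day
    b: float = 7.39e4             # half-saturation burden for APC activation, cells
    mu_apc: float = 0.2310        # APC death rate, 1/day
    a_pem: float = 1.0            # drug activation-boost factor, dimensionless
    alpha_eff: float = 0.8318     # naive CD8+ activation rate, 1/day
    b_pem: float = 1.0            # drug exhaustion-reduction factor, dimensionless
    mu_eff: float = 0.1777        # effector CD8+ exhaustion/death rate, 1/day
    gamma_mel: float = GAMMA_FAST  # net tumor growth rate, 1/day
    nu_mel: float = 0.1245        # maximal per-effector kill rate, 1/day
    g: float = 4.49e7             # half-saturation burden for killing, cells

    def __post_init__(self) -> None:
        for name in ("b", "g", "mu_apc", "mu_eff"):
            if getattr(self, name) <= 0:
                raise DomainError(f"parameter {name!r} must be strictly positive")
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise DomainError(f"parameter {f.name!r} must be nonnegative")

    def personalized(self, a_pem: float, gamma_mel: float,
                     b_pem: float = B_PEM_TREATED) -> "ModelParameters":
        """Treated-phase parameters for one patient."""
        return replace(self, a_pem=float(a_pem), gamma_mel=float(gamma_mel),
                       b_pem=float(b_pem))

    def untreated(self) -> "ModelParameters":
        """Same host with the drug switched off (``a_pem = b_pem = 1``)."""
        return replace(self, a_pem=1.0, b_pem=1.0)


@dataclass(frozen=True)
class SystemState:
    """One point of the state space (all components in cells, >= 0)."""

    a_pc: float
    t_il: float
    m_el: float

    def __post_init__(self) -> None:
        if self.a_pc < 0 or self.t_il < 0 or self.m_el < 0:
            raise DomainError("state components must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.a_pc, self.t_il, self.m_el], dtype=float)


@dataclass(frozen=True)
class CellSodConversion:
    """Conversion between total tumor burden (cells) and SOD (mm).

    The burden is split equally over ``n_lesions`` spheres of effective
    density ``density`` cells per mm^3 of lesion volume; SOD is the sum of
    the sphere diameters.  ``density`` is a scaling constant, not a
    histological cell density: its default places the clinical SOD range
    (5-247 mm) inside the burden window where the immune kill term can
    compete with tumor growth, so that the personal drug effect is
    identifiable from the fits.
    """

    density: float = 15.0
    n_lesions: int = 1

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError("density must be positive")
        if not 1 <= int(self.n_lesions) <= 5:
            raise DomainError("n_lesions must be in [1, 5] (RECIST caps targets at 5)")


def cells_to_sod(m_el: float | np.ndarray,
                 conv: CellSodConversion = CellSodConversion()) -> float | np.ndarray:
    """Sum of diameters (mm) of ``conv.n_lesions`` equal spheres holding ``m_el`` cells."""
    m = np.asarray(m_el, dtype=float)
    if np.any(m < 0):
        raise DomainError("cell burden must be nonnegative")
    volume = (m / conv.n_lesions) / conv.density          # mm^3 per lesion
    diameter = np.cbrt(6.0 * volume / np.pi)
    out = conv.n_lesions * diameter
    return float(out) if np.isscalar(m_el) else out


def sod_to_cells(sod: float | np.ndarray,
                 conv: CellSodConversion = CellSodConversion()) -> float | np.ndarray:
    """Exact inverse of :func:`cells_to_sod`."""
    s = np.asarray(sod, dtype=float)
    if np.any(s < 0):
        raise DomainError("SOD must be nonnegative")
    diameter = s / conv.n_lesions
    volume = np.pi * diameter ** 3 / 6.0
    out = volume * conv.density * conv.n_lesions
    return float(out) if np.isscalar(sod) else out


@dataclass(frozen=True)
class SimulationConfig:
    """Time axis, solver tolerances and unit conversion for one simulation.

    ``t0 <= t1 <= t_end``; the untreated model runs on ``[t0, t1)`` and the
    treated model on ``[t1, t_end]``.  By default both phases collapse to a
    single treated phase starting at day 0.
    """

    t_end: float
    t0: float = 0.0
    t1: float = 0.0
    rtol: float = 1e-6
    atol: float = 1.0       # one cell
    conversion: CellSodConversion = field(default_factory=CellSodConversion)
    grid: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not self.t0 <= self.t1 <= self.t_end:
            raise ConfigError("need t0 <= t1 <= t_end")
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("solver tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped solution of the system on the output grid."""

    t: np.ndarray
    a_pc: np.ndarray
    t_il: np.ndarray
    m_el: np.ndarray

    def sod(self, conv: CellSodConversion = CellSodConversion()) -> np.ndarray:
        return np.asarray(cells_to_sod(self.m_el, conv))


def derivatives(state: SystemState | Sequence[float],
                params: ModelParameters) -> tuple[float, float, float]:
    """Right-hand side of the ODE system at one state.

    Returns ``(dA_pc/dt, dT_il/dt, dM_el/dt)`` in cells/day.
    """
    if isinstance(state, SystemState):
        a, t, m = state.a_pc, state.t_il, state.m_el
    else:
        a, t, m = (float(v) for v in state)
    if a < 0 or t < 0 or m < 0:
        raise DomainError("state components must be nonnegative")
    return _rates(a, t, m, params)


def _rates(a: float, t: float, m: float, p: ModelParameters) -> tuple[float, float, float]:
    sat_apc = m / (m + p.b) if m > 0 else 0.0
    sat_kill = m / (m + p.g) if m > 0 else 0.0
    da = p.alpha_im * sat_apc - p.mu_apc * a
    dt = p.a_pem * p.alpha_eff * a - p.b_pem * p.mu_eff * t
    dm = p.gamma_mel * m - p.nu_mel * t * sat_kill
    return da, dt, dm


def _rhs(p: ModelParameters):
    def f(t: float, y: np.ndarray):
        a, til, m = y
        # solver iterates may undershoot zero by ~atol; evaluate on the
        # clipped state so the saturation terms stay well defined
        a = a if a > 0.0 else 0.0
        til = til if til > 0.0 else 0.0
        m = m if m > 0.0 else 0.0
        return _rates(a, til, m, p)
    return f


def simulate(params: ModelParameters,
             init: SystemState | Sequence[float],
             config: SimulationConfig) -> Trajectory:
    """Integrate the two-phase system and sample it on the output grid.

    For ``t in [t0, t1)`` the untreated parameterization
    (``a_pem = b_pem = 1``) is integrated; from ``t1`` the supplied
    (typically personalized) parameters take over, continuously from the
    state reached at ``t1``.  The returned trajectory contains the output
    grid plus both phase endpoints.
    """
    y0 = init.as_array() if isinstance(init, SystemState) else np.asarray(init, float)
    if y0.shape != (3,) or np.any(y0 < 0):
        raise DomainError("initial state must be three nonnegative components")

    if config.grid is None:
        grid = np.linspace(config.t0, config.t_end, 201)
    else:
        grid = np.asarray(config.grid, dtype=float)
    pts = np.union1d(grid, [config.t0, config.t1, config.t_end])
    pts = pts[(pts >= config.t0) & (pts <= config.t_end)]

    phases: list[tuple[float, float, ModelParameters]] = []
    if config.t1 > config.t0:
        phases.append((config.t0, config.t1, params.untreated()))
    if config.t_end > config.t1:
        phases.append((config.t1, config.t_end, params))

    if not phases:  # degenerate zero-length horizon
        return Trajectory(t=np.array([config.t0]), a_pc=np.array([y0[0]]),
                          t_il=np.array([y0[1]]), m_el=np.array([y0[2]]))

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    state = y0
    for ta, tb, p in phases:
        t_eval = pts[(pts >= ta) & (pts <= tb)]
        sol = solve_ivp(_rhs(p), (ta, tb), state, method="LSODA",
                        rtol=config.rtol, atol=config.atol, t_eval=t_eval)
        if not sol.success:
            t_fail = sol.t[-1] if sol.t.size else ta
            raise IntegrationError(
                f"ODE integration failed near t = {t_fail:.3f} d: {sol.message}")
        # re-integrate endpoint state exactly even if t_eval skipped it
        end_state = sol.y[:, -1] if sol.t.size and sol.t[-1] == tb else None
        if end_state is None:
            sol_end = solve_ivp(_rhs(p), (ta, tb), state, method="LSODA",
                                rtol=config.rtol, atol=config.atol,
                                t_eval=[tb])
            end_state = sol_end.y[:, -1]
        if ts and sol.t.size and sol.t[0] == ts[-1][-1]:
            ts.append(sol.t[1:])
            ys.append(sol.y[:, 1:])
        else:
            ts.append(sol.t)
            ys.append(sol.y)
        state = end_state

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # negative undershoots within solver tolerance are clipped on output
    y_all = np.clip(y_all, 0.0, None)
    return Trajectory(t=t_all, a_pc=y_all[0], t_il=y_all[1], m_el=y_all[2])


def growth_rate_from_doubling_time(delta_t: float) -> float:
    """Net growth rate (1/day) from a tumor doubling time (days): ln(2)/dt."""
    if delta_t <= 0:
        raise DomainError("doubling time must be positive")
    return math.log(2.0) / delta_t


def untreated_equilibrium_immune(m_el: float,
                                 params: ModelParameters) -> tuple[float, float]:
    """Quasi-steady immune state of the untreated host at fixed tumor burden.

    Solves ``dA_pc/dt = dT_il/dt = 0`` of the untreated system
    (``a_pem = b_pem = 1``) conditional on ``M_el = m_el``::

        A* = (alpha_im / mu_apc) * M / (M + b)
        T* = (alpha_eff / mu_eff) * A*

    Used to initialize the immune compartments at treatment start when no
    pre-treatment burn-in is simulated.
    """
    if m_el < 0:
        raise DomainError("cell burden must be nonnegative")
    sat = m_el / (m_el + params.b) if m_el > 0 else 0.0
    a_star = params.alpha_im / params.mu_apc * sat
    t_star = params.alpha_eff / params.mu_eff * a_star
    return a_star, t_star


def burn_in_inoculum(baseline_cells: float, params: ModelParameters,
                     t0: float, t1: float, config: SimulationConfig | None = None,
                     rel_tol: float = 1e-6, max_iter: int = 80) -> float:
    """Inoculum at ``t0`` whose untreated trajectory reaches ``baseline_cells`` at ``t1``.

    Optional helper for the pre-treatment burn-in mode (off by default in
    the fitting pipeline): bisects on the initial burden of an untreated
    simulation started from the conditional immune equilibrium.
    """
    if t1 <= t0:
        raise ConfigError("burn-in requires t0 < t1")
    cfg = config or SimulationConfig(t_end=t1, t0=t0, t1=t1)

    def m_at_t1(m0: float) -> float:
        a0, t0_imm = untreated_equilibrium_immune(m0, params)
        traj = simulate(params.untreated(), (a0, t0_imm, m0),
                        replace(cfg, t0=t0, t1=t1, t_end=t1, grid=[t0, t1]))
        return float(traj.m_el[-1])

    lo, hi = baseline_cells * 1e-6, baseline_cells
    if m_at_t1(hi) < baseline_cells:  # net shrinkage untreated: no solution below target
        raise DomainError("untreated burden shrinks; burn-in inoculum not bracketed")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        if m_at_t1(mid) < baseline_cells:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1.0 < rel_tol:
            break
    return math.sqrt(lo * hi)
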