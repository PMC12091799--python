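"""Tumour-normal cell competition under continuous radiotherapy.

Two logistic populations compete Lotka-Volterra style while a constant
radiation dose rate ``gamma`` (Gray/hour) removes malignant cells and, through
the collateral fraction ``epsilon``, a proportion ``epsilon*gamma`` of healthy
cells:

    dx1/dt = alpha1*x1*(1 - x1/K1) - beta1*x1*x2 - epsilon*gamma*x1  = F1
    dx2/dt = alpha2*x2*(1 - x2/K2) - beta2*x1*x2 - gamma*x2          = F2

``x1`` is the healthy-cell proportion, ``x2`` the malignant-cell proportion.
``gamma = 0`` encodes the untreated system.  The module provides the vector
field, its analytic Jacobian, the boundary equilibria (cancer-free E0 and
healthy-free E*), the treatment thresholds R0 and Rh, the Matignon
local-stability test for fractional order ``mu``, and a check that computed
trajectories stay in the invariant box 0 <= x_i <= K_i.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParameters",
    "State",
    "EquilibriumReport",
    "StabilityVerdict",
    "InvariantRegionReport",
    "rhs",
    "jacobian",
    "equilibria",
    "thresholds",
    "local_stability",
    "eigenvalues_at_E0_as_printed",
    "check_invariant_region",
]


@dataclass(frozen=True)
class ModelParameters:
    """The eight biological constants of the competition/radiation system.

    alpha1, alpha2 : intrinsic growth rates of healthy / malignant cells (1/h)
    K1, K2         : carrying capacities (proportion scale)
    beta1          : competition of malignant on healthy cells (1/h)
    beta2          : competition of healthy on malignant cells (1/h)
    epsilon        : collateral-radiation fraction (dimensionless)
    gamma          : radiation dose rate (Gray/h); 0 = untreated
    """

    alpha1: float
    alpha2: float
    K1: float
    K2: float
    beta1: float
    beta2: float
    epsilon: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "K1", "K2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("beta1", "beta2", "epsilon", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def treated(self) -> bool:
        return self.gamma > 0

    def without_treatment(self) -> "ModelParameters":
        """The same biology with the radiation switched off (gamma = 0)."""
        return replace(self, gamma=0.0)


@dataclass(frozen=True)
class State:
    """Healthy-cell and malignant-cell proportions."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x1) and math.isfinite(self.x2)):
            raise ValueError("state components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2], dtype=float)


@dataclass(frozen=True)
class StabilityVerdict:
    """Matignon verdict for one equilibrium at fractional order mu."""

    equilibrium: State
    feasible: bool
    eigenvalues: tuple[complex, complex]
    matignon_stable: bool


@dataclass(frozen=True)
class EquilibriumReport:
    """Boundary equilibria, feasibility, E0 spectrum and treatment thresholds."""

    E0: State
    E_star: State
    E0_feasible: bool
    E_star_feasible: bool
    eigenvalues_at_E0: tuple[complex, complex]
    R0: float
    Rh: float


def rhs(state: State | Sequence[float], params: ModelParameters) -> tuple[float, float]:
    """Vector field (F1, F2) of the competition/radiation system."""
    x1, x2 = (state.x1, state.x2) if isinstance(state, State) else (state[0], state[1])
    p = params
    F1 = p.alpha1 * x1 * (1.0 - x1 / p.K1) - p.beta1 * x1 * x2 - p.epsilon * p.gamma * x1
    F2 = p.alpha2 * x2 * (1.0 - x2 / p.K2) - p.beta2 * x1 * x2 - p.gamma * x2
    return F1, F2


def jacobian(state: State | Sequence[float], params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``state``."""
    x1, x2 = (state.x1, state.x2) if isinstance(state, State) else (state[0], state[1])
    p = params
    return np.array(
        [
            [p.alpha1 * (1.0 - 2.0 * x1 / p.K1) - p.beta1 * x2 - p.epsilon * p.gamma,
             -p.beta1 * x1],
            [-p.beta2 * x2,
             p.alpha2 * (1.0 - 2.0 * x2 / p.K2) - p.beta2 * x1 - p.gamma],
        ]
    )


def thresholds(params: ModelParameters) -> tuple[float, float]:
    """Treatment thresholds (R0, Rh).

    R0 = alpha2 / (gamma + beta2*K1) is the basic reproduction ratio of
    malignant cells: R0 < 1 predicts eradication under sustained treatment.
    Rh = (alpha1 - epsilon*gamma) / (beta1*K2) measures the net growth of
    healthy cells against competition pressure.
    """
    p = params
    den0 = p.gamma + p.beta2 * p.K1
    denh = p.beta1 * p.K2
    if den0 <= 0 or denh <= 0:
        raise ValueError("degenerate parameters: zero threshold denominator")
    return p.alpha2 / den0, (p.alpha1 - p.epsilon * p.gamma) / denh


def equilibria(params: ModelParameters) -> EquilibriumReport:
    """Boundary equilibria of the system with feasibility flags.

    E0 (cancer-free) = (K1*(alpha1 - gamma*epsilon)/alpha1, 0);
    E* (healthy-free) = (0, K2*(alpha2 - gamma)/alpha2).
    A negative coordinate marks the equilibrium as biologically infeasible
    (it is still reported).
    """
    p = params
    E0 = State(p.K1 * (p.alpha1 - p.gamma * p.epsilon) / p.alpha1, 0.0)
    E_star = State(0.0, p.K2 * (p.alpha2 - p.gamma) / p.alpha2)
    eig = np.linalg.eigvals(jacobian(E0, p))
    R0, Rh = thresholds(p)
    return EquilibriumReport(
        E0=E0,
        E_star=E_star,
        E0_feasible=E0.x1 >= 0.0,
        E_star_feasible=E_star.x2 >= 0.0,
        eigenvalues_at_E0=(complex(eig[0]), complex(eig[1])),
        R0=R0,
        Rh=Rh,
    )


def eigenvalues_at_E0_as_printed(params: ModelParameters) -> tuple[float, float]:
    """E0 eigenvalues in the reduced closed form some references print.

    Returns (gamma*epsilon - alpha1, -gamma - beta1*K1*(alpha1 - gamma*epsilon)/alpha1).
    The second entry differs from the analytic Jacobian's
    ``alpha2 - gamma - beta2*x1(E0)``; the analytic form is authoritative for
    every verdict in this package, this accessor exists only for comparison.
    """
    p = params
    lam1 = p.gamma * p.epsilon - p.alpha1
    lam2 = -p.gamma - p.beta1 * p.K1 * (p.alpha1 - p.gamma * p.epsilon) / p.alpha1
    return lam1, lam2


def _matignon(eig: np.ndarray, mu: float) -> bool:
    """Matignon condition: every eigenvalue satisfies |arg(lambda)| > mu*pi/2."""
    return bool(all(abs(cmath.phase(complex(lam))) > mu * math.pi / 2.0 for lam in eig))


def local_stability(params: ModelParameters, mu: float) -> dict:
    """Local stability report at fractional order ``mu``.

    For each boundary equilibrium, computes the eigenvalues of the analytic
    Jacobian and applies the Matignon condition |arg(lambda)| > mu*pi/2.
    The simple treated-case criterion gamma*epsilon < alpha1 (equivalent to
    E0 feasibility with a stable healthy direction) is reported separately.
    """
    if not (0.0 < mu <= 1.0):
        raise ValueError(f"mu must be in (0, 1], got {mu}")
    rep = equilibria(params)
    verdicts = {}
    for name, eq, feas in (
        ("E0", rep.E0, rep.E0_feasible),
        ("E_star", rep.E_star, rep.E_star_feasible),
    ):
        eig = np.linalg.eigvals(jacobian(eq, params))
        verdicts[name] = StabilityVerdict(
            equilibrium=eq,
            feasible=feas,
            eigenvalues=(complex(eig[0]), complex(eig[1])),
            matignon_stable=_matignon(eig, mu),
        )
    p = params
    return {
        "mu": mu,
        "verdicts": verdicts,
        "treated_criterion": p.gamma * p.epsilon < p.alpha1,
        "R0": rep.R0,
        "Rh": rep.Rh,
    }


@dataclass(frozen=True)
class InvariantRegionReport:
    """Summary of a trajectory against the box 0 <= x1 <= K1, 0 <= x2 <= K2."""

    x1_min: float
    x1_max: float
    x2_min: float
    x2_max: float
    fraction_inside: float
    limsup_ok: bool
    all_inside: bool
    tolerance: float


def check_invariant_region(traj, params: ModelParameters, *, tol: float = 1e-6) -> InvariantRegionReport:
    """Check a trajectory against the invariant region.

    ``traj`` is any object with ``x1`` and ``x2`` array attributes.  Reports
    component ranges, the fraction of points inside the box (within ``tol``),
    and whether the final quartile respects the lim-sup bounds x1 <= K1,
    x2 <= K2.
    """
    x1 = np.asarray(traj.x1, dtype=float)
    x2 = np.asarray(traj.x2, dtype=float)
    if x1.size == 0:
        raise ValueError("empty trajectory")
    inside = (
        (x1 >= -tol) & (x1 <= params.K1 + tol) & (x2 >= -tol) & (x2 <= params.K2 + tol)
    )
    q = max(1, x1.size // 4)
    limsup_ok = bool(
        np.max(x1[-q:]) <= params.K1 + tol and np.max(x2[-q:]) <= params.K2 + tol
    )
    return InvariantRegionReport(
        x1_min=float(x1.min()),
        x1_max=float(x1.max()),
        x2_min=float(x2.min()),
        x2_max=float(x2.max()),
        fraction_inside=float(inside.mean()),
        limsup_ok=limsup_ok,
        all_inside=bool(inside.all()),
        tolerance=tol,
    )
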