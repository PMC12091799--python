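"""Linear-growth and Lipschitz constants for existence and uniqueness.

On a bounded horizon the squared state components are bounded, and the
quadratic right-hand sides F1, F2 of the competition/radiation system then
satisfy a linear-growth condition |F_i|^2 <= k_i (1 + |x_i|^2) and a
one-variable Lipschitz condition |F_i(a) - F_i(b)|^2 <= kbar_i |a_i - b_i|^2,
with the non-varied component frozen at its sup.  Together these guarantee a
unique solution.  This module computes the four constants from the closed
forms (Cauchy-Schwarz with four terms, hence the leading factor 4) and
verifies both inequalities by brute-force sampling.

The sup bounds enter the derivation as ten slots M1..M10, but every slot is
the sup of |x1|^2 or of |x2|^2; callers supply just those two numbers
(defaults: the invariant-region bounds K1^2, K2^2) and the report expands them
back to the ten slots for traceability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelParameters, rhs

__all__ = [
    "SupBounds",
    "GrowthLipschitzReport",
    "growth_constants",
    "lipschitz_constants",
    "verify_conditions",
]


@dataclass(frozen=True)
class SupBounds:
    """Sup bounds on the *squared* state components over the horizon."""

    m1_sq: float  # sup |x1|^2
    m2_sq: float  # sup |x2|^2

    def __post_init__(self) -> None:
        if self.m1_sq < 0 or self.m2_sq < 0:
            raise ValueError("sup bounds must be non-negative")

    @classmethod
    def from_invariant_region(cls, params: ModelParameters) -> "SupBounds":
        return cls(params.K1**2, params.K2**2)

    def ten_slots(self) -> dict[str, float]:
        """The ten sup slots of the derivation, expanded for traceability."""
        a, b = self.m1_sq, self.m2_sq
        return {
            "M1": a, "M2": b,          # growth, F1
            "M3": b, "M4": a,          # growth, F2
            "M5": a, "M6": a, "M7": b,  # Lipschitz, F1
            "M8": b, "M9": b, "M10": a,  # Lipschitz, F2
        }


def growth_constants(params: ModelParameters, M: SupBounds) -> tuple[float, float]:
    """Linear-growth constants (k1, k2).

    k1 = 4*(alpha1^2 + alpha1^2/K1^2 * M1 + beta1^2 * M2 + epsilon^2*gamma^2),
    k2 = 4*(alpha2^2 + alpha2^2/K2^2 * M3 + beta2^2 * M4 + gamma^2),
    with M1 = M4 = sup|x1|^2 and M2 = M3 = sup|x2|^2.
    """
    p = params
    s = M.ten_slots()
    k1 = 4.0 * (
        p.alpha1**2
        + p.alpha1**2 / p.K1**2 * s["M1"]
        + p.beta1**2 * s["M2"]
        + p.epsilon**2 * p.gamma**2
    )
    k2 = 4.0 * (
        p.alpha2**2
        + p.alpha2**2 / p.K2**2 * s["M3"]
        + p.beta2**2 * s["M4"]
        + p.gamma**2
    )
    return k1, k2


def lipschitz_constants(params: ModelParameters, M: SupBounds) -> tuple[float, float]:
    """Lipschitz constants (kbar1, kbar2).

    kbar1 = 4*alpha1^2 + 4*alpha1^2/K1^2*(2*M5 + 2*M6) + 4*beta1^2*M7
            + 4*epsilon^2*gamma^2, and analogously for kbar2.
    """
    p = params
    s = M.ten_slots()
    kbar1 = (
        4.0 * p.alpha1**2
        + 4.0 * p.alpha1**2 / p.K1**2 * (2.0 * s["M5"] + 2.0 * s["M6"])
        + 4.0 * p.beta1**2 * s["M7"]
        + 4.0 * p.epsilon**2 * p.gamma**2
    )
    kbar2 = (
        4.0 * p.alpha2**2
        + 4.0 * p.alpha2**2 / p.K2**2 * (2.0 * s["M8"] + 2.0 * s["M9"])
        + 4.0 * p.beta2**2 * s["M10"]
        + 4.0 * p.gamma**2
    )
    return kbar1, kbar2


@dataclass(frozen=True)
class GrowthLipschitzReport:
    """Constants plus the outcome of the brute-force verification."""

    M_slots: dict[str, float]
    k1: float
    k2: float
    kbar1: float
    kbar2: float
    growth_verified: bool
    lipschitz_verified: bool
    worst_growth_ratio: float
    worst_lipschitz_ratio: float
    n_samples: int
    seed: int
    violating_pair: tuple | None = field(default=None)


def verify_conditions(
    params: ModelParameters,
    M: SupBounds | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    *,
    growth_override: tuple[float, float] | None = None,
    lipschitz_override: tuple[float, float] | None = None,
) -> GrowthLipschitzReport:
    """Brute-force check of the growth and Lipschitz inequalities.

    Samples states uniformly in the box implied by ``M`` and reports the worst
    observed ratio of each inequality's left to right side.  The Lipschitz
    check varies one component at a time with the other frozen at its sup,
    matching the derivation of the constants.  The ``*_override`` arguments
    substitute foreign constants (e.g. deliberately halved ones) to exercise
    failure reporting.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    if M is None:
        M = SupBounds.from_invariant_region(params)
    k1, k2 = growth_override or growth_constants(params, M)
    kbar1, kbar2 = lipschitz_override or lipschitz_constants(params, M)
    s1, s2 = np.sqrt(M.m1_sq), np.sqrt(M.m2_sq)

    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0.0, s1, n_samples)
    x2 = rng.uniform(0.0, s2, n_samples)
    F1 = np.empty(n_samples)
    F2 = np.empty(n_samples)
    for i in range(n_samples):
        F1[i], F2[i] = rhs((x1[i], x2[i]), params)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1 = F1**2 / (k1 * (1.0 + x1**2))
        g2 = F2**2 / (k2 * (1.0 + x2**2))
    worst_growth = float(max(np.nanmax(g1), np.nanmax(g2)))

    # Lipschitz in x1 with x2 frozen at sup, and vice versa.
    a1 = rng.uniform(0.0, s1, n_samples)
    b1 = rng.uniform(0.0, s1, n_samples)
    a2 = rng.uniform(0.0, s2, n_samples)
    b2 = rng.uniform(0.0, s2, n_samples)
    worst_lip = 0.0
    violating_pair = None
    for i in range(n_samples):
        da = a1[i] - b1[i]
        if da != 0.0:
            fa, _ = rhs((a1[i], s2), params)
            fb, _ = rhs((b1[i], s2), params)
            r = (fa - fb) ** 2 / (kbar1 * da * da)
            if r > worst_lip:
                worst_lip = r
                if r > 1.0:
                    violating_pair = ("F1", a1[i], b1[i], s2)
        db = a2[i] - b2[i]
        if db != 0.0:
            _, fa = rhs((s1, a2[i]), params)
            _, fb = rhs((s1, b2[i]), params)
            r = (fa - fb) ** 2 / (kbar2 * db * db)
            if r > worst_lip:
                worst_lip = r
                if r > 1.0:
                    violating_pair = ("F2", a2[i], b2[i], s1)

    return GrowthLipschitzReport(
        M_slots=M.ten_slots(),
        k1=k1,
        k2=k2,
        kbar1=kbar1,
        kbar2=kbar2,
        growth_verified=worst_growth <= 1.0,
        lipschitz_verified=worst_lip <= 1.0,
        worst_growth_ratio=worst_growth,
        worst_lipschitz_ratio=float(worst_lip),
        n_samples=n_samples,
        seed=seed,
        violating_pair=violating_pair,
    )
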