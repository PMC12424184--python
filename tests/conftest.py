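"""Shared fixtures and independent oracles.

The equilibrium oracle solves the full six-species mass-action network
(three conservation laws, three equilibrium relations) as a simultaneous
root-finding problem in log-monomer space, independently of the closed-form
route used by the package.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import root

from ternacoop import TernarySystem


def mass_action_oracle(s: TernarySystem) -> dict[str, float]:
    """Brute-force simultaneous solve of the ternary network.

    Unknowns are the log free-monomer concentrations; complexes follow from
    the equilibrium relations, and the residuals are the three conservation
    laws scaled by their totals.  A damped fixed-point sweep provides the
    starting guess.
    """

    def implied(A: float, B: float, L: float):
        AL = A * L / s.K_AL
        BL = B * L / s.K_BL
        ALB = s.alpha * A * B * L / (s.K_AL * s.K_BL)
        return AL, BL, ALB

    def residuals(u):
        A, B, L = np.exp(u)
        AL, BL, ALB = implied(A, B, L)
        return [
            (A + AL + ALB) / s.A_tot - 1.0,
            (B + BL + ALB) / s.B_tot - 1.0,
            (L + AL + BL + ALB) / s.L_tot - 1.0,
        ]

    A, B, L = s.A_tot, s.B_tot, s.L_tot
    for _ in range(500):
        AL, BL, ALB = implied(A, B, L)
        A *= np.sqrt(s.A_tot / (A + AL + ALB))
        B *= np.sqrt(s.B_tot / (B + BL + ALB))
        L *= np.sqrt(s.L_tot / (L + AL + BL + ALB))
    sol = root(residuals, np.log([A, B, L]), method="hybr", tol=1e-13)
    # hybr can stall when the warm start is already converged; judge by residual
    assert np.max(np.abs(residuals(sol.x))) <= 1e-9, f"oracle failed on {s}: {sol.message}"
    A, B, L = np.exp(sol.x)
    AL, BL, ALB = implied(A, B, L)
    return {"A": A, "B": B, "L": L, "AL": AL, "BL": BL, "ALB": ALB}


def draw_random_system(rng: np.random.Generator) -> TernarySystem:
    """Log-uniform draw: K in [1 nM, 1 mM], alpha in [0.01, 1000], totals in [10 nM, 100 uM]."""
    return TernarySystem(
        A_tot=10 ** rng.uniform(-8, -4),
        B_tot=10 ** rng.uniform(-8, -4),
        L_tot=10 ** rng.uniform(-8, -4),
        K_AL=10 ** rng.uniform(-9, -3),
        K_BL=10 ** rng.uniform(-9, -3),
        alpha=10 ** rng.uniform(-2, 3),
    )


def rel_err(x: float, y: float) -> float:
    return abs(x - y) / max(abs(x), abs(y), 1e-300)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def symmetric_micromolar() -> TernarySystem:
    """The symmetric 1 uM reference system: totals 1 uM, K's 1 uM."""
    return TernarySystem(A_tot=1e-6, B_tot=1e-6, L_tot=2e-6,
                         K_AL=1e-6, K_BL=1e-6, alpha=10.0)
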