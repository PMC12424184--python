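"""Ternary-complex mass-action equilibrium.

Two proteins ``A`` and ``B`` bind a shared ligand ``L`` to form binary
complexes ``AL``/``BL`` and a ternary complex ``ALB``.  The network is fully
determined by the two binary dissociation constants ``K_AL`` and ``K_BL`` and
the (asymmetric, "of the ligand") cooperativity

    alpha = K_AL / K_A-BL = [ALB]*[L] / ([AL]*[BL])

so that the effective ternary dissociation constant is
``K3 = K_AL*K_BL/alpha`` (units M^2).  Proteins are assumed noninteracting in
the absence of ligand (no free ``AB`` species), following the Yang-Hlavacek
ternary equilibrium model.

Given the free-ligand concentration ``[L]`` the ternary concentration has the
closed form

    [ALB] = (C - sqrt(C^2 - 4*A_tot*B_tot)) / 2,
    C     = A_tot + B_tot + ([L]+K_AL)*([L]+K_BL) / (alpha*[L])

and ``[L]`` itself is fixed by ligand conservation, a monotone scalar
equation solved here by bracketed root finding in log-concentration space.

All concentrations are molar throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    InsufficientRangeError,
    InternalConsistencyError,
    InvalidParameterError,
    SolverFailureError,
    UndefinedFractionError,
)

__all__ = [
    "TernarySystem",
    "EquilibriumState",
    "TitrationCurve",
    "solve_free_ligand",
    "solve_equilibrium",
    "ternary_fraction",
    "titration",
    "optimal_free_ligand",
    "optimal_total_ligand",
    "optimal_fraction",
    "hook_severity",
    "response_surface",
]

#: concentrations below this are treated as exactly zero in relative residuals
_TINY = 1e-300


@dataclass(frozen=True)
class TernarySystem:
    """Total concentrations and binding parameters of an A + L + B system.

    Parameters
    ----------
    A_tot, B_tot, L_tot
        Total (bound + free) concentrations in molar, each >= 0.
    K_AL, K_BL
        Binary dissociation constants of the A-L and B-L complexes (molar, > 0).
    alpha
        Dimensionless cooperativity (> 0).  ``alpha > 1`` means the second
        protein facilitates ligand binding, ``alpha < 1`` that it impedes it.
    """

    A_tot: float
    B_tot: float
    L_tot: float
    K_AL: float
    K_BL: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("A_tot", "B_tot", "L_tot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("K_AL", "K_BL", "alpha"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")

    def with_L_tot(self, L_tot: float) -> "TernarySystem":
        return replace(self, L_tot=L_tot)

    def swapped(self) -> "TernarySystem":
        """Exchange the roles of A and B (totals together with their Kd's)."""
        return TernarySystem(
            A_tot=self.B_tot, B_tot=self.A_tot, L_tot=self.L_tot,
            K_AL=self.K_BL, K_BL=self.K_AL, alpha=self.alpha,
        )


@dataclass(frozen=True)
class EquilibriumState:
    """All six species concentrations (molar) with convergence diagnostics."""

    A: float
    B: float
    L: float
    AL: float
    BL: float
    ALB: float
    residual_mass: float
    residual_K: float

    def species(self) -> dict[str, float]:
        return {"A": self.A, "B": self.B, "L": self.L,
                "AL": self.AL, "BL": self.BL, "ALB": self.ALB}


def _alb_given_free_ligand(system: TernarySystem, L: float) -> float:
    """Closed-form [ALB] at a given free-ligand concentration.

    Uses the product form ``2*A_tot*B_tot / (C + sqrt(C^2 - 4*A_tot*B_tot))``
    of the quadratic root, which avoids catastrophic cancellation when C is
    large (weak effective binding).
    """
    if L <= 0 or system.A_tot == 0 or system.B_tot == 0:
        return 0.0
    C = system.A_tot + system.B_tot + (L + system.K_AL) * (L + system.K_BL) / (system.alpha * L)
    disc = C * C - 4.0 * system.A_tot * system.B_tot
    if disc < 0:
        if disc > -1e-12 * C * C:
            disc = 0.0
        else:
            raise InternalConsistencyError(
                f"negative discriminant {disc:g} for C={C:g}, "
                f"A_tot={system.A_tot:g}, B_tot={system.B_tot:g}"
            )
    return 2.0 * system.A_tot * system.B_tot / (C + math.sqrt(disc))


def _ltot_given_free_ligand(system: TernarySystem, L: float) -> float:
    """Total ligand implied by a free-ligand concentration (ligand conservation)."""
    if L <= 0:
        return 0.0
    alb = _alb_given_free_ligand(system, L)
    fA = L / (L + system.K_AL)
    fB = L / (L + system.K_BL)
    return L + fA * system.A_tot + fB * system.B_tot + (1.0 - fA - fB) * alb


def _binary_free_ligand(P_tot: float, K: float, L_tot: float) -> float:
    """Free ligand of an isolated P + L <-> PL isotherm (stable quadratic root)."""
    b = K + P_tot - L_tot
    # L^2 + b L - K L_tot = 0; positive root written without cancellation
    return 2.0 * K * L_tot / (b + math.sqrt(b * b + 4.0 * K * L_tot))


def solve_free_ligand(system: TernarySystem, rel_tol: float = 1e-10) -> float:
    """Solve ligand conservation for the free-monomer concentration [L].

    The implied-total function is monotone increasing in [L], so the root is
    bracketed on ``(0, L_tot]`` and located by Brent's method on ``ln [L]``,
    which keeps the bracket robust over nM-mM dynamic ranges.

    Parameters
    ----------
    system
        Validated ternary system.
    rel_tol
        Relative tolerance on the reproduced total ligand, in ``(0, 1e-3]``.
    """
    if not (0 < rel_tol <= 1e-3):
        raise InvalidParameterError(f"rel_tol must be in (0, 1e-3], got {rel_tol!r}")
    L_tot = system.L_tot
    if L_tot == 0.0:
        return 0.0
    if system.A_tot == 0.0 and system.B_tot == 0.0:
        return L_tot
    # one protein absent: exact binary isotherm, no ternary coupling
    if system.A_tot == 0.0:
        return _binary_free_ligand(system.B_tot, system.K_BL, L_tot)
    if system.B_tot == 0.0:
        return _binary_free_ligand(system.A_tot, system.K_AL, L_tot)

    def g(u: float) -> float:
        return _ltot_given_free_ligand(system, math.exp(u)) - L_tot

    hi = math.log(L_tot)
    if g(hi) < 0:  # cannot happen analytically; guards rounding
        raise SolverFailureError(
            f"upper bracket failed: implied L_tot({L_tot:g}) < target {L_tot:g}"
        )
    lo = hi - 60.0  # ~1e-26 relative; expanded below if still too high
    while g(lo) > 0:
        lo -= 120.0
        if lo < math.log(_TINY) + 10:
            raise SolverFailureError(
                f"could not bracket free ligand below {math.exp(lo):g} M "
                f"(L_tot={L_tot:g}, K_AL={system.K_AL:g}, K_BL={system.K_BL:g})"
            )
    u = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    L = math.exp(u)
    achieved = _ltot_given_free_ligand(system, L)
    if abs(achieved - L_tot) > rel_tol * max(L_tot, _TINY):
        raise SolverFailureError(
            f"free-ligand solve converged to {L:g} M but reproduces "
            f"L_tot={achieved:g} (target {L_tot:g}, rel_tol={rel_tol:g})"
        )
    return min(L, L_tot)


def _state_from_free_ligand(system: TernarySystem, L: float) -> EquilibriumState:
    alb = _alb_given_free_ligand(system, L)
    if L > 0:
        A = (system.A_tot - alb) / (1.0 + L / system.K_AL)
        B = (system.B_tot - alb) / (1.0 + L / system.K_BL)
    else:
        A, B = system.A_tot, system.B_tot
    A, B, alb = max(A, 0.0), max(B, 0.0), max(alb, 0.0)
    AL = A * L / system.K_AL
    BL = B * L / system.K_BL

    def rel(err: float, scale: float) -> float:
        return abs(err) / max(scale, _TINY)

    residual_mass = max(
        rel(A + AL + alb - system.A_tot, system.A_tot),
        rel(B + BL + alb - system.B_tot, system.B_tot),
        rel(L + AL + BL + alb - system.L_tot, system.L_tot),
    )
    residual_K = max(
        rel(AL * system.K_AL - A * L, A * L),
        rel(BL * system.K_BL - B * L, B * L),
        rel(alb * system.K_AL * system.K_BL - system.alpha * A * B * L,
            system.alpha * A * B * L),
    )
    return EquilibriumState(A=A, B=B, L=L, AL=AL, BL=BL, ALB=alb,
                            residual_mass=residual_mass, residual_K=residual_K)


def solve_equilibrium(system: TernarySystem, rel_tol: float = 1e-10) -> EquilibriumState:
    """Equilibrium concentrations of all six species.

    Solves for the free ligand, evaluates the closed-form ternary
    concentration, and back-substitutes the remaining species from the
    conservation laws.  Mass-balance and equilibrium-relation residuals are
    reported on the returned state (both <= 1e-8 for converged solves).
    """
    L = solve_free_ligand(system, rel_tol=rel_tol)
    return _state_from_free_ligand(system, L)


def ternary_fraction(state: EquilibriumState, system: TernarySystem) -> float:
    """Fraction of the limiting species sequestered in the ternary complex.

    ``f3 = [ALB] / min(A_tot, B_tot, L_tot)`` — the maximum possible ternary
    concentration is set by the scarcest component.
    """
    limiting = min(system.A_tot, system.B_tot, system.L_tot)
    if limiting <= 0:
        raise UndefinedFractionError("ternary fraction undefined when a total is zero")
    return min(state.ALB / limiting, 1.0)


@dataclass(frozen=True)
class TitrationCurve:
    """Equilibrium states along a total-ligand dose grid."""

    L_tot_grid: np.ndarray
    states: tuple[EquilibriumState, ...]
    f3: np.ndarray
    system_base: TernarySystem = field(repr=False)

    def __len__(self) -> int:
        return len(self.L_tot_grid)

    def __iter__(self) -> Iterator[tuple[float, EquilibriumState, float]]:
        return iter(zip(self.L_tot_grid, self.states, self.f3))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"L_tot": lt, **s.species(), "f3": f}
            for lt, s, f in zip(self.L_tot_grid, self.states, self.f3)
        ]
        return pd.DataFrame(rows, columns=["L_tot", "L", "A", "B", "AL", "BL", "ALB", "f3"])


def titration(system_base: TernarySystem, L_tot_grid: Sequence[float]) -> TitrationCurve:
    """Titrate total ligand over a strictly increasing positive grid."""
    grid = np.asarray(L_tot_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise InvalidParameterError("L_tot_grid must be a non-empty 1-D sequence")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("L_tot_grid must be strictly increasing and positive")
    states = []
    f3 = np.empty(len(grid))
    for i, lt in enumerate(grid):
        sys_i = system_base.with_L_tot(float(lt))
        try:
            st = solve_equilibrium(sys_i)
        except SolverFailureError as exc:
            raise SolverFailureError(f"titration failed at L_tot={lt:g} M: {exc}") from exc
        states.append(st)
        limiting = min(sys_i.A_tot, sys_i.B_tot, sys_i.L_tot)
        f3[i] = ternary_fraction(st, sys_i) if limiting > 0 else np.nan
    return TitrationCurve(L_tot_grid=grid, states=tuple(states), f3=f3,
                          system_base=system_base)


def optimal_free_ligand(K_AL: float, K_BL: float) -> float:
    """Free-ligand concentration maximising [ALB]: the geometric mean of the Kd's."""
    if not (K_AL > 0 and K_BL > 0 and math.isfinite(K_AL) and math.isfinite(K_BL)):
        raise InvalidParameterError("both dissociation constants must be finite and > 0")
    return math.sqrt(K_AL * K_BL)


def optimal_total_ligand(system: TernarySystem) -> float:
    """Total-ligand dose at which [ALB] peaks.

    Depends only on the binary affinities and the protein totals, not on
    cooperativity:

        [L_tot]opt = sqrt(K_AL*K_BL) + A_tot/(1+sqrt(K_AL/K_BL))
                                     + B_tot/(1+sqrt(K_BL/K_AL))
    """
    r = math.sqrt(system.K_AL / system.K_BL)
    return (math.sqrt(system.K_AL * system.K_BL)
            + system.A_tot / (1.0 + r)
            + system.B_tot / (1.0 + 1.0 / r))


def optimal_fraction(system: TernarySystem) -> float:
    """Peak ternary fraction ``f3_opt`` over ligand dose (L_tot of ``system`` ignored).

    Evaluates the closed-form [ALB] at the optimal free ligand
    ``sqrt(K_AL*K_BL)`` and normalises by the limiting total at the optimal
    dose.
    """
    L_opt = optimal_free_ligand(system.K_AL, system.K_BL)
    alb = _alb_given_free_ligand(system, L_opt)
    L_tot_opt = optimal_total_ligand(system)
    limiting = min(system.A_tot, system.B_tot, L_tot_opt)
    if limiting <= 0:
        raise UndefinedFractionError("optimal fraction undefined when a protein total is zero")
    return min(alb / limiting, 1.0)


def hook_severity(curve: TitrationCurve) -> float:
    """Depth of the post-peak decline (hook effect) of a titration curve.

    The peak is the dose maximising [ALB] (the optimal dose of the closed
    forms); at strong binding f3 itself can plateau at low dose because the
    scarce ligand is almost always doubly bound, which is not the hook.
    Returns ``1 - f3(10 * L_tot_peak) / f3_peak`` in [0, 1]; the post-peak
    value is log-interpolated on the grid.  Larger values mean a more severe
    hook, i.e. stronger self-antagonism at high dose.
    """
    ipk = int(np.argmax([s.ALB for s in curve.states]))
    f_peak = curve.f3[ipk]
    if f_peak <= 0:
        raise InsufficientRangeError("titration curve never forms ternary complex")
    L_target = 10.0 * curve.L_tot_grid[ipk]
    if curve.L_tot_grid[-1] < L_target:
        raise InsufficientRangeError(
            f"grid ends at {curve.L_tot_grid[-1]:g} M, "
            f"needs to reach 10x the peak ({L_target:g} M)"
        )
    f_post = float(np.interp(math.log(L_target), np.log(curve.L_tot_grid), curve.f3))
    return min(max(1.0 - f_post / f_peak, 0.0), 1.0)


def response_surface(
    A_tot: float,
    B_tot: float,
    axis1: Sequence[float],
    axis2: Sequence[float],
    fixed: dict[str, float],
) -> np.ndarray:
    """Grid of ``f3_opt`` over two swept binding parameters.

    Two modes, selected by the single entry of ``fixed``:

    - ``{"alpha": a}``  — axes are (K_AL, K_BL) at fixed cooperativity;
    - ``{"K_AL": k}``   — axes are (K_BL, alpha) at fixed K_AL.

    Returns an array of shape ``(len(axis1), len(axis2))``.
    """
    ax1 = np.asarray(axis1, dtype=float)
    ax2 = np.asarray(axis2, dtype=float)
    keys = set(fixed)
    out = np.empty((len(ax1), len(ax2)))
    if keys == {"alpha"}:
        for i, kal in enumerate(ax1):
            for j, kbl in enumerate(ax2):
                out[i, j] = optimal_fraction(TernarySystem(
                    A_tot=A_tot, B_tot=B_tot, L_tot=0.0,
                    K_AL=float(kal), K_BL=float(kbl), alpha=fixed["alpha"]))
    elif keys == {"K_AL"}:
        for i, kbl in enumerate(ax1):
            for j, a in enumerate(ax2):
                out[i, j] = optimal_fraction(TernarySystem(
                    A_tot=A_tot, B_tot=B_tot, L_tot=0.0,
                    K_AL=fixed["K_AL"], K_BL=float(kbl), alpha=float(a)))
    else:
        raise InvalidParameterError(
            "fixed must be exactly {'alpha': ...} (axes K_AL,K_BL) "
            "or {'K_AL': ...} (axes K_BL,alpha)"
        )
    return out
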