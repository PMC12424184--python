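"""Cooperativity <-> free-energy conversions and the decomposition ledger.

Cooperativity maps to a cooperative free energy through

    dG_alpha = -kB*T * ln(alpha)

and a dissociation constant to a binding free energy through
``K = c0 * exp(beta * dG)`` with the standard concentration ``c0 = 1 M``.
The cooperative free energy decomposes (within the stabilized geometric
space, superscript ``s``) into

    dG_alpha = dG_AB_induced + ddG_coop_solv + dG_gas_coop + ddG_alpha_geo
             ~ dG_AB_induced + ddG_coop_solv

where the two-term approximation drops the gas-phase correlation and net
geometric cost, both small for rigid ligands.  The *reduced cooperativity*
``phi`` removes the intrinsic protein-protein contribution:
``dG_phi = dG_alpha - dG_AB``; phi = 1 for a nonperturbative ligand.

All energies are kJ/mol, all concentrations molar.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from dataclasses import replace

from .equilibrium import TernarySystem, titration
from .errors import (
    IncompleteLedgerError,
    InsufficientRangeError,
    InvalidParameterError,
)

__all__ = [
    "KB_KJ_PER_MOL_K",
    "ThermoContext",
    "CooperativityValue",
    "FreeEnergyLedger",
    "LedgerAlphaResult",
    "dg_from_alpha",
    "alpha_from_dg",
    "kd_from_dg",
    "dg_from_kd",
    "k3_from_alpha",
    "k3_from_phi",
    "phi_from_alpha",
    "alpha_nonperturbative",
    "induced_ppi_from_geometry",
    "classify_perturbation",
    "ledger_alpha",
    "apparent_cooperativity",
]

#: Boltzmann constant x Avogadro, kJ/mol/K
KB_KJ_PER_MOL_K = 0.0083145


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and standard-state convention for all conversions.

    Defaults to 298 K and c0 = 1 M, giving kB*T ~ 2.478 kJ/mol.
    """

    temperature: float = 298.0
    c0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise InvalidParameterError(f"temperature must be > 0 K, got {self.temperature!r}")
        if self.c0 != 1.0:
            raise InvalidParameterError("standard concentration is fixed at 1 M")

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return KB_KJ_PER_MOL_K * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB*T) in mol/kJ."""
        return 1.0 / self.kT


def dg_from_alpha(alpha: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Cooperative free energy -kB*T*ln(alpha) in kJ/mol."""
    if not (alpha > 0 and math.isfinite(alpha)):
        raise InvalidParameterError(f"alpha must be finite and > 0, got {alpha!r}")
    return -ctx.kT * math.log(alpha)


def alpha_from_dg(dG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Cooperativity exp(-beta*dG); exact inverse of :func:`dg_from_alpha`."""
    if not math.isfinite(dG):
        raise InvalidParameterError(f"dG must be finite, got {dG!r}")
    return math.exp(-ctx.beta * dG)


def kd_from_dg(dG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Dissociation constant c0*exp(beta*dG) in molar."""
    if not math.isfinite(dG):
        raise InvalidParameterError(f"dG must be finite, got {dG!r}")
    x = ctx.beta * dG
    if x > 700.0:
        raise InvalidParameterError(f"dG={dG:g} kJ/mol overflows exp at T={ctx.temperature:g} K")
    return ctx.c0 * math.exp(x)


def dg_from_kd(K: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Binding free energy kB*T*ln(K/c0) in kJ/mol."""
    if not (K > 0 and math.isfinite(K)):
        raise InvalidParameterError(f"K must be finite and > 0, got {K!r}")
    return ctx.kT * math.log(K / ctx.c0)


def k3_from_alpha(K_AL: float, K_BL: float, alpha: float,
                  ctx: ThermoContext = ThermoContext()) -> float:
    """Effective ternary dissociation constant K3 = K_AL*K_BL/alpha (M^2)."""
    for name, v in (("K_AL", K_AL), ("K_BL", K_BL), ("alpha", alpha)):
        if not (v > 0 and math.isfinite(v)):
            raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
    return K_AL * K_BL / alpha


def k3_from_phi(K_AL: float, K_BL: float, K_AB: float, phi: float,
                ctx: ThermoContext = ThermoContext()) -> float:
    """K3 expressed with reduced cooperativity: (K_AB/c0)*K_AL*K_BL/phi (M^2).

    K_AB is normalised by c0 so the result keeps units molar^2; this is the
    implicit standard-state convention of writing phi = K_AB for a
    noncooperative ligand.
    """
    for name, v in (("K_AL", K_AL), ("K_BL", K_BL), ("K_AB", K_AB), ("phi", phi)):
        if not (v > 0 and math.isfinite(v)):
            raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
    return (K_AB / ctx.c0) * K_AL * K_BL / phi


@dataclass(frozen=True)
class CooperativityValue:
    """A cooperativity with its free energy, optionally reduced by the intrinsic PPI."""

    alpha: float
    dG_alpha: float
    phi: float | None = None
    dG_phi: float | None = None


def phi_from_alpha(alpha: float, dG_AB: float,
                   ctx: ThermoContext = ThermoContext()) -> CooperativityValue:
    """Reduced cooperativity: dG_phi = dG_alpha - dG_AB, phi = exp(-beta*dG_phi).

    ``dG_AB`` is the intrinsic protein-protein binding free energy (kJ/mol).
    phi isolates the genuinely nonadditive part of ternary binding: a
    nonperturbative ligand (dG_alpha == dG_AB) has phi = 1, while a
    noncooperative ligand (alpha = 1) has phi = K_AB/c0.
    """
    if not math.isfinite(dG_AB):
        raise InvalidParameterError(f"dG_AB must be finite, got {dG_AB!r}")
    dga = dg_from_alpha(alpha, ctx)
    dgp = dga - dG_AB
    return CooperativityValue(alpha=alpha, dG_alpha=dga,
                              phi=math.exp(-ctx.beta * dgp), dG_phi=dgp)


def alpha_nonperturbative(K_AB: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Cooperativity of a nonperturbative ligand: c0 / K_AB.

    A ligand that binds without perturbing the intrinsic protein-protein
    bound state makes the induced PPIs equal to the intrinsic ones, so the
    whole cooperative free energy is the intrinsic binding free energy and
    alpha reduces to the reciprocal (c0-scaled) dissociation constant.  Even
    a weak 10 mM protein pair then yields alpha = 100.
    """
    if not (K_AB > 0 and math.isfinite(K_AB)):
        raise InvalidParameterError(f"K_AB must be finite and > 0, got {K_AB!r}")
    return ctx.c0 / K_AB


def _check_geo(geo_A: float, geo_B: float, geo_AB: float) -> None:
    for name, v in (("geo_A", geo_A), ("geo_B", geo_B), ("geo_AB", geo_AB)):
        if not math.isfinite(v) or v < 0:
            raise InvalidParameterError(
                f"{name} must be finite and >= 0 (free forms are always at "
                f"least as favorable as stabilized forms), got {v!r}"
            )


def induced_ppi_from_geometry(dG_AB: float, geo_A: float, geo_B: float,
                              geo_AB: float) -> float:
    """Induced PPI strength from the intrinsic PPI and geometric costs.

    ``dG_AB_induced = dG_AB + geo_AB - (geo_A + geo_B)``: a binary
    perturbation (geo_AB > 0) weakens the induced PPIs relative to the
    intrinsic ones, whereas unary perturbations (geo_A, geo_B > 0) can
    strengthen them.
    """
    if not math.isfinite(dG_AB):
        raise InvalidParameterError(f"dG_AB must be finite, got {dG_AB!r}")
    _check_geo(geo_A, geo_B, geo_AB)
    return dG_AB + geo_AB - geo_A - geo_B


def classify_perturbation(geo_A: float, geo_B: float, geo_AB: float,
                          dG_induced: float, tol: float = 0.1) -> str:
    """Classify how a ligand modulates the protein-protein interface.

    - ``nonperturbative``: no geometric cost at all — induced PPIs equal the
      intrinsic ones;
    - ``noncooperative``: the induced PPIs vanish — the ligand separates the
      proteins back to their binary state;
    - ``binary-perturbative``: only the intermolecular pose is altered
      (geo_AB > 0, unary costs ~ 0);
    - ``unary-perturbative``: the intramolecular geometry of at least one
      protein is perturbed.

    ``tol`` (kJ/mol) absorbs numerical noise in the inputs.
    """
    _check_geo(geo_A, geo_B, geo_AB)
    if tol < 0:
        raise InvalidParameterError("tol must be >= 0")
    if geo_A <= tol and geo_B <= tol and geo_AB <= tol:
        return "nonperturbative"
    if abs(dG_induced) <= tol:
        return "noncooperative"
    if geo_AB > tol and geo_A + geo_B <= tol:
        return "binary-perturbative"
    return "unary-perturbative"


@dataclass(frozen=True)
class FreeEnergyLedger:
    """The four-term decomposition of the cooperative free energy (kJ/mol).

    ``dG_induced_PPI`` is the binding free energy between the
    ligand-stabilized protein conformations; ``ddG_coop_solv`` the
    non-additive (three-body) desolvation; ``dG_gas_coop`` the gas-phase
    correlation between the two protein-ligand binding events; and
    ``ddG_alpha_geo`` the net geometric cost of the ligand-associated states.
    Optional fields carry the intrinsic PPI and the individual stabilization
    costs (each >= 0).
    """

    dG_induced_PPI: float
    ddG_coop_solv: float
    dG_gas_coop: float
    ddG_alpha_geo: float
    dG_AB_intrinsic: float | None = None
    geo_A: float | None = None
    geo_B: float | None = None
    geo_AB: float | None = None

    def __post_init__(self) -> None:
        for name in ("dG_induced_PPI", "ddG_coop_solv", "dG_gas_coop", "ddG_alpha_geo"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise IncompleteLedgerError(f"ledger component {name} must be a finite energy")
        for name in ("geo_A", "geo_B", "geo_AB"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class LedgerAlphaResult:
    """Exact and two-term-approximate cooperativities implied by a ledger."""

    dG_alpha: float
    alpha: float
    dG_alpha_approx: float
    alpha_approx: float
    gap: float  # |dropped terms| = |dG_gas_coop + ddG_alpha_geo|


def ledger_alpha(ledger: FreeEnergyLedger,
                 ctx: ThermoContext = ThermoContext()) -> LedgerAlphaResult:
    """Close the decomposition: sum the four terms and convert to cooperativity.

    The exact cooperative free energy is the full four-term sum; the
    approximation keeps only the induced-PPI and cooperative-solvation terms.
    """
    exact = (ledger.dG_induced_PPI + ledger.ddG_coop_solv
             + ledger.dG_gas_coop + ledger.ddG_alpha_geo)
    approx = ledger.dG_induced_PPI + ledger.ddG_coop_solv
    return LedgerAlphaResult(
        dG_alpha=exact,
        alpha=alpha_from_dg(exact, ctx),
        dG_alpha_approx=approx,
        alpha_approx=alpha_from_dg(approx, ctx),
        gap=abs(ledger.dG_gas_coop + ledger.ddG_alpha_geo),
    )


def _ec50(grid: np.ndarray, frac: np.ndarray, plateau_tol: float = 0.01) -> float:
    """Half-plateau dose from a bound-fraction titration, log-interpolated.

    The bound fraction of the monitored protein is monotone in dose; the
    plateau is taken from the top of the grid and must have flattened to
    within ``plateau_tol`` relative over the last decade.
    """
    plateau = float(frac[-1])
    if plateau <= 0:
        raise InsufficientRangeError("bound fraction is zero over the whole grid")
    # flatness check: compare against the value one decade below the top
    ref = float(np.interp(math.log(grid[-1] / 10.0), np.log(grid), frac))
    if plateau - ref > plateau_tol * plateau:
        raise InsufficientRangeError(
            f"bound fraction still rising at the top of the grid "
            f"({ref:g} -> {plateau:g}); extend the dose range"
        )
    half = plateau / 2.0
    above = frac >= half
    if not above.any() or above[0]:
        raise InsufficientRangeError("half-plateau dose not bracketed by the grid")
    idx = int(np.argmax(above))
    lo, hi = idx - 1, idx
    t = (half - frac[lo]) / (frac[hi] - frac[lo])
    return float(math.exp(math.log(grid[lo]) + t * (math.log(grid[hi]) - math.log(grid[lo]))))


def bound_fraction_curve(system: TernarySystem, grid: Sequence[float]) -> np.ndarray:
    """Ligand-bound fraction of protein A, (AL + ALB)/A_tot, along a dose grid."""
    if system.A_tot <= 0:
        raise InvalidParameterError("bound fraction of A requires A_tot > 0")
    curve = titration(system, grid)
    return np.array([(s.AL + s.ALB) / system.A_tot for s in curve.states])


def apparent_cooperativity(system_base: TernarySystem,
                           saturating_partner_conc: float,
                           grid: Sequence[float]) -> float:
    """Apparent cooperativity as an EC50-shift ratio.

    Titrates ligand against protein A alone and against A in the presence of
    partner B at a saturating concentration, locates both EC50 values of A's
    ligand-bound fraction ``(AL + ALB)/A_tot`` by monotone log-interpolation,
    and returns ``EC50(binary) / EC50(ternary)``.  For alpha = 1 the ratio is
    1 up to grid tolerance; positive cooperativity shifts the ternary EC50
    left and makes the ratio > 1.
    """
    if saturating_partner_conc < 10.0 * system_base.K_BL:
        warnings.warn(
            f"partner concentration {saturating_partner_conc:g} M is below "
            f"10x K_BL = {10 * system_base.K_BL:g} M; the EC50 shift will "
            f"underestimate the true cooperativity",
            stacklevel=2,
        )
    grid = np.asarray(grid, dtype=float)
    binary = replace(system_base, B_tot=0.0)
    ternary = replace(system_base, B_tot=float(saturating_partner_conc))
    f_bin = bound_fraction_curve(binary, grid)
    f_ter = bound_fraction_curve(ternary, grid)
    return _ec50(grid, f_bin) / _ec50(grid, f_ter)
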