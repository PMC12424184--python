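"""Rapid cooperativity estimation from per-frame subsystem energies.

Under the single-trajectory approximation all seven subsystems
{ALB, AL, BL, AB, A, B, L} are evaluated on the same ternary-complex
trajectory frames, each frame contributing a gas-phase potential energy
``E_gas`` and an implicit-solvent solvation energy ``G_solv`` per subsystem
(MM/PBSA-style post-processing).  Two frame-level combinations are averaged:

- induced PPIs:  (E_AB - E_A - E_B) + (G_AB - G_A - G_B)
- cooperative solvation:  G_ALB - G_AL - G_BL - G_AB + G_A + G_B + G_L

and their sum approximates the cooperative free energy dG_alpha.  Frames
within a replicate trajectory are autocorrelated, so replicate means are the
statistical unit: the SEM is the sample standard deviation of per-replicate
means over sqrt(N).  Binary entropy contributions are neglected throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidParameterError, SchemaError
from .thermo import ThermoContext, alpha_from_dg, dg_from_alpha

__all__ = [
    "SUBSYSTEMS",
    "COOP_SOLV_WEIGHTS",
    "KCAL_TO_KJ",
    "FrameEnergyTable",
    "CoopEstimate",
    "ExperimentalRecord",
    "interaction_energy_frame",
    "desolvation_ab_frame",
    "induced_ppi_estimate",
    "coop_solvation_estimate",
    "estimate_complex",
    "estimate_panel",
    "kendall_tau",
    "ComparisonReport",
    "compare_to_experiment",
]

#: canonical subsystem order of the single-trajectory decomposition
SUBSYSTEMS = ("ALB", "AL", "BL", "AB", "A", "B", "L")

#: signs applied to G_solv of each subsystem (in SUBSYSTEMS order) for the
#: cooperative-solvation combination; note the weights sum to +1, so a
#: constant added to every subsystem's solvation energy shifts the estimate
#: by exactly that constant.
COOP_SOLV_WEIGHTS = (1, -1, -1, -1, 1, 1, 1)

KCAL_TO_KJ = 4.184

_COLUMNS = ("complex_id", "replicate_id", "frame_index", "subsystem", "E_gas", "G_solv")


@dataclass(frozen=True)
class FrameEnergyTable:
    """Validated long-format table of per-frame subsystem energies.

    Columns: ``complex_id, replicate_id, frame_index, subsystem, E_gas,
    G_solv`` (energies in kJ/mol).  Every (complex, replicate, frame) must
    carry all seven subsystems exactly once; incomplete frames are rejected,
    never imputed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"frame-energy table missing columns: {missing}")
        if len(df) == 0:
            raise SchemaError("frame-energy table is empty")
        bad = set(df["subsystem"].unique()) - set(SUBSYSTEMS)
        if bad:
            raise SchemaError(f"unknown subsystem labels: {sorted(bad)}")
        if not np.isfinite(df["E_gas"]).all() or not np.isfinite(df["G_solv"]).all():
            raise SchemaError("non-finite energies in frame-energy table")
        counts = df.groupby(
            ["complex_id", "replicate_id", "frame_index"], sort=False
        )["subsystem"].agg(["count", "nunique"])
        offenders = counts[(counts["count"] != len(SUBSYSTEMS))
                           | (counts["nunique"] != len(SUBSYSTEMS))]
        if len(offenders):
            key = offenders.index[0]
            raise SchemaError(
                f"frame {key} does not carry all seven subsystems exactly once "
                f"({len(offenders)} offending frame(s))"
            )

    @property
    def complex_ids(self) -> list:
        return list(pd.unique(self.df["complex_id"]))

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "kJ") -> "FrameEnergyTable":
        """Read a table from CSV; ``units='kcal'`` converts energies to kJ/mol."""
        df = pd.read_csv(path, float_precision="round_trip")
        if units == "kcal":
            df = df.assign(E_gas=df["E_gas"] * KCAL_TO_KJ,
                           G_solv=df["G_solv"] * KCAL_TO_KJ)
        elif units != "kJ":
            raise InvalidParameterError(f"units must be 'kJ' or 'kcal', got {units!r}")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.17g")

    def _wide(self, column: str) -> pd.DataFrame:
        """Pivot one energy column to frame rows x subsystem columns."""
        wide = self.df.pivot_table(
            index=["complex_id", "replicate_id", "frame_index"],
            columns="subsystem", values=column, aggfunc="first", sort=False,
        )
        return wide[list(SUBSYSTEMS)]


def interaction_energy_frame(E_AB: float, E_A: float, E_B: float) -> float:
    """Gas-phase protein-protein interaction energy of one frame: E_AB - E_A - E_B."""
    for name, v in (("E_AB", E_AB), ("E_A", E_A), ("E_B", E_B)):
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError(f"{name} must be finite")
    return E_AB - E_A - E_B


def desolvation_ab_frame(G_AB: float, G_A: float, G_B: float) -> float:
    """Protein-protein desolvation penalty of one frame: G_AB - G_A - G_B."""
    for name, v in (("G_AB", G_AB), ("G_A", G_A), ("G_B", G_B)):
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError(f"{name} must be finite")
    return G_AB - G_A - G_B


def induced_ppi_estimate(table: FrameEnergyTable, by_replicate: bool = True) -> pd.Series:
    """Induced protein-protein interaction free energy per replicate (kJ/mol).

    Frame-wise ``(E_AB - E_A - E_B) + (G_AB - G_A - G_B)`` averaged over the
    frames of each replicate; with ``by_replicate=False`` the unaveraged
    per-frame values are returned.
    """
    eg, gs = table._wide("E_gas"), table._wide("G_solv")
    per_frame = (eg["AB"] - eg["A"] - eg["B"]) + (gs["AB"] - gs["A"] - gs["B"])
    per_frame.name = "induced_ppi"
    if not by_replicate:
        return per_frame
    return per_frame.groupby(level=["complex_id", "replicate_id"], sort=False).mean()


def coop_solvation_estimate(table: FrameEnergyTable, by_replicate: bool = True) -> pd.Series:
    """Cooperative (non-additive three-body) solvation free energy per replicate.

    Frame-wise ``G_ALB - G_AL - G_BL - G_AB + G_A + G_B + G_L`` averaged over
    each replicate; identically zero when solvation is pairwise additive.
    """
    gs = table._wide("G_solv")
    per_frame = sum(w * gs[s] for w, s in zip(COOP_SOLV_WEIGHTS, SUBSYSTEMS))
    per_frame.name = "coop_solv"
    if not by_replicate:
        return per_frame
    return per_frame.groupby(level=["complex_id", "replicate_id"], sort=False).mean()


@dataclass(frozen=True)
class CoopEstimate:
    """Replicate-level summary of the approximated cooperative free energy."""

    complex_id: str
    induced_ppi_mean: float
    induced_ppi_sem: float
    coop_solv_mean: float
    coop_solv_sem: float
    dG_alpha_approx: float
    n_replicates: int

    def alpha_approx(self, ctx: ThermoContext = ThermoContext()) -> float:
        """Predicted cooperativity exp(-beta * dG_alpha_approx)."""
        return alpha_from_dg(self.dG_alpha_approx, ctx)


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, math.nan
    return mean, float(np.std(values, ddof=1) / math.sqrt(n))


def estimate_complex(table: FrameEnergyTable,
                     ctx: ThermoContext = ThermoContext()) -> CoopEstimate:
    """Approximated cooperative free energy of a single complex.

    Both components are averaged per replicate; replicate means (not pooled
    frames) define the SEM, since frames within a trajectory are correlated.
    A single replicate yields NaN SEMs with a warning.
    """
    ids = table.complex_ids
    if len(ids) != 1:
        raise InvalidParameterError(
            f"estimate_complex expects one complex, table has {ids}; use estimate_panel"
        )
    induced = induced_ppi_estimate(table).to_numpy()
    coop = coop_solvation_estimate(table).to_numpy()
    n = len(induced)
    if n < 2:
        warnings.warn(
            f"complex {ids[0]!r} has a single replicate; SEM is undefined",
            stacklevel=2,
        )
    ind_mean, ind_sem = _mean_sem(induced)
    coop_mean, coop_sem = _mean_sem(coop)
    return CoopEstimate(
        complex_id=ids[0],
        induced_ppi_mean=ind_mean, induced_ppi_sem=ind_sem,
        coop_solv_mean=coop_mean, coop_solv_sem=coop_sem,
        dG_alpha_approx=ind_mean + coop_mean,
        n_replicates=n,
    )


def estimate_panel(table: FrameEnergyTable,
                   ctx: ThermoContext = ThermoContext()) -> list[CoopEstimate]:
    """One :class:`CoopEstimate` per complex in a multi-complex table."""
    return [
        estimate_complex(FrameEnergyTable(sub), ctx)
        for _, sub in table.df.groupby("complex_id", sort=False)
    ]


def estimates_to_frame(estimates: Iterable[CoopEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


@dataclass(frozen=True)
class ExperimentalRecord:
    """An experimentally measured cooperativity for one complex."""

    complex_id: str
    alpha_exp: float
    alpha_kind: str  # "absolute" (Kd ratio) or "apparent" (EC50/IC50 shift)

    def __post_init__(self) -> None:
        if not (self.alpha_exp > 0 and math.isfinite(self.alpha_exp)):
            raise InvalidParameterError(f"alpha_exp must be > 0, got {self.alpha_exp!r}")
        if self.alpha_kind not in ("absolute", "apparent"):
            raise InvalidParameterError(
                f"alpha_kind must be 'absolute' or 'apparent', got {self.alpha_kind!r}"
            )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall rank correlation by explicit pair counting (tie-adjusted tau-b).

    tau = (concordant - discordant) / sqrt((n0 - t_x) * (n0 - t_y)) with
    n0 = n(n-1)/2 and t the tied-pair counts in each variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 2:
        raise InsufficientDataError("kendall tau needs at least two observations")
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        raise InsufficientDataError("all pairs tied; tau undefined")
    return (conc - disc) / denom


@dataclass(frozen=True)
class ComparisonReport:
    """Predicted-vs-experimental cooperative free energies for a panel."""

    complex_ids: tuple
    dG_pred: np.ndarray
    dG_exp: np.ndarray
    alpha_kinds: tuple
    tau: float
    #: fits as {"slope", "intercept", "r"}; experimental-on-predicted mirrors
    #: plotting experiment against prediction, the reverse fit is also given
    fit_exp_on_pred: dict
    fit_pred_on_exp: dict

    @property
    def n(self) -> int:
        return len(self.complex_ids)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "complex_ids": list(self.complex_ids),
            "dG_pred_kJ_mol": [float(v) for v in self.dG_pred],
            "dG_exp_kJ_mol": [float(v) for v in self.dG_exp],
            "alpha_kinds": list(self.alpha_kinds),
            "kendall_tau": self.tau,
            "fit_exp_on_pred": self.fit_exp_on_pred,
            "fit_pred_on_exp": self.fit_pred_on_exp,
        }


def _fit(x: np.ndarray, y: np.ndarray) -> dict:
    res = linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue)}


def compare_to_experiment(
    estimates: Sequence[CoopEstimate],
    experiments: Sequence[ExperimentalRecord] | pd.DataFrame,
    ctx: ThermoContext = ThermoContext(),
) -> ComparisonReport:
    """Rank agreement between predicted and experimental cooperativities.

    Experimental alphas are converted to free energies via
    ``dG = -kB*T*ln(alpha)`` and matched to predictions on ``complex_id``
    (at least three matches required).  Reports the tie-adjusted Kendall tau
    between the two dG series and ordinary least-squares fits in both
    orientations, since either axis convention appears in practice.
    """
    if isinstance(experiments, pd.DataFrame):
        experiments = [
            ExperimentalRecord(row.complex_id, float(row.alpha_exp), row.alpha_kind)
            for row in experiments.itertuples(index=False)
        ]
    exp_by_id = {r.complex_id: r for r in experiments}
    matched = [(e, exp_by_id[e.complex_id]) for e in estimates
               if e.complex_id in exp_by_id]
    if len(matched) < 3:
        raise InsufficientDataError(
            f"need >=3 matched complex_ids, got {len(matched)}"
        )
    dg_pred = np.array([e.dG_alpha_approx for e, _ in matched])
    dg_exp = np.array([dg_from_alpha(r.alpha_exp, ctx) for _, r in matched])
    return ComparisonReport(
        complex_ids=tuple(e.complex_id for e, _ in matched),
        dG_pred=dg_pred,
        dG_exp=dg_exp,
        alpha_kinds=tuple(r.alpha_kind for _, r in matched),
        tau=kendall_tau(dg_pred, dg_exp),
        fit_exp_on_pred=_fit(dg_pred, dg_exp),
        fit_pred_on_exp=_fit(dg_exp, dg_pred),
    )
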