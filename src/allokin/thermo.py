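"""Transition-state thermodynamics for elementary reactions.

The Eyring equation relates a unidirectional rate constant to the activation
free energy of its transition state,

    k = kappa * (k_B * T / h) * exp(-dG_act / (R * T)),

and the linear free energy relationship (LFER) ties the shift of the
transition-state energy linearly to the shifts of the two ground states,

    ddG_act = alpha * ddG_P + (1 - alpha) * ddG_R,

where alpha in [0, 1] locates the transition state on the reaction coordinate
(0 = reactant-like, 1 = product-like).  A state-selective ligand lowers the
free energy of each ground state by the binding polynomial
-RT*ln(1 + [M]/K_D); pushing that shift through the LFER yields the modified
forward and backward rate constants of the modulated reaction.  These two
equations, composed, are the whole machinery of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "BOLTZMANN",
    "PLANCK",
    "DEFAULT_TEMPERATURE",
    "ThermoContext",
    "ElementaryReaction",
    "TransitionBarrier",
    "ModulatorBinding",
    "LFERShift",
    "barrier_to_rate",
    "rate_to_barrier",
    "reaction_barriers",
    "stabilization_energy",
    "lfer_apply",
    "extract_alpha",
    "enumerate_balanced_pairs",
]

#: molar gas constant, J mol^-1 K^-1 (CODATA 2018, exact)
GAS_CONSTANT = 8.31446261815324
#: Boltzmann constant, J K^-1 (exact)
BOLTZMANN = 1.380649e-23
#: Planck constant, J s (exact)
PLANCK = 6.62607015e-34
#: default simulation temperature, K (20 deg C)
DEFAULT_TEMPERATURE = 293.15


@dataclass(frozen=True)
class ThermoContext:
    """Physical constants and temperature governing rate <-> energy conversions.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 293.15 K.
    transmission_coefficient : float
        Eyring transmission coefficient kappa in (0, 1]; 1 means no
        recrossing of the barrier.  Default 1.
    """

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT
    boltzmann: float = BOLTZMANN
    planck: float = PLANCK
    transmission_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not (0.0 < self.transmission_coefficient <= 1.0):
            raise ValueError(
                "transmission_coefficient must lie in (0, 1], got "
                f"{self.transmission_coefficient}"
            )
        for name in ("gas_constant", "boltzmann", "planck"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def rt(self) -> float:
        """R*T in J mol^-1."""
        return self.gas_constant * self.temperature

    @property
    def attempt_frequency(self) -> float:
        """Universal attempt frequency k_B*T/h in s^-1 (~6.1e12 at 293 K)."""
        return self.boltzmann * self.temperature / self.planck


@dataclass(frozen=True)
class ElementaryReaction:
    """A reversible single-barrier step with an alpha locating its transition state.

    ``alpha`` may be any real number on construction: values outside [0, 1]
    violate the LFER bracketing assumption but remain thermodynamically legal
    (they still satisfy detailed balance); the ``lfer_compliant`` flag records
    which regime the reaction is in.
    """

    k_fw: float
    k_bw: float
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not (self.k_fw > 0 and math.isfinite(self.k_fw)):
            raise ValueError(f"k_fw must be positive and finite, got {self.k_fw}")
        if not (self.k_bw > 0 and math.isfinite(self.k_bw)):
            raise ValueError(f"k_bw must be positive and finite, got {self.k_bw}")
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    @property
    def equilibrium_constant(self) -> float:
        return self.k_fw / self.k_bw

    @property
    def lfer_compliant(self) -> bool:
        return 0.0 <= self.alpha <= 1.0


@dataclass(frozen=True)
class TransitionBarrier:
    """Forward and backward activation free energies of one step, J mol^-1."""

    dG_forward: float
    dG_backward: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dG_forward) and math.isfinite(self.dG_backward)):
            raise ValueError("activation free energies must be finite")

    @property
    def reaction_free_energy(self) -> float:
        """dG of the overall step (= -RT ln K_eq of the generating reaction)."""
        return self.dG_forward - self.dG_backward


@dataclass(frozen=True)
class ModulatorBinding:
    """A ligand's dissociation constants for the two ground states, plus [M].

    All quantities in molar.  ``selectivity`` > 1 means the ligand prefers the
    product state, i.e. it stabilizes the product more than the reactant.
    """

    kd_reactant: float
    kd_product: float
    concentration: float

    def __post_init__(self) -> None:
        if not self.kd_reactant > 0:
            raise ValueError("kd_reactant must be positive")
        if not self.kd_product > 0:
            raise ValueError("kd_product must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def selectivity(self) -> float:
        """Affinity ratio K_D(reactant)/K_D(product)."""
        return self.kd_reactant / self.kd_product


@dataclass(frozen=True)
class LFERShift:
    """Result of pushing ground-state stabilizations through the LFER.

    ``ddG_ts`` is the transition-state shift; ``k_fw_new``/``k_bw_new`` are the
    modulated rate constants.  The equilibrium shift
    (k_fw_new/k_bw_new)/(k_fw/k_bw) = exp(-(ddG_product - ddG_reactant)/RT)
    is independent of alpha: the LFER only decides how the shift is split
    between the two unidirectional rates.
    """

    ddG_reactant: float
    ddG_product: float
    ddG_ts: float
    k_fw_new: float
    k_bw_new: float


def barrier_to_rate(dG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Eyring equation: activation free energy (J mol^-1) -> rate constant (s^-1).

    Strictly decreasing in ``dG``; at dG = 0 returns kappa*k_B*T/h.
    """
    if not math.isfinite(dG):
        raise ValueError(f"activation free energy must be finite, got {dG}")
    return ctx.transmission_coefficient * ctx.attempt_frequency * math.exp(-dG / ctx.rt)


def rate_to_barrier(k: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse Eyring equation: rate constant (s^-1) -> activation free energy.

    Raises ``ValueError`` for non-positive rates.
    """
    if not (k > 0 and math.isfinite(k)):
        raise ValueError(f"rate constant must be positive and finite, got {k}")
    return -ctx.rt * math.log(k / (ctx.transmission_coefficient * ctx.attempt_frequency))


def reaction_barriers(
    rxn: ElementaryReaction, ctx: ThermoContext = ThermoContext()
) -> TransitionBarrier:
    """Activation free energies of both directions of an elementary reaction."""
    return TransitionBarrier(
        dG_forward=rate_to_barrier(rxn.k_fw, ctx),
        dG_backward=rate_to_barrier(rxn.k_bw, ctx),
    )


def stabilization_energy(
    kd: float, conc: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """Ground-state free-energy shift on ligand binding, -RT*ln(1 + [M]/K_D).

    Always <= 0 (binding can only stabilize a ground state); 0 at zero ligand.
    For two states with K_D ratio rho the difference of their shifts tends to
    -RT*ln(rho) as [M] -> infinity, which is what caps the attainable rate
    change at the selectivity ratio.
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return -ctx.rt * math.log1p(conc / kd)


def lfer_apply(
    rxn: ElementaryReaction,
    binding: ModulatorBinding,
    ctx: ThermoContext = ThermoContext(),
    alpha: float | None = None,
) -> LFERShift:
    """Modulated rate constants of an elementary reaction under the LFER.

    Computes the ground-state stabilizations from the binding polynomial,
    places the transition-state shift at
    ddG_ts = alpha*ddG_P + (1-alpha)*ddG_R, and re-derives both rate constants
    from the changed barrier heights:

        k_fw_new = k_fw * exp(-(ddG_ts - ddG_R)/RT)
        k_bw_new = k_bw * exp(-(ddG_ts - ddG_P)/RT)

    ``alpha`` defaults to the reaction's own alpha.  Equal affinities for both
    states leave both rate constants untouched at any alpha.
    """
    if alpha is None:
        alpha = rxn.alpha
    ddG_r = stabilization_energy(binding.kd_reactant, binding.concentration, ctx)
    ddG_p = stabilization_energy(binding.kd_product, binding.concentration, ctx)
    ddG_ts = alpha * ddG_p + (1.0 - alpha) * ddG_r
    k_fw_new = rxn.k_fw * math.exp(-(ddG_ts - ddG_r) / ctx.rt)
    k_bw_new = rxn.k_bw * math.exp(-(ddG_ts - ddG_p) / ctx.rt)
    return LFERShift(
        ddG_reactant=ddG_r,
        ddG_product=ddG_p,
        ddG_ts=ddG_ts,
        k_fw_new=k_fw_new,
        k_bw_new=k_bw_new,
    )


def extract_alpha(ddG_ts: float, ddG_reactant: float, ddG_product: float) -> float:
    """Position of the transition state from the three free-energy shifts.

    Inverts the LFER: alpha = (ddG_ts - ddG_R) / (ddG_P - ddG_R).  Values
    outside [0, 1] are returned as-is — they describe landscapes that satisfy
    detailed balance but defy the LFER bracketing assumption.

    Raises ``ValueError`` when ddG_P = ddG_R (a non-selective perturbation
    leaves alpha undefined).
    """
    denom = ddG_product - ddG_reactant
    if denom == 0.0:
        raise ValueError(
            "alpha is undefined for a degenerate perturbation "
            "(ddG_product == ddG_reactant)"
        )
    return (ddG_ts - ddG_reactant) / denom


def enumerate_balanced_pairs(
    rxn: ElementaryReaction,
    binding: ModulatorBinding,
    alpha_grid,
    ctx: ThermoContext = ThermoContext(),
) -> pd.DataFrame:
    """Continuum of modulated rate-constant pairs satisfying detailed balance.

    For each alpha on the grid, applies the LFER transform and tabulates the
    pair (k_fw, k_bw) together with the three energy shifts.  Every row has
    the same k_fw/k_bw ratio (detailed balance only pins the ratio; alpha
    selects one landscape on the vertical line); rows with alpha outside
    [0, 1] are flagged ``lfer_compliant = False``.

    Returns a DataFrame with columns
    ``alpha, k_fw, k_bw, ddG_R, ddG_P, ddG_ts, lfer_compliant``.
    """
    alphas = np.asarray(list(alpha_grid), dtype=float)
    if alphas.size == 0:
        raise ValueError("alpha_grid must be non-empty")
    rows = []
    for a in alphas:
        shift = lfer_apply(rxn, binding, ctx, alpha=a)
        rows.append(
            {
                "alpha": a,
                "k_fw": shift.k_fw_new,
                "k_bw": shift.k_bw_new,
                "ddG_R": shift.ddG_reactant,
                "ddG_P": shift.ddG_product,
                "ddG_ts": shift.ddG_ts,
                "lfer_compliant": bool(0.0 <= a <= 1.0),
            }
        )
    return pd.DataFrame(rows)
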