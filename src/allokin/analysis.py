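"""Scan engines: gain/inhibition surfaces, EC50/IC50, and composite reactions.

The positive-modulator scans ask how much a state-selective ligand can speed
up steady-state substrate uptake as a function of the LFER position alpha, the
ligand concentration and its selectivity for the outward-facing state; the
negative-modulator scans ask the mirror question for uptake inhibition.  All
scan points are full 8-state steady-state solves — nothing here is fitted.

EC50/IC50 extraction: curves are normalized to [0, 1] between baseline and
plateau and the half-effect concentration is located by log-linear
interpolation between grid points.  A non-monotone normalized curve leaves the
value undefined (NaN) and adds a warning record instead of guessing.

The composite-reaction functions reduce a two-barrier reaction passing through
a short-lived intermediate (e.g. an occluded state) to an equivalent
single-barrier reaction via the quasi-steady-state approximation, and express
the modulator sensitivity of that observable reaction as an apparent alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scheme import cap_second_step, negative_cycle, positive_cycle
from .simulate import steady_state
from .thermo import (
    ElementaryReaction,
    ModulatorBinding,
    ThermoContext,
    extract_alpha,
    lfer_apply,
    stabilization_energy,
)

__all__ = [
    "GainScanResult",
    "InhibitionScanResult",
    "CompositeReaction",
    "CompositeRates",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_CONC_GRID",
    "DEFAULT_SELECTIVITIES",
    "gain_vs_alpha",
    "dose_response",
    "gain_vs_selectivity",
    "capped_gain_scan",
    "inhibition_scan",
    "composite_reduce",
    "alpha_app",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.linspace(0.0, 1.0, 21), 10))
DEFAULT_CONC_GRID = tuple(np.logspace(-8, 0, 31))
DEFAULT_SELECTIVITIES = (10.0, 100.0, 1000.0, 10000.0)


def _half_crossing_conc(concs: np.ndarray, norm: np.ndarray) -> float:
    """Concentration where a normalized 0->1 curve crosses 0.5, log-interpolated."""
    idx = np.nonzero(norm >= 0.5)[0]
    if idx.size == 0 or idx[0] == 0:
        return float("nan")
    i = idx[0]
    x0, x1 = math.log10(concs[i - 1]), math.log10(concs[i])
    y0, y1 = norm[i - 1], norm[i]
    return 10.0 ** (x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))


def _is_monotone(values: np.ndarray, increasing: bool, tol: float = 1.0e-9) -> bool:
    d = np.diff(values)
    return bool(np.all(d >= -tol) if increasing else np.all(d <= tol))


@dataclass(frozen=True)
class GainScanResult:
    """Tidy grid of uptake gains plus derived half-effect summaries."""

    table: pd.DataFrame  # columns: alpha, selectivity, conc_M, gain
    ec50: pd.DataFrame  # columns: alpha, selectivity, ec50_M (NaN if undefined)
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class InhibitionScanResult:
    """Tidy grid of normalized uptake under a negative modulator."""

    table: pd.DataFrame  # columns: alpha, selectivity, conc_M, normalized_uptake
    ic50: pd.DataFrame  # columns: alpha, selectivity, ic50_M, residual_uptake
    warnings: tuple[str, ...] = ()


def _positive_gain(alpha: float, conc: float, selectivity: float, baseline: float,
                   cap: float = math.inf) -> float:
    scheme = positive_cycle(alpha, conc, selectivity)
    if not math.isinf(cap):
        scheme = cap_second_step(scheme, cap)
    return steady_state(scheme).uptake_rate / baseline


def _positive_baseline(selectivity: float, cap: float = math.inf) -> float:
    # at zero modulator the rear loop is unpopulated, so the baseline does not
    # depend on alpha
    scheme = positive_cycle(0.5, 0.0, selectivity)
    if not math.isinf(cap):
        scheme = cap_second_step(scheme, cap)
    return steady_state(scheme).uptake_rate


def gain_vs_alpha(
    selectivity: float,
    conc_list=DEFAULT_CONC_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
) -> GainScanResult:
    """Uptake gain over an (alpha, concentration) grid at one selectivity.

    At alpha = 0 the modulator cannot accelerate the forward rate and the
    gain is 1 at every concentration; at saturation the gain grows
    monotonically with alpha up to the selectivity ratio.
    """
    if not selectivity >= 1:
        raise ValueError("selectivity must be >= 1")
    baseline = _positive_baseline(selectivity)
    rows = []
    for a in alpha_grid:
        for c in conc_list:
            rows.append(
                {
                    "alpha": float(a),
                    "selectivity": float(selectivity),
                    "conc_M": float(c),
                    "gain": _positive_gain(a, c, selectivity, baseline),
                }
            )
    table = pd.DataFrame(rows)
    ec50_rows = []
    warnings: list[str] = []
    concs = np.asarray(sorted(set(float(c) for c in conc_list)))
    if concs.size >= 4:
        for a, grp in table.groupby("alpha"):
            g = grp.sort_values("conc_M")["gain"].to_numpy()
            gmax = g.max()
            if gmax <= 1.0 + 1.0e-3:
                ec50 = float("nan")
            else:
                norm = (g - 1.0) / (gmax - 1.0)
                if not _is_monotone(norm, increasing=True):
                    warnings.append(f"non-monotone gain curve at alpha={a}")
                    ec50 = float("nan")
                else:
                    ec50 = _half_crossing_conc(concs, norm)
            ec50_rows.append(
                {"alpha": a, "selectivity": float(selectivity), "ec50_M": ec50}
            )
    return GainScanResult(
        table=table, ec50=pd.DataFrame(ec50_rows), warnings=tuple(warnings)
    )


def dose_response(
    selectivities=(10.0, 100.0, 1000.0),
    conc_grid=DEFAULT_CONC_GRID,
    alpha: float = 1.0,
) -> GainScanResult:
    """Normalized gain vs concentration for several selectivities, plus EC50s.

    The EC50 of the allosteric effect right-shifts as the modulator becomes
    more selective: a more selective ligand needs a higher concentration to
    stay bound through the low-affinity (inward-facing) states.
    """
    concs = np.asarray(sorted(float(c) for c in conc_grid))
    if math.log10(concs.max() / concs.min()) < 4:
        raise ValueError("conc_grid must span at least 4 decades")
    rows = []
    ec50_rows = []
    warnings: list[str] = []
    for sel in selectivities:
        baseline = _positive_baseline(sel)
        gains = np.array(
            [_positive_gain(alpha, c, sel, baseline) for c in concs]
        )
        gmax = gains.max()
        norm = (gains - 1.0) / (gmax - 1.0) if gmax > 1.0 else np.zeros_like(gains)
        for c, g, nv in zip(concs, gains, norm):
            rows.append(
                {
                    "alpha": float(alpha),
                    "selectivity": float(sel),
                    "conc_M": float(c),
                    "gain": float(g),
                    "normalized_gain": float(nv),
                }
            )
        if not _is_monotone(norm, increasing=True):
            warnings.append(f"non-monotone dose-response at selectivity={sel}")
            ec50 = float("nan")
        else:
            ec50 = _half_crossing_conc(concs, norm)
        ec50_rows.append(
            {"alpha": float(alpha), "selectivity": float(sel), "ec50_M": ec50}
        )
    return GainScanResult(
        table=pd.DataFrame(rows),
        ec50=pd.DataFrame(ec50_rows),
        warnings=tuple(warnings),
    )


def gain_vs_selectivity(
    alpha: float,
    conc: float,
    selectivity_grid=tuple(np.logspace(1, 4, 13)),
) -> pd.DataFrame:
    """Uptake gain as a function of modulator selectivity at fixed alpha, [M].

    At sub-saturating concentration and alpha < 1 the relation is
    bell-shaped: moderate selectivity buys acceleration (factor
    selectivity^alpha), but an over-selective ligand no longer occupies the
    low-affinity inward-facing state (occupancy ~ [M]/selectivity), so the
    product falls once selectivity^(alpha-1) decays faster than occupancy is
    gained.  At alpha = 1 the two effects exactly compensate and the curve
    rises to the plateau 1 + [M]/K_D(To).
    """
    rows = []
    for sel in selectivity_grid:
        baseline = _positive_baseline(sel)
        rows.append(
            {
                "alpha": float(alpha),
                "selectivity": float(sel),
                "conc_M": float(conc),
                "gain": _positive_gain(alpha, conc, sel, baseline),
            }
        )
    return pd.DataFrame(rows)


def capped_gain_scan(
    cap: float = 20.0,
    selectivities=(10.0, 100.0, 1000.0),
    alpha_grid=DEFAULT_ALPHA_GRID,
    conc: float = 1.0,
) -> GainScanResult:
    """Gain vs alpha when a second reaction (``cap`` s^-1) limits the cycle.

    Once the rate-limiting return step is accelerated past the capped
    translocation step, turnover saturates near the two-slow-step harmonic
    limit, so extra selectivity buys almost nothing.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    rows = []
    for sel in selectivities:
        baseline = _positive_baseline(sel, cap=cap)
        for a in alpha_grid:
            rows.append(
                {
                    "alpha": float(a),
                    "selectivity": float(sel),
                    "conc_M": float(conc),
                    "gain": _positive_gain(a, conc, sel, baseline, cap=cap),
                }
            )
    return GainScanResult(table=pd.DataFrame(rows), ec50=pd.DataFrame())


def inhibition_scan(
    selectivities=(10.0, 100.0, 1000.0),
    alpha_grid=DEFAULT_ALPHA_GRID,
    conc_grid=DEFAULT_CONC_GRID,
    base_translocation: float = 100.0,
) -> InhibitionScanResult:
    """Normalized uptake under a negative modulator, with IC50s and residuals.

    Because the slowed translocation step (100 s^-1 at baseline) stays faster
    than the 2 s^-1 rate-limiting return step unless the selectivity is large,
    uptake survives even at saturating modulator: the modulator acts as a
    partial inhibitor whose residual uptake shrinks with selectivity.
    """
    concs = np.asarray(sorted(float(c) for c in conc_grid))
    rows = []
    summary_rows = []
    warnings: list[str] = []
    for sel in selectivities:
        for a in alpha_grid:
            v0 = steady_state(
                negative_cycle(a, 0.0, sel, base_translocation)
            ).uptake_rate
            u = np.array(
                [
                    steady_state(
                        negative_cycle(a, c, sel, base_translocation)
                    ).uptake_rate
                    / v0
                    for c in concs
                ]
            )
            for c, val in zip(concs, u):
                rows.append(
                    {
                        "alpha": float(a),
                        "selectivity": float(sel),
                        "conc_M": float(c),
                        "normalized_uptake": float(val),
                    }
                )
            residual = float(u[-1])
            # effect curve rescaled to [0, 1] between baseline and plateau
            if 1.0 - residual > 1.0e-6:
                effect = (1.0 - u) / (1.0 - residual)
                if not _is_monotone(effect, increasing=True):
                    warnings.append(
                        f"non-monotone inhibition curve at alpha={a}, sel={sel}"
                    )
                    ic50 = float("nan")
                else:
                    ic50 = _half_crossing_conc(concs, effect)
            else:
                ic50 = float("nan")
            summary_rows.append(
                {
                    "alpha": float(a),
                    "selectivity": float(sel),
                    "ic50_M": ic50,
                    "residual_uptake": residual,
                }
            )
    return InhibitionScanResult(
        table=pd.DataFrame(rows),
        ic50=pd.DataFrame(summary_rows),
        warnings=tuple(warnings),
    )


# --------------------------------------------------------------------------- #
# composite reactions (occluded-state intermediate)
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CompositeReaction:
    """Two sequential barriers R <-> I <-> P with a short-lived intermediate.

    Step 1: R -> I forward rate ``a``, backward ``b``; step 2: I -> P forward
    ``c``, backward ``d`` (all s^-1).  ``alpha1``/``alpha2`` locate the two
    transition states; the per-state dissociation constants give the
    modulator's affinity for reactant, intermediate and product.
    """

    a: float
    b: float
    c: float
    d: float
    alpha1: float = 0.5
    alpha2: float = 0.5
    kd_reactant: float = 1.0e-6
    kd_intermediate: float = 5.0e-6
    kd_product: float = 1.0e-5

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate {name} must be positive")
        for name in ("kd_reactant", "kd_intermediate", "kd_product"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def intermediate_lifetime(self) -> float:
        """Mean lifetime of the intermediate, 1/(b + c), in seconds."""
        return 1.0 / (self.b + self.c)

    @property
    def equilibrium_constant(self) -> float:
        return (self.a * self.c) / (self.b * self.d)


@dataclass(frozen=True)
class CompositeRates:
    """Effective single-barrier rates of a composite reaction, +/- modulator."""

    k_fw: float
    k_bw: float
    k_fw_mod: float
    k_bw_mod: float
    method: str
    warnings: tuple[str, ...] = ()


def _qss_rates(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    # quasi-steady-state elimination of the intermediate
    return a * c / (b + c), d * b / (b + c)


def _eigen_rates(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    # dominant-relaxation reduction: the slowest nonzero eigenvalue of the
    # 3-state generator is the observable relaxation rate k_fw + k_bw; the
    # equilibrium constant splits it into the two unidirectional rates
    gen = np.array(
        [[-a, b, 0.0], [a, -(b + c), d], [0.0, c, -d]]
    )
    eig = np.linalg.eigvals(gen)
    nonzero = sorted(abs(e.real) for e in eig if abs(e) > 1.0e-12 * max(a, b, c, d))
    lam = nonzero[0]
    keq = (a * c) / (b * d)
    return lam * keq / (1.0 + keq), lam / (1.0 + keq)


def composite_reduce(
    cr: CompositeReaction,
    conc: float,
    ctx: ThermoContext = ThermoContext(),
    method: str = "qss",
) -> CompositeRates:
    """Effective composite rates with and without the modulator.

    Both elementary steps are LFER-transformed with their own alpha and the
    per-state dissociation constants; the modulated composite is reduced the
    same way as the free one.  The composite equilibrium ratio shifts exactly
    by the product/reactant stabilization ratio, independent of alpha1,
    alpha2 and the intermediate K_D.  A warning is recorded when the
    intermediate is not fast relative to the composite rates (QSS dubious).
    """
    if method not in ("qss", "eigen"):
        raise ValueError("method must be 'qss' or 'eigen'")
    reduce_fn = _qss_rates if method == "qss" else _eigen_rates
    k_fw, k_bw = reduce_fn(cr.a, cr.b, cr.c, cr.d)

    step1 = lfer_apply(
        ElementaryReaction(cr.a, cr.b, cr.alpha1),
        ModulatorBinding(cr.kd_reactant, cr.kd_intermediate, conc),
        ctx,
    )
    step2 = lfer_apply(
        ElementaryReaction(cr.c, cr.d, cr.alpha2),
        ModulatorBinding(cr.kd_intermediate, cr.kd_product, conc),
        ctx,
    )
    k_fw_mod, k_bw_mod = reduce_fn(
        step1.k_fw_new, step1.k_bw_new, step2.k_fw_new, step2.k_bw_new
    )
    warnings = []
    if cr.b + cr.c < 100.0 * max(k_fw, k_bw, k_fw_mod, k_bw_mod):
        warnings.append(
            "intermediate is not short-lived relative to the composite rates; "
            "the quasi-steady-state reduction may be inaccurate"
        )
    return CompositeRates(
        k_fw=k_fw,
        k_bw=k_bw,
        k_fw_mod=k_fw_mod,
        k_bw_mod=k_bw_mod,
        method=method,
        warnings=tuple(warnings),
    )


def alpha_app(
    cr: CompositeReaction,
    conc: float,
    ctx: ThermoContext = ThermoContext(),
    method: str = "qss",
    direction: str = "forward",
) -> float:
    """Apparent alpha of the composite reaction seen as a single barrier.

    The observable quantities are the composite rate with and without the
    modulator and the modulator's affinities for the two stable ground
    states.  The transition-state shift is recovered from the rate change
    (ddG_ts = ddG_R - RT*ln(k_fw'/k_fw), or equivalently from the backward
    rate) and inverted through the LFER; detailed balance guarantees that the
    forward- and backward-derived values agree.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    rates = composite_reduce(cr, conc, ctx, method=method)
    ddG_r = stabilization_energy(cr.kd_reactant, conc, ctx)
    ddG_p = stabilization_energy(cr.kd_product, conc, ctx)
    if direction == "forward":
        ddG_ts = ddG_r - ctx.rt * math.log(rates.k_fw_mod / rates.k_fw)
    else:
        ddG_ts = ddG_p - ctx.rt * math.log(rates.k_bw_mod / rates.k_bw)
    return extract_alpha(ddG_ts, ddG_r, ddG_p)
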