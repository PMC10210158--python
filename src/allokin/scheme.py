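"""Transport-cycle reaction networks and thermodynamic consistency checks.

The central object is an 8-state, two-loop kinetic scheme of a sodium-coupled
transporter.  The front loop is the modulator-free transport cycle

    To -> ToNaS -> TiNaS -> Ti -> To

(outward-facing empty carrier binds Na+ and substrate, translocates, releases
inside, and returns empty), and the rear loop is its modulator-bound mirror
(ToM -> ToNaSM -> TiNaSM -> TiM -> ToM), connected to the front loop by four
modulator binding/unbinding edges.  The cycle is biased forward by an
inwardly-directed Na+ gradient (internal Na+ and substrate set to zero).

Every closed loop of rate constants must satisfy detailed balance
(microscopic reversibility): the product of rates around the loop in one
direction equals the product in the other.  ``check_detailed_balance``
verifies this on a cycle basis of the reaction graph, which suffices for all
cycles.

Two preset builders cover the two pharmacological scenarios:

* ``build_positive_scheme`` — the modulator binds the empty outward-facing
  state (To) with the highest affinity, accelerating the rate-limiting
  return step (Ti -> To, 2 s^-1) in the rear loop by up to the selectivity
  ratio; the split between forward acceleration and backward deceleration is
  set by the LFER position alpha through the factor X = selectivity^(alpha-1).
* ``build_negative_scheme`` — the modulator binds the substrate-loaded
  outward-facing state (ToNaS) with the highest affinity, slowing the
  substrate translocation step (base 100 s^-1) in the rear loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "STATE_NAMES",
    "StateSpec",
    "Concentrations",
    "DirectedRate",
    "TransportCycleScheme",
    "DetailedBalanceReport",
    "build_positive_scheme",
    "build_negative_scheme",
    "positive_cycle",
    "negative_cycle",
    "alpha_to_x",
    "x_to_alpha",
    "check_detailed_balance",
    "cap_second_step",
]

#: canonical ordering of the 8 states (front loop first, then rear loop)
STATE_NAMES = ("To", "ToNaS", "TiNaS", "Ti", "ToM", "ToNaSM", "TiNaSM", "TiM")

# diffusion-limited lumped on-rate for Na+/substrate co-binding, M^-2 s^-1
_CO_BINDING_ON = 1.0e16
# intracellular release of Na+ and substrate, s^-1
_RELEASE = 1.0e12
# substrate translocation in the reference (positive-modulator) cycle, s^-1
_TRANSLOCATION = 1.0e6
# empty-carrier return step, s^-1 — the rate-limiting reaction
_RETURN = 2.0
# modulator association rate constant, M^-1 s^-1
_MOD_ON = 1.0e6


@dataclass(frozen=True)
class StateSpec:
    """One conformational/liganded state of the carrier."""

    name: str
    facing: str  # "outward" or "inward"
    substrate_bound: bool
    modulator_bound: bool

    def __post_init__(self) -> None:
        if self.facing not in ("outward", "inward"):
            raise ValueError(f"facing must be 'outward' or 'inward', got {self.facing!r}")


def _default_states() -> tuple[StateSpec, ...]:
    specs = []
    for name in STATE_NAMES:
        specs.append(
            StateSpec(
                name=name,
                facing="outward" if name.startswith("To") else "inward",
                substrate_bound="NaS" in name,
                modulator_bound=name.endswith("M"),
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class Concentrations:
    """Ion, substrate and modulator concentrations (molar).

    Defaults bias the cycle forward: 150 mM external Na+, 1 mM external
    substrate, nothing inside, no modulator.
    """

    na_out: float = 0.15
    s_out: float = 1.0e-3
    na_in: float = 0.0
    s_in: float = 0.0
    modulator: float = 0.0

    def __post_init__(self) -> None:
        for name in ("na_out", "s_out", "na_in", "s_in", "modulator"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "na_out": self.na_out,
            "s_out": self.s_out,
            "na_in": self.na_in,
            "s_in": self.s_in,
            "modulator": self.modulator,
        }


@dataclass(frozen=True)
class DirectedRate:
    """A directed edge of the network: base constant times concentration factors.

    ``base_constant`` is the printed rate constant; the effective first-order
    rate (s^-1) is the base constant multiplied by the named concentrations
    (e.g. a lumped co-binding step carries factors ("na_out", "s_out")).
    """

    from_state: str
    to_state: str
    base_constant: float
    concentration_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.base_constant < 0:
            raise ValueError("base_constant must be non-negative")
        valid = {"na_out", "s_out", "na_in", "s_in", "modulator"}
        unknown = set(self.concentration_factors) - valid
        if unknown:
            raise ValueError(f"unknown concentration factors: {sorted(unknown)}")

    def effective(self, conc: Concentrations) -> float:
        rate = self.base_constant
        values = conc.as_dict()
        for factor in self.concentration_factors:
            rate *= values[factor]
        return rate


@dataclass(frozen=True)
class TransportCycleScheme:
    """A reaction network with its concentrations and scenario metadata."""

    states: tuple[StateSpec, ...]
    rates: tuple[DirectedRate, ...]
    concentrations: Concentrations
    x_factor: float = 1.0
    modulator_mode: str = "positive"
    temperature: float = 293.15

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        known = set(names)
        for r in self.rates:
            if r.from_state not in known or r.to_state not in known:
                raise ValueError(f"rate references unknown state: {r}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def rate_between(self, from_state: str, to_state: str) -> DirectedRate | None:
        for r in self.rates:
            if r.from_state == from_state and r.to_state == to_state:
                return r
        return None

    def effective_rate(self, from_state: str, to_state: str) -> float:
        r = self.rate_between(from_state, to_state)
        return 0.0 if r is None else r.effective(self.concentrations)

    def with_modulator(self, conc: float) -> "TransportCycleScheme":
        """Copy of the scheme at a different modulator concentration."""
        return replace(self, concentrations=replace(self.concentrations, modulator=conc))

    def with_concentrations(self, conc: Concentrations) -> "TransportCycleScheme":
        return replace(self, concentrations=conc)

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        return {
            "states": [
                {
                    "name": s.name,
                    "facing": s.facing,
                    "substrate_bound": s.substrate_bound,
                    "modulator_bound": s.modulator_bound,
                }
                for s in self.states
            ],
            "rates": [
                {
                    "from": r.from_state,
                    "to": r.to_state,
                    "constant": r.base_constant,
                    "factors": list(r.concentration_factors),
                }
                for r in self.rates
            ],
            "concentrations": self.concentrations.as_dict(),
            "x_factor": self.x_factor,
            "modulator_mode": self.modulator_mode,
            "temperature": self.temperature,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TransportCycleScheme":
        states = tuple(
            StateSpec(
                name=s["name"],
                facing=s["facing"],
                substrate_bound=bool(s["substrate_bound"]),
                modulator_bound=bool(s["modulator_bound"]),
            )
            for s in data["states"]
        )
        rates = tuple(
            DirectedRate(
                from_state=r["from"],
                to_state=r["to"],
                base_constant=float(r["constant"]),
                concentration_factors=tuple(r.get("factors", ())),
            )
            for r in data["rates"]
        )
        return cls(
            states=states,
            rates=rates,
            concentrations=Concentrations(**data["concentrations"]),
            x_factor=float(data.get("x_factor", 1.0)),
            modulator_mode=data.get("modulator_mode", "positive"),
            temperature=float(data.get("temperature", 293.15)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "TransportCycleScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def alpha_to_x(alpha: float, selectivity: float = 10.0) -> float:
    """Map the LFER position alpha to the rear-loop adjustment factor X.

    X = selectivity^(alpha - 1): the modulator-bound return step runs at
    forward rate 2*selectivity*X = 2*selectivity^alpha and backward rate
    2*X = 2*selectivity^(alpha-1), so alpha = 1 accelerates only the forward
    direction (X = 1) and alpha = 0 leaves it untouched (X = 1/selectivity).
    """
    return float(selectivity) ** (alpha - 1.0)


def x_to_alpha(x: float, selectivity: float = 10.0) -> float:
    """Inverse of :func:`alpha_to_x`."""
    if x <= 0:
        raise ValueError("x must be positive")
    return 1.0 + math.log(x) / math.log(selectivity)


def build_positive_scheme(
    x_factor: float = 1.0,
    conc: Concentrations | None = None,
    selectivity: float = 10.0,
) -> TransportCycleScheme:
    """Two-loop cycle for a positive allosteric modulator.

    The modulator binds the empty outward-facing state To with K_D = 1 uM
    (off-rate 1 s^-1 at on-rate 1e6 M^-1 s^-1), the empty inward-facing
    state Ti with K_D = selectivity uM — so ``selectivity`` is the OF/IF
    affinity ratio across the rate-limiting return step — and the
    substrate-loaded states with K_D = 10 uM (off-rate 10 s^-1).  In the
    rear loop the return step TiM -> ToM runs at 2*selectivity*X s^-1
    against 2*X s^-1 backward; the remaining rear rates are completed so
    that every loop satisfies detailed balance (hence the counter-clockwise
    release step ToNaSM -> ToM at 1e13 s^-1 and the rear re-binding step
    TiM -> TiNaSM scaled by selectivity/10).
    """
    if not x_factor > 0:
        raise ValueError("x_factor must be positive")
    if not selectivity >= 1:
        raise ValueError("selectivity must be >= 1")
    if conc is None:
        conc = Concentrations()
    s = float(selectivity)
    x = float(x_factor)
    rates = (
        # front loop, clockwise
        DirectedRate("To", "ToNaS", _CO_BINDING_ON, ("na_out", "s_out")),
        DirectedRate("ToNaS", "TiNaS", _TRANSLOCATION),
        DirectedRate("TiNaS", "Ti", _RELEASE),
        DirectedRate("Ti", "To", _RETURN),
        # front loop, counter-clockwise
        DirectedRate("To", "Ti", _RETURN),
        DirectedRate("Ti", "TiNaS", _CO_BINDING_ON, ("na_in", "s_in")),
        DirectedRate("TiNaS", "ToNaS", _TRANSLOCATION),
        DirectedRate("ToNaS", "To", _RELEASE),
        # rear loop, clockwise
        DirectedRate("ToM", "ToNaSM", _CO_BINDING_ON, ("na_out", "s_out")),
        DirectedRate("ToNaSM", "TiNaSM", _TRANSLOCATION),
        DirectedRate("TiNaSM", "TiM", _RELEASE),
        DirectedRate("TiM", "ToM", _RETURN * s * x),
        # rear loop, counter-clockwise
        DirectedRate("ToM", "TiM", _RETURN * x),
        DirectedRate("TiM", "TiNaSM", _CO_BINDING_ON * s / 10.0, ("na_in", "s_in")),
        DirectedRate("TiNaSM", "ToNaSM", _TRANSLOCATION),
        DirectedRate("ToNaSM", "ToM", _RELEASE * 10.0),
        # modulator binding (on-rates) and unbinding (off-rates)
        DirectedRate("To", "ToM", _MOD_ON, ("modulator",)),
        DirectedRate("ToM", "To", 1.0),  # K_D = 1 uM, the high-affinity state
        DirectedRate("ToNaS", "ToNaSM", _MOD_ON, ("modulator",)),
        DirectedRate("ToNaSM", "ToNaS", 10.0),  # K_D = 10 uM
        DirectedRate("TiNaS", "TiNaSM", _MOD_ON, ("modulator",)),
        DirectedRate("TiNaSM", "TiNaS", 10.0),
        DirectedRate("Ti", "TiM", _MOD_ON, ("modulator",)),
        DirectedRate("TiM", "Ti", s),  # K_D = selectivity uM, low affinity
    )
    return TransportCycleScheme(
        states=_default_states(),
        rates=rates,
        concentrations=conc,
        x_factor=x,
        modulator_mode="positive",
    )


def build_negative_scheme(
    selectivity: float = 10.0,
    alpha: float = 1.0,
    conc: Concentrations | None = None,
    base_translocation: float = 100.0,
) -> TransportCycleScheme:
    """Two-loop cycle for a negative allosteric modulator.

    The modulator binds the substrate-loaded outward-facing state ToNaS with
    K_D = 1 uM and every other state with K_D = selectivity uM, so in the
    rear loop only the substrate translocation step (base 100 s^-1) is
    modified: forward rate base*selectivity^(-alpha), backward rate
    base*selectivity^(1-alpha), per the LFER at saturation.  The rate-limiting
    return step (2 s^-1) is untouched; binding edges are completed so that
    every loop satisfies detailed balance.
    """
    if not selectivity >= 1:
        raise ValueError("selectivity must be >= 1")
    if not base_translocation > 0:
        raise ValueError("base_translocation must be positive")
    if conc is None:
        conc = Concentrations()
    s = float(selectivity)
    base = float(base_translocation)
    k_fw_mod = base * s ** (-alpha)
    k_bw_mod = base * s ** (1.0 - alpha)
    rates = (
        # front loop, clockwise
        DirectedRate("To", "ToNaS", _CO_BINDING_ON, ("na_out", "s_out")),
        DirectedRate("ToNaS", "TiNaS", base),
        DirectedRate("TiNaS", "Ti", _RELEASE),
        DirectedRate("Ti", "To", _RETURN),
        # front loop, counter-clockwise
        DirectedRate("To", "Ti", _RETURN),
        DirectedRate("Ti", "TiNaS", _CO_BINDING_ON, ("na_in", "s_in")),
        DirectedRate("TiNaS", "ToNaS", base),
        DirectedRate("ToNaS", "To", _RELEASE),
        # rear loop, clockwise
        DirectedRate("ToM", "ToNaSM", _CO_BINDING_ON, ("na_out", "s_out")),
        DirectedRate("ToNaSM", "TiNaSM", k_fw_mod),
        DirectedRate("TiNaSM", "TiM", _RELEASE),
        DirectedRate("TiM", "ToM", _RETURN),
        # rear loop, counter-clockwise
        DirectedRate("ToM", "TiM", _RETURN),
        DirectedRate("TiM", "TiNaSM", _CO_BINDING_ON, ("na_in", "s_in")),
        DirectedRate("TiNaSM", "ToNaSM", k_bw_mod),
        DirectedRate("ToNaSM", "ToM", _RELEASE / s),
        # modulator binding and unbinding
        DirectedRate("To", "ToM", _MOD_ON, ("modulator",)),
        DirectedRate("ToM", "To", s),  # K_D = selectivity uM
        DirectedRate("ToNaS", "ToNaSM", _MOD_ON, ("modulator",)),
        DirectedRate("ToNaSM", "ToNaS", 1.0),  # K_D = 1 uM, high affinity
        DirectedRate("TiNaS", "TiNaSM", _MOD_ON, ("modulator",)),
        DirectedRate("TiNaSM", "TiNaS", s),
        DirectedRate("Ti", "TiM", _MOD_ON, ("modulator",)),
        DirectedRate("TiM", "Ti", s),
    )
    scheme = TransportCycleScheme(
        states=_default_states(),
        rates=rates,
        concentrations=conc,
        x_factor=s ** (alpha - 1.0),
        modulator_mode="negative",
    )
    report = check_detailed_balance(scheme)
    if not report.passed:  # pragma: no cover - construction bug guard
        raise RuntimeError(
            f"negative scheme violates detailed balance:\n{report.loops}"
        )
    return scheme


def positive_cycle(
    alpha: float, modulator_conc: float, selectivity: float = 10.0
) -> TransportCycleScheme:
    """Positive-modulator preset parameterized by alpha instead of X."""
    conc = Concentrations(modulator=modulator_conc)
    return build_positive_scheme(
        x_factor=alpha_to_x(alpha, selectivity), conc=conc, selectivity=selectivity
    )


def negative_cycle(
    alpha: float,
    modulator_conc: float,
    selectivity: float = 10.0,
    base_translocation: float = 100.0,
) -> TransportCycleScheme:
    """Negative-modulator preset at a given modulator concentration."""
    conc = Concentrations(modulator=modulator_conc)
    return build_negative_scheme(
        selectivity=selectivity,
        alpha=alpha,
        conc=conc,
        base_translocation=base_translocation,
    )


@dataclass(frozen=True)
class DetailedBalanceReport:
    """Per-loop forward/backward rate products and the overall verdict."""

    loops: pd.DataFrame
    passed: bool
    tolerance: float


def check_detailed_balance(
    scheme: TransportCycleScheme, tolerance: float = 1.0e-6
) -> DetailedBalanceReport:
    """Verify microscopic reversibility on a cycle basis of the reaction graph.

    All concentration factors are evaluated at a common reference value of
    1 M so that only the thermodynamic consistency of the rate constants is
    tested, not the kinetic bias imposed by the gradients.  Detailed balance
    on a cycle basis implies it on every cycle of the graph.

    Raises ``ValueError`` naming the orphan edge if any directed rate lacks a
    reverse partner.
    """
    ref = Concentrations(na_out=1.0, s_out=1.0, na_in=1.0, s_in=1.0, modulator=1.0)
    lookup: dict[tuple[str, str], float] = {}
    for r in scheme.rates:
        lookup[(r.from_state, r.to_state)] = r.effective(ref)
    for (a, b) in list(lookup):
        if (b, a) not in lookup:
            raise ValueError(f"rate {a} -> {b} has no reverse partner")

    graph = nx.Graph()
    graph.add_nodes_from(scheme.state_names)
    graph.add_edges_from(lookup)
    rows = []
    all_pass = True
    for cycle in nx.cycle_basis(graph):
        fwd = 1.0
        bwd = 1.0
        n = len(cycle)
        for i in range(n):
            a, b = cycle[i], cycle[(i + 1) % n]
            fwd *= lookup[(a, b)]
            bwd *= lookup[(b, a)]
        ratio = fwd / bwd
        ok = abs(ratio - 1.0) <= tolerance
        all_pass = all_pass and ok
        rows.append(
            {
                "loop": "-".join(cycle),
                "forward_product": fwd,
                "backward_product": bwd,
                "ratio": ratio,
                "passed": ok,
            }
        )
    return DetailedBalanceReport(
        loops=pd.DataFrame(rows), passed=all_pass, tolerance=tolerance
    )


def cap_second_step(
    scheme: TransportCycleScheme, cap: float = 20.0
) -> TransportCycleScheme:
    """Slow the lumped fast step so a second reaction becomes rate-limiting.

    Replaces the substrate-translocation forward rate in both loops by
    ``cap`` (s^-1), scaling the reverse rate of each edge to preserve its
    equilibrium constant and therefore detailed balance.  Modulator binding
    edges are untouched.  ``cap = inf`` returns the scheme unchanged.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    if math.isinf(cap):
        return scheme
    targets = {("ToNaS", "TiNaS"), ("ToNaSM", "TiNaSM")}
    new_rates = []
    for r in scheme.rates:
        pair = (r.from_state, r.to_state)
        if pair in targets:
            new_rates.append(replace(r, base_constant=float(cap)))
        else:
            new_rates.append(r)
    # second pass: fix the reverse edges to preserve each equilibrium constant
    fixed = []
    for r in new_rates:
        pair = (r.to_state, r.from_state)
        if pair in targets:
            forward = scheme.rate_between(r.to_state, r.from_state)
            ratio = forward.base_constant / r.base_constant
            fixed.append(replace(r, base_constant=float(cap) / ratio))
        else:
            fixed.append(r)
    return replace(scheme, rates=tuple(fixed))
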