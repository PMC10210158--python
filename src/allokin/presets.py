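"""Run configurations, figure-scenario presets, and the file-writing runner.

A :class:`RunConfig` fully specifies one computation: an elementary-reaction
LFER table, a positive-modulator gain scan, a negative-modulator inhibition
scan, or a composite-reaction reduction.  ``preset(name)`` returns the
built-in scenario configurations (figure-style names fig2a…fig6 covering the
landscape, gain, inhibition and composite analyses); ``run`` executes a
configuration, writes the tidy tables and JSON summaries, and records every
output file with its checksum in a manifest, so a rerun of the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (
    CompositeReaction,
    alpha_app,
    capped_gain_scan,
    composite_reduce,
    dose_response,
    gain_vs_alpha,
    gain_vs_selectivity,
    inhibition_scan,
)
from .scheme import check_detailed_balance, negative_cycle, positive_cycle
from .thermo import (
    ElementaryReaction,
    ModulatorBinding,
    ThermoContext,
    enumerate_balanced_pairs,
)

__all__ = ["RunConfig", "preset", "preset_names", "run"]

_SCENARIOS = ("elementary", "positive", "negative", "composite")

#: modulator concentrations used by the gain-vs-alpha panels, molar
_PANEL_CONCS = (3e-6, 1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 1e-2, 1e-1, 1.0)
_ALPHA_GRID = [round(a, 10) for a in np.linspace(0.0, 1.0, 21)]
_CONC_GRID = [float(c) for c in np.logspace(-8, 0, 31)]


@dataclass
class RunConfig:
    """Everything needed to (re)run one scenario deterministically."""

    name: str
    scenario: str
    params: dict = field(default_factory=dict)
    temperature_K: float = 293.15
    seed: int = 20230505

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(
                f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}"
            )
        if not self.temperature_K > 0:
            raise ValueError("temperature_K must be positive")
        for key, value in self.params.items():
            if key.endswith(("_grid", "_list")) and len(value) == 0:
                raise ValueError(f"grid parameter {key} must be non-empty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _elementary(name, k_fw, k_bw, kd_r, kd_p, conc, alpha_grid) -> RunConfig:
    return RunConfig(
        name=name,
        scenario="elementary",
        params={
            "k_fw_per_s": k_fw,
            "k_bw_per_s": k_bw,
            "kd_reactant_M": kd_r,
            "kd_product_M": kd_p,
            "conc_M": conc,
            "alpha_grid": list(alpha_grid),
        },
    )


def _registry() -> dict[str, RunConfig]:
    uM, nM, mM = 1e-6, 1e-9, 1e-3
    fine_alpha = [round(a, 10) for a in np.linspace(-1.0, 2.0, 61)]
    reg = {
        # elementary free-energy landscapes
        "fig2a": _elementary("fig2a", 2.0, 2.0, 1 * uM, 1 * uM, mM, [0.5]),
        "fig2b": _elementary("fig2b", 2.0, 2.0, 10 * uM, 1 * uM, mM, [0.5]),
        "fig2c": _elementary("fig2c", 2.0, 2.0, 1 * uM, 10 * uM, mM, [0.5]),
        "fig2d": _elementary("fig2d", 2.0, 2.0, 10 * nM, 1 * nM, 1e-6, [0.5]),
        "fig2e": _elementary("fig2e", 2.0, 2.0, 1 * nM, 10 * nM, 1e-6, [0.5]),
        "fig3a": _elementary("fig3a", 2.0, 2.0, 10 * uM, 1 * uM, mM, [0.0]),
        "fig3b": _elementary("fig3b", 2.0, 2.0, 10 * uM, 1 * uM, mM, [1.0]),
        "fig3c": _elementary("fig3c", 2.0, 2.0, 10 * uM, 1 * uM, mM, fine_alpha),
        "fig3d": _elementary("fig3d", 2.0, 2.0, 10 * uM, 1 * uM, mM, [2.0]),
        "fig3e": _elementary("fig3e", 2.0, 2.0, 10 * uM, 1 * uM, mM, [-1.0]),
        # worked single-step examples
        "fig4a": _elementary("fig4a", 2.0, 2.0, 10 * uM, 1 * uM, mM, [0.5]),
        "fig5a": _elementary("fig5a", 100.0, 100.0, 1 * uM, 10 * uM, mM, [1.0]),
        # positive-modulator cycle scans
        "fig4b": RunConfig("fig4b", "positive", {
            "analysis": "gain_vs_alpha", "selectivity": 10.0,
            "conc_list": list(_PANEL_CONCS), "alpha_grid": _ALPHA_GRID}),
        "fig4c": RunConfig("fig4c", "positive", {
            "analysis": "gain_vs_alpha", "selectivity": 100.0,
            "conc_list": list(_PANEL_CONCS), "alpha_grid": _ALPHA_GRID}),
        "fig4d": RunConfig("fig4d", "positive", {
            "analysis": "gain_vs_alpha", "selectivity": 1000.0,
            "conc_list": list(_PANEL_CONCS), "alpha_grid": _ALPHA_GRID}),
        "fig4e": RunConfig("fig4e", "positive", {
            "analysis": "dose_response", "selectivity_list": [10.0, 100.0, 1000.0],
            "conc_grid": _CONC_GRID, "alpha": 1.0}),
        "fig4f": RunConfig("fig4f", "positive", {
            "analysis": "gain_vs_selectivity", "alpha": 0.5, "conc_M": 1e-5,
            "selectivity_grid": [float(s) for s in np.logspace(1, 4, 13)]}),
        "fig4g": RunConfig("fig4g", "positive", {
            "analysis": "gain_vs_selectivity", "alpha": 1.0, "conc_M": 1e-5,
            "selectivity_grid": [float(s) for s in np.logspace(1, 4, 13)]}),
        "fig4h": RunConfig("fig4h", "positive", {
            "analysis": "capped", "cap_per_s": 20.0,
            "selectivity_list": [10.0, 100.0, 1000.0],
            "alpha_grid": _ALPHA_GRID, "conc_M": 1.0}),
        # negative-modulator cycle scans
        "fig5b": RunConfig("fig5b", "negative", {
            "selectivity_list": [10.0], "alpha_grid": _ALPHA_GRID,
            "conc_grid": list(_PANEL_CONCS), "base_translocation_per_s": 100.0}),
        "fig5c": RunConfig("fig5c", "negative", {
            "selectivity_list": [100.0], "alpha_grid": _ALPHA_GRID,
            "conc_grid": list(_PANEL_CONCS), "base_translocation_per_s": 100.0}),
        "fig5d": RunConfig("fig5d", "negative", {
            "selectivity_list": [1000.0], "alpha_grid": _ALPHA_GRID,
            "conc_grid": list(_PANEL_CONCS), "base_translocation_per_s": 100.0}),
        "fig5e": RunConfig("fig5e", "negative", {
            "selectivity_list": [10.0, 100.0, 1000.0], "alpha_grid": [1.0],
            "conc_grid": _CONC_GRID, "base_translocation_per_s": 100.0}),
        # occluded-state composite reaction
        "fig6": RunConfig("fig6", "composite", {
            "branching_ratio": 0.5, "intermediate_lifetime_s": 1e-5,
            "composite_rate_per_s": 100.0, "alpha1": 0.5, "alpha2": 0.5,
            "kd_reactant_M": 1 * uM, "kd_intermediate_M": 5 * uM,
            "kd_product_M": 10 * uM, "conc_M": mM}),
    }
    # 5F is a renormalized replot of the 5E curves; same computation
    reg["fig5f"] = RunConfig("fig5f", "negative", dict(reg["fig5e"].params))
    return reg


def preset_names() -> list[str]:
    return sorted(_registry())


def preset(name: str) -> RunConfig:
    """Return the built-in configuration for a named scenario."""
    reg = _registry()
    if name not in reg:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(reg))}"
        )
    return reg[name]


def _composite_from_params(p: dict) -> CompositeReaction:
    # branching ratio b/(b+c) and lifetime 1/(b+c) fix the intermediate's
    # exits; the target composite rate fixes a (and d by symmetry of K=1)
    total = 1.0 / p["intermediate_lifetime_s"]
    b = p["branching_ratio"] * total
    c = total - b
    k_comp = p["composite_rate_per_s"]
    a = k_comp * (b + c) / c
    d = k_comp * (b + c) / b
    return CompositeReaction(
        a=a, b=b, c=c, d=d,
        alpha1=p["alpha1"], alpha2=p["alpha2"],
        kd_reactant=p["kd_reactant_M"],
        kd_intermediate=p["kd_intermediate_M"],
        kd_product=p["kd_product_M"],
    )


def _execute(config: RunConfig):
    """Run the configured computation; returns (table, summary dict, balance reports)."""
    p = config.params
    ctx = ThermoContext(temperature=config.temperature_K)
    balance = []
    if config.scenario == "elementary":
        rxn = ElementaryReaction(p["k_fw_per_s"], p["k_bw_per_s"])
        binding = ModulatorBinding(p["kd_reactant_M"], p["kd_product_M"], p["conc_M"])
        table = enumerate_balanced_pairs(rxn, binding, p["alpha_grid"], ctx)
        summary = {
            "base_k_fw_per_s": rxn.k_fw,
            "base_k_bw_per_s": rxn.k_bw,
            "selectivity": binding.selectivity,
            "equilibrium_shift": float(
                (table["k_fw"] / table["k_bw"]).iloc[0] / rxn.equilibrium_constant
            ),
        }
    elif config.scenario == "positive":
        kind = p["analysis"]
        if kind == "gain_vs_alpha":
            res = gain_vs_alpha(p["selectivity"], p["conc_list"], p["alpha_grid"])
            table, summary = res.table, {
                "ec50": res.ec50.to_dict("records"), "warnings": list(res.warnings)}
        elif kind == "dose_response":
            res = dose_response(p["selectivity_list"], p["conc_grid"], p["alpha"])
            table, summary = res.table, {
                "ec50": res.ec50.to_dict("records"), "warnings": list(res.warnings)}
        elif kind == "gain_vs_selectivity":
            table = gain_vs_selectivity(p["alpha"], p["conc_M"], p["selectivity_grid"])
            summary = {"max_gain": float(table["gain"].max())}
        elif kind == "capped":
            res = capped_gain_scan(
                p["cap_per_s"], p["selectivity_list"], p["alpha_grid"], p["conc_M"])
            table, summary = res.table, {"cap_per_s": p["cap_per_s"]}
        else:
            raise ValueError(f"unknown positive analysis {kind!r}")
        sel = p.get("selectivity", (p.get("selectivity_list") or [10.0])[0])
        balance.append(check_detailed_balance(positive_cycle(0.5, 1e-3, sel)))
    elif config.scenario == "negative":
        res = inhibition_scan(
            p["selectivity_list"], p["alpha_grid"], p["conc_grid"],
            p["base_translocation_per_s"])
        table = res.table
        summary = {
            "ic50_and_residuals": res.ic50.to_dict("records"),
            "warnings": list(res.warnings),
        }
        balance.append(
            check_detailed_balance(
                negative_cycle(1.0, 1e-3, p["selectivity_list"][0],
                               p["base_translocation_per_s"])))
    else:  # composite
        cr = _composite_from_params(p)
        rates = composite_reduce(cr, p["conc_M"], ctx)
        table = None
        summary = {
            "elementary_rates_per_s": {"a": cr.a, "b": cr.b, "c": cr.c, "d": cr.d},
            "intermediate_lifetime_s": cr.intermediate_lifetime,
            "composite_k_fw_per_s": rates.k_fw,
            "composite_k_bw_per_s": rates.k_bw,
            "modulated_k_fw_per_s": rates.k_fw_mod,
            "modulated_k_bw_per_s": rates.k_bw_mod,
            "alpha_app": alpha_app(cr, p["conc_M"], ctx),
            "warnings": list(rates.warnings),
        }
    return table, summary, balance


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, outdir, fmt: str = "csv") -> dict:
    """Execute a configuration and write its tables, summary and manifest.

    Returns the manifest dict (also written as ``manifest.json``), which
    records the configuration, package version, detailed-balance verdicts of
    every scheme built, and a sha256 checksum per output file.
    """
    if fmt not in ("csv", "tsv"):
        raise ValueError("fmt must be 'csv' or 'tsv'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, summary, balance = _execute(config)
    sep = "," if fmt == "csv" else "\t"
    files = []
    if table is not None:
        tpath = outdir / f"{config.name}_table.{fmt}"
        table.to_csv(tpath, sep=sep, index=False)
        files.append(tpath)
    spath = outdir / f"{config.name}_summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    files.append(spath)
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "detailed_balance_passed": [bool(b.passed) for b in balance],
        "files": {f.name: _sha256(f) for f in files},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
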