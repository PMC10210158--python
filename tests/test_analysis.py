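"""Gain/inhibition scans, EC50/IC50 extraction, and composite-reaction reduction."""

import math

import numpy as np
import pytest

from allokin.analysis import (
    CompositeReaction,
    alpha_app,
    capped_gain_scan,
    composite_reduce,
    dose_response,
    gain_vs_alpha,
    gain_vs_selectivity,
    inhibition_scan,
)
from allokin.thermo import ThermoContext, stabilization_energy

CONCS = (3e-6, 1e-5, 1e-4, 1e-3, 1e-1, 1.0)
ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)


@pytest.fixture(scope="module")
def tenfold_scan():
    return gain_vs_alpha(10.0, CONCS, ALPHAS)


@pytest.fixture(scope="module")
def curves():
    return dose_response((10.0, 100.0, 1000.0), np.logspace(-8, 0, 25), alpha=1.0)


@pytest.fixture(scope="module")
def scan():
    return inhibition_scan((10.0, 100.0, 1000.0), (0.5, 1.0), np.logspace(-8, 0, 17))


class TestGainVsAlpha:
    def test_alpha_zero_gain_is_unity_at_all_concentrations(self, tenfold_scan):
        rows = tenfold_scan.table.query("alpha == 0.0")
        assert np.allclose(rows["gain"], 1.0, atol=1e-3)

    def test_gain_monotone_in_alpha_at_saturation(self, tenfold_scan):
        sat = tenfold_scan.table.query("conc_M == 1.0").sort_values("alpha")
        assert sat["gain"].is_monotonic_increasing

    def test_maximum_gain_equals_selectivity(self, tenfold_scan):
        assert tenfold_scan.table["gain"].max() == pytest.approx(10.0, rel=0.01)

    def test_gain_bounded_by_selectivity_everywhere(self, tenfold_scan):
        assert (tenfold_scan.table["gain"] <= 10.0 * (1 + 1e-6)).all()

    def test_unit_selectivity_gives_flat_unity_gain(self):
        res = gain_vs_alpha(1.0, (1e-5, 1e-3, 1.0), ALPHAS)
        assert np.allclose(res.table["gain"], 1.0, atol=1e-3)

    def test_gains_positive_everywhere(self, tenfold_scan):
        assert (tenfold_scan.table["gain"] > 0).all()


class TestDoseResponse:
    def test_ec50_right_shifts_with_selectivity(self, curves):
        ec50 = curves.ec50.set_index("selectivity")["ec50_M"]
        assert ec50[10.0] < ec50[100.0] < ec50[1000.0]

    def test_normalized_gain_saturates_at_one(self, curves):
        top = curves.table.query("conc_M == 1.0")
        assert np.allclose(top["normalized_gain"], 1.0, atol=1e-6)

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError):
            dose_response((10.0,), np.logspace(-4, -2, 5), alpha=1.0)

    def test_over_selective_modulator_less_effective_at_low_concentration(self):
        # 10 uM of drug, alpha = 0.5: the 10-fold-selective ligand beats the
        # 10,000-fold-selective one
        table = gain_vs_selectivity(0.5, 1e-5, (10.0, 10000.0))
        gains = table.set_index("selectivity")["gain"]
        assert gains[10.0] > gains[10000.0]


class TestGainVsSelectivity:
    def test_bell_shape_at_sub_saturating_concentration(self):
        # alpha = 0.5, 10 uM: rises, peaks, falls
        table = gain_vs_selectivity(0.5, 1e-5, np.logspace(1, 4, 13))
        g = table["gain"].to_numpy()
        peak = g.argmax()
        assert 0 < peak < len(g) - 1
        assert g[peak] > g[0] and g[peak] > g[-1]

    def test_saturating_concentration_gain_approaches_selectivity(self):
        table = gain_vs_selectivity(1.0, 1.0, (10.0, 100.0))
        gains = table.set_index("selectivity")["gain"]
        assert gains[10.0] == pytest.approx(10.0, rel=0.01)
        assert gains[100.0] == pytest.approx(100.0, rel=0.01)

    def test_unit_selectivity_gain_is_unity(self):
        table = gain_vs_selectivity(1.0, 1e-3, (1.0,))
        assert table["gain"].iloc[0] == pytest.approx(1.0, abs=1e-3)


class TestCappedGain:
    def test_gain_flattens_across_selectivities(self):
        res = capped_gain_scan(20.0, (10.0, 100.0, 1000.0), (1.0,), conc=1.0)
        gains = res.table["gain"]
        # uncapped the same selectivities span ~100x; capped they are within ~1.5x
        assert gains.max() / gains.min() < 1.5

    def test_bounded_by_two_slow_step_harmonic_limit(self):
        res = capped_gain_scan(20.0, (10.0, 1000.0), (0.0, 0.5, 1.0), conc=1.0)
        # baseline ~ 1/(1/2 + 1/20); modulated turnover cannot exceed
        # 1/(1/20 + 1/20) = 10 s^-1
        bound = 10.0 / (1.0 / (1.0 / 2.0 + 1.0 / 20.0))
        assert (res.table["gain"] <= bound * (1 + 1e-6)).all()

    def test_cap_of_two_limits_gain_to_two(self):
        res = capped_gain_scan(2.0, (10.0, 1000.0), (1.0,), conc=1.0)
        assert (res.table["gain"] <= 2.0 + 1e-6).all()

    def test_infinite_cap_recovers_uncapped_gain(self):
        capped = capped_gain_scan(math.inf, (10.0,), (1.0,), conc=1.0)
        plain = gain_vs_alpha(10.0, (1.0,), (1.0,))
        assert capped.table["gain"].iloc[0] == pytest.approx(
            plain.table["gain"].iloc[0], rel=1e-9
        )


class TestInhibitionScan:
    def test_no_modulator_means_no_inhibition(self, scan):
        low = scan.table.query("conc_M == 1e-8")
        assert np.allclose(low["normalized_uptake"], 1.0, atol=1e-3)

    def test_uptake_non_increasing_in_concentration(self, scan):
        for (_, _), grp in scan.table.groupby(["alpha", "selectivity"]):
            u = grp.sort_values("conc_M")["normalized_uptake"].to_numpy()
            assert (np.diff(u) <= 1e-9).all()

    def test_normalized_uptake_in_unit_interval(self, scan):
        u = scan.table["normalized_uptake"]
        assert (u > 0).all() and (u <= 1.0 + 1e-9).all()

    def test_tenfold_selective_inhibits_only_modestly(self, scan):
        # 100 -> ~10 s^-1 translocation still beats the 2 s^-1 return step
        row = scan.ic50.query("alpha == 1.0 and selectivity == 10.0")
        assert float(row["residual_uptake"].iloc[0]) > 0.7

    def test_residual_uptake_positive_and_decreasing_with_selectivity(self, scan):
        res = scan.ic50.query("alpha == 1.0").set_index("selectivity")[
            "residual_uptake"
        ]
        assert (res > 0).all()
        assert res[10.0] > res[100.0] > res[1000.0]

    def test_ic50_right_shifts_modestly_with_selectivity(self, scan):
        ic50 = scan.ic50.query("alpha == 1.0").set_index("selectivity")["ic50_M"]
        assert ic50[10.0] < ic50[100.0] < ic50[1000.0]
        # modest: well under two decades across a 100-fold selectivity range
        assert ic50[1000.0] / ic50[10.0] < 100.0


class TestCompositeReduction:
    def test_committed_intermediate_recovers_first_step_rate(self):
        cr = CompositeReaction(a=50.0, b=1e-2, c=1e5, d=40.0)
        rates = composite_reduce(cr, 0.0)
        assert rates.k_fw == pytest.approx(50.0, rel=1e-6)

    def test_lifetime_property(self):
        cr = CompositeReaction(a=200.0, b=5e4, c=5e4, d=200.0)
        assert cr.intermediate_lifetime == pytest.approx(1e-5, rel=1e-12)

    def test_qss_matches_eigenvalue_reduction_for_fast_intermediate(self):
        # 10 us intermediate, composite rates ~100 s^-1: the reductions agree
        cr = CompositeReaction(a=200.0, b=5e4, c=5e4, d=200.0)
        for conc in (0.0, 1e-3):
            q = composite_reduce(cr, conc, method="qss")
            e = composite_reduce(cr, conc, method="eigen")
            assert q.k_fw_mod == pytest.approx(e.k_fw_mod, rel=0.01)
            assert q.k_bw_mod == pytest.approx(e.k_bw_mod, rel=0.01)

    def test_slow_intermediate_triggers_warning(self):
        cr = CompositeReaction(a=200.0, b=300.0, c=300.0, d=200.0)
        rates = composite_reduce(cr, 1e-3)
        assert rates.warnings

    def test_equilibrium_shift_is_reactant_product_stabilization_ratio(self):
        rng = np.random.default_rng(20230505)
        ctx = ThermoContext()
        for _ in range(50):
            cr = CompositeReaction(
                a=10.0 ** rng.uniform(1, 3), b=10.0 ** rng.uniform(4, 6),
                c=10.0 ** rng.uniform(4, 6), d=10.0 ** rng.uniform(1, 3),
                alpha1=rng.uniform(0, 1), alpha2=rng.uniform(0, 1),
                kd_reactant=10.0 ** rng.uniform(-7, -5),
                kd_intermediate=10.0 ** rng.uniform(-7, -5),
                kd_product=10.0 ** rng.uniform(-7, -5),
            )
            conc = 10.0 ** rng.uniform(-5, -2)
            r = composite_reduce(cr, conc, ctx)
            shift = (r.k_fw_mod / r.k_bw_mod) / (r.k_fw / r.k_bw)
            s_r = math.exp(-stabilization_energy(cr.kd_reactant, conc, ctx) / ctx.rt)
            s_p = math.exp(-stabilization_energy(cr.kd_product, conc, ctx) / ctx.rt)
            assert shift == pytest.approx(s_p / s_r, rel=1e-9)


class TestAlphaApp:
    def test_forward_and_backward_derivations_agree(self):
        rng = np.random.default_rng(20230505)
        for _ in range(300):
            cr = CompositeReaction(
                a=10.0 ** rng.uniform(1, 3), b=10.0 ** rng.uniform(4, 6),
                c=10.0 ** rng.uniform(4, 6), d=10.0 ** rng.uniform(1, 3),
                alpha1=rng.uniform(0, 1), alpha2=rng.uniform(0, 1),
                kd_reactant=1e-6, kd_intermediate=5e-6, kd_product=1e-5,
            )
            conc = 10.0 ** rng.uniform(-5, -2)
            fwd = alpha_app(cr, conc, direction="forward")
            bwd = alpha_app(cr, conc, direction="backward")
            assert fwd == pytest.approx(bwd, abs=1e-9)

    def test_degenerate_composite_reduces_to_elementary_alpha(self):
        # the intermediate is a product clone (same KD) reached almost
        # irreversibly, so only the first barrier matters
        cr = CompositeReaction(a=100.0, b=0.1, c=1e5, d=100.0,
                               alpha1=0.3, alpha2=0.9,
                               kd_reactant=1e-6, kd_intermediate=1e-5,
                               kd_product=1e-5)
        assert alpha_app(cr, 1e-3) == pytest.approx(0.3, abs=1e-2)

    def test_reference_occluded_state_value_lies_in_branching_envelope(self):
        # KDs (1, 5, 10) uM, alpha1 = alpha2 = 0.5, 10 us lifetime: the
        # apparent alpha at branching 0.5 sits strictly inside the envelope
        # swept by the intermediate branching ratio
        total = 1e5
        values = []
        for frac in np.linspace(0.01, 0.99, 49):
            b = frac * total
            c = total - b
            cr = CompositeReaction(a=100.0 * total / c, b=b, c=c,
                                   d=100.0 * total / b)
            values.append(alpha_app(cr, 1e-3))
        mid = alpha_app(
            CompositeReaction(a=200.0, b=5e4, c=5e4, d=200.0), 1e-3
        )
        assert min(values) < mid < max(values)

    def test_extreme_alphas_recovered_when_intermediate_matches_a_ground_state(self):
        # alpha1 = alpha2 = 1 with KD(I) = KD(P): both barriers track the
        # product, so the composite does too; mirror case for alpha = 0
        product_like = CompositeReaction(a=200.0, b=5e4, c=5e4, d=200.0,
                                         alpha1=1.0, alpha2=1.0,
                                         kd_reactant=1e-6, kd_intermediate=1e-5,
                                         kd_product=1e-5)
        assert alpha_app(product_like, 1e-3) == pytest.approx(1.0, abs=1e-9)
        reactant_like = CompositeReaction(a=200.0, b=5e4, c=5e4, d=200.0,
                                          alpha1=0.0, alpha2=0.0,
                                          kd_reactant=1e-6, kd_intermediate=1e-6,
                                          kd_product=1e-5)
        assert alpha_app(reactant_like, 1e-3) == pytest.approx(0.0, abs=1e-9)
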