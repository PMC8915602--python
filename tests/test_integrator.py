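"""Tests for the RK4 stepper, RHS assembly and full simulation invariants."""

import math

import numpy as np
import pytest

import mmplug
from mmplug import IntegratorConfig, Scenario, mass_balance, preset, simulate
from mmplug.integrator import InstabilityError, assemble_rhs, rk4_step
from mmplug.scenarios import REFERENCE_DRUG, REFERENCE_PK, build_plug


class TestRK4Step:
    def test_exponential_decay_oracle(self):
        # dy/dt = -y over one 0.001-min step: RK4 matches e^-h to ~1e-15
        y1 = rk4_step(1.0, 0.0, 0.001, lambda y, t: -y)
        assert y1 == pytest.approx(math.exp(-0.001), abs=1e-15)

    def test_zero_rhs_leaves_state_unchanged(self):
        y = np.array([1.0, 2.0, 3.0])
        out = rk4_step(y, 0.0, 0.5, lambda y, t: np.zeros_like(y))
        assert np.array_equal(out, y)

    def test_exact_for_constant_rhs(self):
        c = np.array([0.25, -0.0])
        out = rk4_step(np.array([1.0, 1.0]), 0.0, 0.1, lambda y, t: c)
        assert out[0] == pytest.approx(1.025, abs=1e-16)

    def test_tiny_negative_clamped_large_negative_raises(self):
        out = rk4_step(np.array([1e-10]), 0.0, 1.0, lambda y, t: np.array([-2e-10]))
        assert out[0] == 0.0
        with pytest.raises(InstabilityError):
            rk4_step(np.array([0.0]), 0.0, 1.0, lambda y, t: np.array([-1.0]))

    def test_nonfinite_derivative_reported_with_time(self):
        with pytest.raises(mmplug.NumericalError) as err:
            rk4_step(np.array([1.0]), 3.0, 1.0, lambda y, t: np.array([np.nan]))
        assert err.value.t == 4.0


class TestAssembleRHS:
    def test_plug_independence(self):
        scn = preset("figure2")
        rhs, layout = assemble_rhs(scn.plugs, scn.drug, scn.pk)
        y = mmplug.SystemState.from_plugs(scn.plugs).to_vector()
        y[layout.n_fractions : 2 * layout.n_fractions] = 0.3  # some dissolved drug
        base = rhs(y, 20.0)

        doubled = preset("figure2")
        doubled.plugs[0].fractions[0].x0 *= 2
        doubled.plugs[0].fractions[0].xs *= 2
        rhs2, _ = assemble_rhs(doubled.plugs, doubled.drug, doubled.pk)
        y2 = mmplug.SystemState.from_plugs(doubled.plugs).to_vector()
        y2[layout.n_fractions : 2 * layout.n_fractions] = 0.3
        other = rhs2(y2, 20.0)
        # plugs 2 and 3 see identical derivatives whatever plug 1 carries
        nf = layout.n_fractions
        for blk in range(4):
            assert np.array_equal(base[blk * nf + 1 : blk * nf + 3], other[blk * nf + 1 : blk * nf + 3])

    def test_only_first_plug_transitioning_at_onset(self):
        scn = preset("figure2")
        kas = [p.ka.evaluate(0.5) for p in scn.plugs]
        assert kas[0] > 0.0 and kas[1] == 0.0 and kas[2] == 0.0

    def test_saturated_plug_without_absorption_is_stationary(self):
        # all mass dissolved, Xd/V = Cs, ka = 0: nothing moves
        plug = build_plug(1, volume=80.0, dose=0.8, onset=None, ka_si=0.0, predissolved=True)
        scn = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=[plug], label="eq")
        rhs, _ = assemble_rhs(scn.plugs, scn.drug, scn.pk)
        y = mmplug.SystemState.from_plugs(scn.plugs).to_vector()
        assert np.all(rhs(y, 10.0) == 0.0)

    def test_dimension_mismatch_rejected(self):
        scn = preset("figure2")
        rhs, layout = assemble_rhs(scn.plugs, scn.drug, scn.pk)
        with pytest.raises(ValueError):
            rhs(np.zeros(layout.n_states + 1), 0.0)


class TestSimulate:
    def test_engines_agree(self):
        cfg_c = IntegratorConfig(duration=3.0, output_interval=0.5)
        cfg_p = IntegratorConfig(duration=3.0, output_interval=0.5, engine="python")
        rc = simulate(preset("figure2"), cfg_c)
        rp = simulate(preset("figure2"), cfg_p)
        assert np.allclose(rc.cp_total, rp.cp_total, rtol=1e-12, atol=1e-20)
        assert np.allclose(rc.xs_per_plug, rp.xs_per_plug, rtol=1e-12, atol=1e-15)
        assert np.allclose(rc.eliminated, rp.eliminated, rtol=1e-12, atol=1e-20)

    def test_total_is_fixed_order_sum_of_plugs(self, fig2_result):
        total = fig2_result.cp_per_plug.sum(axis=0)
        assert np.array_equal(total, fig2_result.cp_total)

    def test_mass_conserved_from_start(self, fig2_result):
        mb = mass_balance(fig2_result)
        assert mb.residuals[0] == pytest.approx(0.0, abs=1e-15)
        assert mb.max_abs_residual < 1e-6 * fig2_result.total_dose

    def test_recorded_states_non_negative(self, fig2_result):
        for arr in (
            fig2_result.xs_per_plug,
            fig2_result.xd_per_plug,
            fig2_result.xp_per_plug,
            fig2_result.xt_per_plug,
        ):
            assert arr.min() >= 0.0

    def test_partial_final_step_included_and_noted(self):
        cfg = IntegratorConfig(duration=1.0005, output_interval=0.5)
        res = simulate(preset("figure2"), cfg)
        assert res.times[-1] == pytest.approx(1.0005, abs=1e-12)
        assert any("partial step" in w for w in res.warnings)

    def test_plug_permutation_leaves_total_unchanged(self):
        scn = preset("figure2")
        cfg = IntegratorConfig(duration=40.0, output_interval=0.5)
        base = simulate(scn, cfg)
        permuted = preset("figure2")
        # relabel so construction order differs from index order
        permuted.plugs = [permuted.plugs[2], permuted.plugs[0], permuted.plugs[1]]
        again = simulate(permuted, cfg)
        assert np.array_equal(base.cp_total, again.cp_total)

    def test_superposition_of_identical_plugs(self):
        # n identical plugs of dose/n behave as one plug of the full dose
        cfg = IntegratorConfig(duration=60.0, output_interval=0.5)
        plugs3 = [build_plug(j + 1, volume=80.0, dose=0.8, onset=0.0) for j in range(3)]
        s3 = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=plugs3, label="3x")
        s1 = Scenario(
            drug=REFERENCE_DRUG,
            pk=REFERENCE_PK,
            plugs=[build_plug(1, volume=240.0, dose=2.4, onset=0.0)],
            label="1x",
        )
        r3, r1 = simulate(s3, cfg), simulate(s1, cfg)
        scale = r1.cp_total.max()
        assert np.abs(r3.cp_total - r1.cp_total).max() / scale < 1e-9

    def test_long_run_asymptote_dose_in_ledgers(self, bateman_result):
        # open system: eventually everything is eliminated or first-pass lost
        end = bateman_result.eliminated[-1] + bateman_result.firstpass[-1]
        assert end == pytest.approx(bateman_result.total_dose, rel=1e-6)

    def test_instability_threshold_enforced(self):
        # an absurdly tight threshold must trip on the extinction overshoot
        cfg = IntegratorConfig(duration=5.0, output_interval=0.5, sink=True,
                               instability_threshold=1e-12)
        plug = build_plug(1, volume=80.0, dose=0.8, onset=None, ka_si=0.0)
        scn = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=[plug], label="tight")
        with pytest.raises(InstabilityError):
            simulate(scn, cfg)
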