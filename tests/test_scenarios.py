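"""Tests for presets, config parsing, size grouping, plug grouping, sampling."""

import textwrap

import numpy as np
import pytest

import mmplug
from mmplug import (
    EmptyingDistribution,
    IntegratorConfig,
    Scenario,
    build_size_fractions,
    group_plugs,
    load_scenario,
    preset,
    sample_emptying,
    simulate,
)
from mmplug.scenarios import REFERENCE_DRUG, REFERENCE_PK, ScenarioError, build_plug


class TestPresets:
    def test_three_plug_preset_matches_published_layout(self):
        scn = preset("figure2")
        assert len(scn.plugs) == 3
        assert scn.total_dose == pytest.approx(2.4)
        assert scn.total_volume == pytest.approx(240.0)
        assert [p.onset for p in scn.plugs] == [0.0, 15.0, 30.0]
        assert all(p.volume(0.0) == pytest.approx(80.0) for p in scn.plugs)
        assert all(p.fractions[0].r0 == pytest.approx(1e-4) for p in scn.plugs)
        assert all(p.transition == 1.0 for p in scn.plugs)
        assert all(p.ka.final_value == pytest.approx(0.07) for p in scn.plugs)

    def test_large_particle_preset_uses_10um_radius(self):
        scn = preset("figure3")
        assert all(p.fractions[0].r0 == pytest.approx(10e-4) for p in scn.plugs)

    def test_empty_first_plug_preset(self):
        scn = preset("figure4")
        assert scn.plugs[0].dose == 0.0
        assert scn.plugs[1].dose == pytest.approx(1.2)
        assert scn.plugs[2].dose == pytest.approx(1.2)
        assert scn.total_dose == pytest.approx(2.4)

    def test_single_plug_reference(self):
        scn = preset("figure5_single")
        assert len(scn.plugs) == 1
        assert scn.plugs[0].volume(0.0) == pytest.approx(240.0)
        assert scn.plugs[0].dose == pytest.approx(2.4)
        assert scn.plugs[0].onset == 0.0

    def test_seven_plug_even_split(self):
        scn = preset("figure6_seven")
        assert len(scn.plugs) == 7
        assert [p.onset for p in scn.plugs] == [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
        assert all(p.volume(0.0) == pytest.approx(240.0 / 7) for p in scn.plugs)
        assert all(p.dose == pytest.approx(2.4 / 7) for p in scn.plugs)

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ScenarioError, match="figure2"):
            preset("figure99")


VALID_CONFIG = textwrap.dedent(
    """
    schema_version: 1
    label: demo
    drug:
      solubility_mg_per_ml: 0.01
      density_mg_per_cm3: 1300.0
      diffusion_coefficient_cm2_per_min: 3.0e-4
    pk:
      clearance_ml_per_min_per_kg: 4.0
      volume_of_distribution_ml_per_kg: 600.0
      body_mass_kg: 70.0
      k12_per_min: 0.03
      k21_per_min: 0.01
    absorption:
      ka_intestine_per_min: 0.07
      bioavailability_factor: 0.5
    totals:
      volume_ml: 240.0
      dose_mg: 2.4
    integrator:
      step_min: 0.001
      duration_min: 720.0
      output_interval_min: 0.5
    plugs:
      - {onset_min: 0.0, transition_min: 1.0, volume_ml: 80.0, dose_mg: 0.8, particle_radius_um: 1.0}
      - {onset_min: 15.0, transition_min: 1.0, volume_ml: 80.0, dose_mg: 0.8, particle_radius_um: 1.0}
      - {onset_min: 30.0, transition_min: 1.0, volume_ml: 80.0, dose_mg: 0.8, particle_radius_um: 1.0}
    """
)


class TestLoadScenario:
    def test_valid_file_reproduces_preset(self, tmp_path):
        path = tmp_path / "demo.yaml"
        path.write_text(VALID_CONFIG)
        scn = load_scenario(path)
        ref = preset("figure2")
        assert len(scn.plugs) == 3
        assert [p.onset for p in scn.plugs] == [p.onset for p in ref.plugs]
        assert scn.total_dose == pytest.approx(ref.total_dose)
        assert scn.integrator.duration == 720.0
        # and it simulates identically to the preset
        cfg = IntegratorConfig(duration=30.0, output_interval=0.5)
        assert np.array_equal(
            simulate(scn, cfg).cp_total, simulate(ref, cfg).cp_total
        )

    def test_volume_mismatch_names_key(self, tmp_path):
        bad = VALID_CONFIG.replace("volume_ml: 240.0", "volume_ml: 230.0")
        path = tmp_path / "bad.yaml"
        path.write_text(bad)
        with pytest.raises(ScenarioError, match="totals.volume_ml"):
            load_scenario(path)

    def test_zero_plugs_rejected(self, tmp_path):
        lines = VALID_CONFIG.splitlines()
        head = "\n".join(l for l in lines if not l.strip().startswith("- {") and "plugs:" not in l)
        path = tmp_path / "empty.yaml"
        path.write_text(head + "\nplugs: []\n")
        with pytest.raises(ScenarioError, match="plugs"):
            load_scenario(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "unk.yaml"
        path.write_text(VALID_CONFIG + "\nbogus_section: 1\n")
        with pytest.raises(ScenarioError, match="bogus_section"):
            load_scenario(path)

    def test_nonpositive_parameter_rejected(self, tmp_path):
        bad = VALID_CONFIG.replace("density_mg_per_cm3: 1300.0", "density_mg_per_cm3: -5")
        path = tmp_path / "neg.yaml"
        path.write_text(bad)
        with pytest.raises(ScenarioError, match="density_mg_per_cm3"):
            load_scenario(path)

    def test_diameter_interpretation_halves_radius(self, tmp_path):
        cfg = VALID_CONFIG + "\noptions:\n  particle_size_interpretation: diameter\n"
        path = tmp_path / "diam.yaml"
        path.write_text(cfg)
        scn = load_scenario(path)
        assert scn.plugs[0].fractions[0].r0 == pytest.approx(0.5e-4)


class TestSizeFractions:
    def test_monodisperse_identity(self):
        fracs = build_size_fractions([(1e-4, 1.0)], 0.8, 1)
        assert len(fracs) == 1
        assert fracs[0].r0 == pytest.approx(1e-4)
        assert fracs[0].x0 == pytest.approx(0.8)

    def test_two_sizes_grouped_to_mass_weighted_mean(self):
        fracs = build_size_fractions([(1e-4, 0.5), (3e-4, 0.5)], 1.0, 1)
        assert len(fracs) == 1
        assert fracs[0].r0 == pytest.approx(2e-4)
        assert fracs[0].x0 == pytest.approx(1.0)

    def test_group_masses_sum_to_dose_exactly(self):
        rng = np.random.default_rng(0)
        radii = np.sort(rng.lognormal(np.log(2e-4), 0.4, size=10))
        weights = rng.dirichlet(np.ones(10))
        dist = list(zip(radii, weights / weights.sum()))
        for n in (1, 3, 10):
            fracs = build_size_fractions(dist, 0.8, n)
            assert sum(f.x0 for f in fracs) == 0.8  # exact, largest remainder
            assert len(fracs) == n

    def test_empty_distribution_rejected(self):
        with pytest.raises(ScenarioError):
            build_size_fractions([], 0.8, 1)

    def test_grouping_preserves_simulated_profile(self):
        # a 10-point polydisperse powder grouped into 3 representative bins
        # must simulate close to the ungrouped powder
        rng = np.random.default_rng(7)
        radii = np.sort(rng.lognormal(np.log(3e-4), 0.35, size=10))
        weights = rng.dirichlet(2.0 * np.ones(10))
        dist = [(float(r), float(w / weights.sum())) for r, w in zip(radii, weights)]
        cfg = IntegratorConfig(duration=240.0, output_interval=0.5)
        results = {}
        for n in (3, 10):
            plug = build_plug(
                1, volume=240.0, dose=2.4, onset=0.0,
                fractions=build_size_fractions(dist, 2.4, n),
            )
            scn = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=[plug], label=f"g{n}")
            results[n] = simulate(scn, cfg)
        cmax = results[10].cp_total.max()
        delta = np.abs(results[3].cp_total - results[10].cp_total).max()
        assert delta / cmax < 0.05


class TestGroupPlugs:
    def test_distant_onsets_left_alone(self):
        plugs = preset("figure2").plugs
        out = group_plugs(plugs, window=5.0)
        assert len(out) == 3
        assert [p.onset for p in out] == [0.0, 15.0, 30.0]

    def test_seven_to_three(self):
        out = group_plugs(preset("figure6_seven").plugs, window=12.0)
        assert len(out) == 3
        # dose-weighted mean onsets of {0,5,10}, {15,20}, {25,30}
        assert [p.onset for p in out] == pytest.approx([5.0, 17.5, 27.5])
        assert sum(p.dose for p in out) == pytest.approx(2.4)
        assert sum(p.volume(0.0) for p in out) == pytest.approx(240.0)

    def test_identical_onsets_merge_to_equivalent_plug(self):
        cfg = IntegratorConfig(duration=60.0, output_interval=0.5)
        pair = [build_plug(j + 1, volume=80.0, dose=0.8, onset=10.0) for j in range(2)]
        merged = group_plugs(pair, window=1.0)
        assert len(merged) == 1
        assert merged[0].dose == pytest.approx(1.6)
        s_pair = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=pair, label="pair")
        s_one = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=merged, label="one")
        r_pair, r_one = simulate(s_pair, cfg), simulate(s_one, cfg)
        scale = r_pair.cp_total.max()
        assert np.abs(r_pair.cp_total - r_one.cp_total).max() / scale < 1e-9

    def test_zero_dose_window_uses_volume_weighting(self):
        plugs = [
            build_plug(1, volume=60.0, dose=0.0, onset=0.0),
            build_plug(2, volume=20.0, dose=0.0, onset=8.0),
        ]
        out = group_plugs(plugs, window=10.0)
        assert len(out) == 1
        assert out[0].onset == pytest.approx((0.0 * 60 + 8.0 * 20) / 80.0)


class TestSampleEmptying:
    DIST = EmptyingDistribution()

    def test_same_seed_bit_identical(self):
        a = sample_emptying(self.DIST, 240.0, 2.4, seed=42)
        b = sample_emptying(self.DIST, 240.0, 2.4, seed=42)
        assert len(a.plugs) == len(b.plugs)
        for pa, pb in zip(a.plugs, b.plugs):
            assert pa.onset == pb.onset
            assert pa.volume(0.0) == pb.volume(0.0)
            assert pa.dose == pb.dose

    def test_closure_and_sorted_onsets(self):
        for seed in range(10):
            scn = sample_emptying(self.DIST, 240.0, 2.4, seed=seed)
            assert sum(p.volume(0.0) for p in scn.plugs) == pytest.approx(240.0, abs=1e-12)
            assert sum(p.dose for p in scn.plugs) == pytest.approx(2.4, abs=1e-12)
            onsets = [p.onset for p in scn.plugs]
            assert onsets == sorted(onsets)

    def test_degenerate_distribution_reproduces_even_split(self):
        dist = EmptyingDistribution(
            n_plugs=3, fixed_onsets=(0.0, 15.0, 30.0),
            volume_mode="equal", dose_mode="equal",
        )
        scn = sample_emptying(dist, 240.0, 2.4, seed=1)
        ref = preset("figure2")
        assert [p.onset for p in scn.plugs] == [p.onset for p in ref.plugs]
        assert [p.volume(0.0) for p in scn.plugs] == pytest.approx(
            [p.volume(0.0) for p in ref.plugs]
        )
        assert [p.dose for p in scn.plugs] == pytest.approx([p.dose for p in ref.plugs])

    def test_invalid_fixed_onsets_length(self):
        dist = EmptyingDistribution(n_plugs=3, fixed_onsets=(0.0, 15.0))
        with pytest.raises(ScenarioError):
            sample_emptying(dist, 240.0, 2.4, seed=1)
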