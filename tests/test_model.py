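"""Model schema, validation, scaling and state layout."""

from types import SimpleNamespace

import numpy as np
import pytest

from morphsim import Morphology, assemble_state, unpack_state
from morphsim.deskmodel import desk_mirror_maps
from morphsim.geometry import AnalyticGeometry
from morphsim.model import (
    ModelError,
    apply_segment_scaling,
    build_scaled_model,
    compute_anthropometrics,
    load_model_definition,
    save_model_definition,
    scale_muscle_parameters,
)


class TestSchema:
    def test_yaml_round_trip(self, desk_model, tmp_path):
        path = tmp_path / "desk.yaml"
        save_model_definition(desk_model, path)
        loaded = load_model_definition(path)
        assert [s.name for s in loaded.segments] == [s.name for s in desk_model.segments]
        revolute = [j.name for j in loaded.joints if j.type == "revolute"]
        assert sorted(revolute) == sorted(
            f"{j}_{s}" for j in ("hip", "knee", "ankle") for s in ("r", "l"))
        for a, b in zip(loaded.muscles, desk_model.muscles):
            assert a.name == b.name
            assert a.l_t_slack == pytest.approx(b.l_t_slack, abs=1e-12)

    def test_invariant_violation_names_location(self, desk_model, tmp_path):
        path = tmp_path / "bad.yaml"
        save_model_definition(desk_model, path)
        text = path.read_text().replace(
            f"pcsa: {desk_model.muscles[0].pcsa}", "pcsa: 0.0", 1)
        path.write_text(text)
        with pytest.raises(ModelError, match="hip_flexor_r"):
            load_model_definition(path)

    def test_dangling_reference_rejected(self, desk_model, tmp_path):
        path = tmp_path / "dangling.yaml"
        save_model_definition(desk_model, path)
        path.write_text(path.read_text().replace("segment: foot_r", "segment: foot_x"))
        with pytest.raises(ModelError, match="dangling"):
            load_model_definition(path)

    def test_full_configuration_layout(self, full_model, tmp_path):
        assert len(full_model.segments) == 18
        assert full_model.n_coordinates == 31
        assert full_model.n_muscles == 92
        assert full_model.n_torque_actuators == 8
        assert full_model.state_size == 254
        for side in "rl":
            n_sph = sum(len(full_model.segment(f"{seg}_{side}").contact_sphere_ids)
                        for seg in ("talus", "midhindfoot", "toes"))
            assert n_sph == 8
        path = tmp_path / "full.yaml"
        save_model_definition(full_model, path)
        assert load_model_definition(path).state_size == 254


class TestScaling:
    def test_identity_scaling_bitwise(self, desk_model, generic, desk_geo):
        scaled = build_scaled_model(desk_model, generic, desk_geo.lmt_anatomical)
        for i, s in enumerate(desk_model.segments):
            assert scaled.seg_mass[i] == s.mass
            assert tuple(scaled.seg_com[i]) == s.com
            assert scaled.seg_inertia[i] == s.inertia[2]
        for sm, m in zip(scaled.muscles, desk_model.muscles):
            assert sm.f_max_iso == pytest.approx(m.f_max_iso, rel=1e-15)
            assert sm.l_m_opt == pytest.approx(m.l_m_opt, rel=1e-15)
            assert sm.l_t_slack == pytest.approx(m.l_t_slack, rel=1e-15)
            assert sm.volume == pytest.approx(m.volume, rel=1e-15)

    def test_constant_density_mass_product(self, desk_model, generic):
        generic.p_s["thigh"] = np.array([1.1, 1.1, 1.1])
        scaled = apply_segment_scaling(desk_model, generic)
        i = [s.name for s in desk_model.segments].index("thigh_r")
        assert scaled.seg_mass[i] == pytest.approx(9.3 * 1.331, rel=1e-12)

    def test_per_axis_com_scaling(self, desk_model, generic):
        generic.p_s["foot"] = np.array([1.2, 1.0, 1.0])
        scaled = apply_segment_scaling(desk_model, generic)
        i = [s.name for s in desk_model.segments].index("foot_r")
        com = desk_model.segments[i].com
        assert scaled.seg_com[i][0] == pytest.approx(com[0] * 1.2)
        assert scaled.seg_com[i][1] == pytest.approx(com[1])

    def test_mass_conservation(self, desk_model, desk_geo):
        rng = np.random.default_rng(4)
        for _ in range(3):
            morph = Morphology(
                p_s={g: rng.uniform(0.8, 1.2, 3) for g in desk_model.scaling_groups()},
                p_v=np.ones(desk_model.n_muscles))
            scaled = apply_segment_scaling(desk_model, morph)
            assert scaled.total_mass == pytest.approx(np.sum(scaled.seg_mass), rel=1e-14)

    def test_volume_factor_monotone_and_local(self, desk_model, generic, desk_geo):
        base = scale_muscle_parameters(desk_model, generic, desk_geo.lmt_anatomical)
        bumped = generic.copy()
        bumped.p_v[3] = 1.2
        new = scale_muscle_parameters(desk_model, bumped, desk_geo.lmt_anatomical)
        assert new[3].f_max_iso > base[3].f_max_iso
        assert new[3].volume == pytest.approx(base[3].volume * 1.2, rel=1e-12)
        assert new[3].l_m_opt == pytest.approx(base[3].l_m_opt, rel=1e-14)
        for k in range(len(base)):
            if k != 3:
                assert new[k].f_max_iso == pytest.approx(base[k].f_max_iso, rel=1e-14)

    def test_mirrored_morphology_mirrors_muscles(self, desk_model, desk_geo):
        mperm, _, _ = desk_mirror_maps(desk_model)
        rng = np.random.default_rng(7)
        pv = rng.uniform(1.0, 1.2, desk_model.n_muscles)
        morph = Morphology(
            p_s={g: np.ones(3) for g in desk_model.scaling_groups()}, p_v=pv)
        mirrored = Morphology(
            p_s={g: np.ones(3) for g in desk_model.scaling_groups()}, p_v=pv[mperm])
        a = scale_muscle_parameters(desk_model, morph, desk_geo.lmt_anatomical)
        b = scale_muscle_parameters(desk_model, mirrored, desk_geo.lmt_anatomical)
        for i in range(desk_model.n_muscles):
            assert a[i].f_max_iso == pytest.approx(b[mperm[i]].f_max_iso, rel=1e-14)


class TestAnthropometrics:
    def test_generic_desk_values(self, desk_model, generic, desk_geo):
        scaled = build_scaled_model(desk_model, generic, desk_geo.lmt_anatomical)
        mass, stature, bmi = compute_anthropometrics(scaled)
        assert mass == pytest.approx(75.2, abs=1e-9)
        assert stature == pytest.approx(1.81, abs=1e-9)
        assert bmi == pytest.approx(75.2 / 1.81**2, rel=1e-12)
        assert bmi == pytest.approx(22.95, abs=0.01)

    @pytest.mark.parametrize("mass,stature,expected", [
        (75.2, 1.81, 22.95), (54.2, 1.76, 17.5)])
    def test_bmi_arithmetic(self, mass, stature, expected):
        stub = SimpleNamespace(seg_mass=np.array([mass]), stature=stature)
        m, s, bmi = compute_anthropometrics(stub)
        assert bmi == pytest.approx(expected, abs=0.05)

    def test_bmi_linear_in_mass(self, desk_model, generic, desk_geo):
        scaled = build_scaled_model(desk_model, generic, desk_geo.lmt_anatomical)
        _, _, bmi = compute_anthropometrics(scaled)
        scaled.seg_mass = scaled.seg_mass * 2.0
        _, _, bmi2 = compute_anthropometrics(scaled)
        assert bmi2 == pytest.approx(2.0 * bmi, rel=1e-12)


class TestStateLayout:
    def test_desk_state_length(self, desk_model):
        x = assemble_state(desk_model, np.zeros(18), np.zeros(0), np.zeros(18),
                           np.zeros(9), np.zeros(9))
        assert x.shape == (54,)

    def test_full_state_length(self, full_model):
        x = assemble_state(full_model, np.zeros(92), np.zeros(8), np.zeros(92),
                           np.zeros(31), np.zeros(31))
        assert x.shape == (254,)

    def test_pack_unpack_round_trip(self, desk_model):
        rng = np.random.default_rng(0)
        parts = (rng.random(18), np.zeros(0), rng.random(18), rng.random(9), rng.random(9))
        x = assemble_state(desk_model, *parts)
        back = unpack_state(desk_model, x)
        for a, b in zip(parts, back):
            np.testing.assert_array_equal(a, b)

    def test_length_mismatch_rejected(self, desk_model):
        with pytest.raises(ModelError, match="length"):
            assemble_state(desk_model, np.zeros(17), np.zeros(0), np.zeros(18),
                           np.zeros(9), np.zeros(9))
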