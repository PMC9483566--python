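import numpy as np
import pytest

from tdhdx.arrhenius import R_KCAL
from tdhdx.synthetic import (
    SimConfig,
    SyntheticModel,
    arrhenius_rate,
    default_scenario,
    generate_uptake,
)


class TestArrheniusRate:
    def test_identity_at_reference_temperature(self):
        assert arrhenius_rate(0.5, 12.3, 298.15, 298.15) == pytest.approx(0.5)

    def test_zero_barrier_is_temperature_independent(self):
        for t in (283.15, 298.15, 313.15):
            assert arrhenius_rate(0.5, 0.0, t, 298.15) == pytest.approx(0.5)

    def test_two_point_closed_form_round_trip(self):
        # Ea that exactly doubles the rate from 283.15 K to 313.15 K:
        # Ea = R ln 2 / (1/283.15 - 1/313.15) ~ 4.07 kcal/mol
        t_a, t_b = 283.15, 313.15
        ea = R_KCAL * np.log(2.0) / (1.0 / t_a - 1.0 / t_b)
        assert ea == pytest.approx(4.07, abs=0.01)
        assert arrhenius_rate(0.1, ea, t_b, t_a) == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(k_ref=0.0), dict(t_k=-1.0), dict(t_ref_k=0.0)])
    def test_nonpositive_inputs_rejected(self, kwargs):
        args = dict(k_ref=0.5, ea=5.0, t_k=298.15, t_ref_k=298.15)
        args.update(kwargs)
        with pytest.raises(ValueError):
            arrhenius_rate(args["k_ref"], args["ea"], args["t_k"], args["t_ref_k"])


@pytest.fixture(scope="module")
def noise_free():
    model, config = default_scenario(seed=0, noise_sd=0.0, states=("WT-apo", "F61A-apo"))
    curves, truth = generate_uptake(model, config)
    return model, config, curves, truth


class TestGenerateUptake:
    def test_time_zero_is_always_zero(self, noise_free):
        _, _, curves, _ = noise_free
        for c in curves:
            assert c.deuterons[0] == 0.0

    def test_mass_conservation(self, noise_free):
        model, _, curves, _ = noise_free
        n_t = {p.peptide_id: p.n_t for p in model.peptides}
        for c in curves:
            assert np.all(c.deuterons >= 0.0)
            assert np.all(c.deuterons <= n_t[c.peptide_id])

    def test_monotone_in_time_without_noise(self, noise_free):
        _, _, curves, _ = noise_free
        for c in curves:
            assert np.all(np.diff(c.deuterons) >= -1e-12)

    def test_monotone_in_temperature_without_noise(self, noise_free):
        _, _, curves, _ = noise_free
        by_key = {}
        for c in curves:
            by_key.setdefault((c.peptide_id, c.state, c.replicate), []).append(c)
        for grp in by_key.values():
            grp.sort(key=lambda c: c.temperature_c)
            for cold, warm in zip(grp, grp[1:]):
                assert np.all(warm.deuterons - cold.deuterons >= -1e-9)

    def test_long_time_plateau_approaches_exchangeable_pool(self):
        model, config = default_scenario(seed=0, noise_sd=0.0, states=("WT-apo",))
        # extend the grid far beyond 10 / k3 so all exchange completes
        config = SimConfig(
            states=("WT-apo",), temperatures_c=(25.0,),
            times_s=tuple([0] + [int(6e5 * i) for i in range(1, 9)]), n_replicates=1,
        )
        curves, _ = generate_uptake(model, config)
        for c in curves:
            pep = next(p for p in model.peptides if p.peptide_id == c.peptide_id)
            kin = model.kinetics[c.peptide_id]
            expected = (1 - pep.f_be) * (pep.n_t - kin.n_ne)
            assert c.deuterons[-1] == pytest.approx(expected, rel=1e-3)

    def test_same_seed_reproduces_identical_tables(self):
        a = generate_uptake(*default_scenario(seed=42, states=("WT-apo",)))[0]
        b = generate_uptake(*default_scenario(seed=42, states=("WT-apo",)))[0]
        assert a == b

    def test_different_seed_changes_noise(self):
        a = generate_uptake(*default_scenario(seed=42, states=("WT-apo",)))[0]
        b = generate_uptake(*default_scenario(seed=43, states=("WT-apo",)))[0]
        assert a != b

    def test_state_without_offset_entry_rejected(self):
        model, config = default_scenario(seed=0)
        config = SimConfig(states=("WT-apo", "not-a-state"))
        with pytest.raises(ValueError, match="not-a-state"):
            generate_uptake(model, config)

    def test_truth_table_reflects_state_offsets(self, noise_free):
        _, _, _, truth = noise_free
        wide = truth.pivot(index="peptide_id", columns="state", values="ea_true")
        off = truth.pivot(index="peptide_id", columns="state", values="ea_offset")
        # offsets shift both phase barriers equally, so the projected
        # weighted Ea difference equals the offset difference exactly
        np.testing.assert_allclose(
            wide["F61A-apo"] - wide["WT-apo"],
            off["F61A-apo"] - off["WT-apo"],
            atol=1e-9,
        )


class TestModelValidation:
    def test_amplitudes_must_sum_to_n_t(self):
        model, _ = default_scenario(seed=0)
        pid = model.peptides[0].peptide_id
        model.kinetics[pid].b += 0.5
        with pytest.raises(ValueError, match="sum"):
            SyntheticModel(
                peptides=model.peptides, kinetics=model.kinetics,
                state_offsets=model.state_offsets,
            )

    def test_default_design_matches_study(self):
        _, config = default_scenario()
        assert config.temperatures_c == (10.0, 20.0, 25.0, 30.0, 40.0)
        assert len(config.times_s) == 14
        assert config.times_s[0] == 0.0 and config.times_s[-1] == 14400.0
        assert config.n_replicates == 2

    def test_scenario_has_23_nonoverlapping_peptides(self):
        model, _ = default_scenario()
        assert len(model.peptides) == 23
        spans = sorted((p.start_res, p.end_res) for p in model.peptides)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
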