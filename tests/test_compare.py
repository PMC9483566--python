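import numpy as np
import pandas as pd
import pytest

from tdhdx.arrhenius import ArrheniusFit
from tdhdx.compare import (
    DeltaEaRecord,
    check_pair_consistency,
    classify,
    count_significant,
    delta_ea,
    single_temperature_difference,
)
from tdhdx.reference import (
    ADA_CONTROL_ELIMINATED,
    load_f61a_table,
    load_wt_ligand_table,
    records_for_pair,
)

from .conftest import make_triexp_curve


def afit(pid="46-62", state="apo", ea=5.0, se=1.0, indet=False):
    return ArrheniusFit(peptide_id=pid, state=state, ea=ea, se_ea=se, indeterminate=indet)


class TestDeltaEa:
    def test_identical_fits_give_zero(self):
        rec = delta_ea(afit(), afit())
        assert rec.delta == 0.0

    def test_error_propagates_in_quadrature(self):
        rec = delta_ea(afit(se=3.0), afit(se=4.0))
        assert rec.sigma == pytest.approx(5.0)

    def test_antisymmetric_with_identical_sigma(self):
        a, b = afit(ea=3.15, se=2.0), afit(ea=6.01, se=2.0)
        fwd, rev = delta_ea(a, b), delta_ea(b, a)
        assert fwd.delta == pytest.approx(-rev.delta)
        assert fwd.sigma == pytest.approx(rev.sigma)

    def test_ligand_state_composition(self):
        # ES and ETS barriers relative to a shared apo baseline compose
        # to the ETS-ES difference: 6.01 - 3.15 = 2.86
        apo, es, ets = afit(ea=10.0), afit(ea=13.15), afit(ea=16.01)
        assert delta_ea(apo, es).delta == pytest.approx(3.15)
        assert delta_ea(apo, ets).delta == pytest.approx(6.01)
        assert delta_ea(es, ets).delta == pytest.approx(2.86)

    def test_indeterminate_propagates(self):
        rec = delta_ea(afit(indet=True), afit())
        assert rec.indeterminate

    def test_peptide_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_ea(afit(pid="46-62"), afit(pid="63-74"))


class TestClassification:
    def test_difference_beyond_sigma_is_significant(self):
        rec = DeltaEaRecord("46-62", "ETS-ES", delta=2.86, sigma=1.8)
        assert classify(rec) == "significant"

    def test_difference_within_sigma_is_not(self):
        rec = DeltaEaRecord("109-131", "ETS-ES", delta=0.26, sigma=1.0)
        assert classify(rec) == "not_significant"

    def test_elimination_overrides_significance(self):
        rec = DeltaEaRecord("201-229", "F61A-WT", delta=-6.2, sigma=1.6)
        assert classify(rec, ADA_CONTROL_ELIMINATED) == "control_eliminated"

    def test_indeterminate_flag_wins_over_magnitude(self):
        rec = DeltaEaRecord("86-97", "F61A-WT", delta=-4.0, sigma=1.0, indeterminate=True)
        assert classify(rec) == "indeterminate"

    def test_count_on_empty_list_is_zero(self):
        assert count_significant([]) == 0


class TestReferenceTables:
    def test_inhibitor_vs_substrate_analog_has_three_significant(self):
        records = records_for_pair(load_wt_ligand_table(), "ETS-ES")
        assert len(records) == 11
        assert count_significant(records) == 3
        sig = {r.peptide_id for r in records if r.classification == "significant"}
        assert sig == {"46-62", "86-97", "201-229"}

    def test_apo_network_has_seven_peptides_after_elimination(self):
        records = records_for_pair(load_f61a_table(), "F61A-WT-apo")
        assert count_significant(records, ADA_CONTROL_ELIMINATED) == 7

    def test_bound_network_has_five_peptides_after_elimination(self):
        records = records_for_pair(load_f61a_table(), "F61A-WT-ETS")
        assert count_significant(records, ADA_CONTROL_ELIMINATED) == 5

    def test_pairwise_closure_is_exact_for_all_rows(self):
        table = load_wt_ligand_table()
        resid = check_pair_consistency(table, "ES-apo", "ETS-apo", "ETS-ES")
        assert len(resid) == 11
        assert np.max(np.abs(resid.to_numpy())) < 1e-9


class TestPairConsistency:
    def test_identically_zero_for_per_state_tables(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in ("1-10", "11-20", "21-30"):
            ea = dict(zip("abc", rng.normal(10, 3, 3)))
            rows += [
                {"peptide_id": pid, "pair": "b-a", "delta": ea["b"] - ea["a"]},
                {"peptide_id": pid, "pair": "c-a", "delta": ea["c"] - ea["a"]},
                {"peptide_id": pid, "pair": "c-b", "delta": ea["c"] - ea["b"]},
            ]
        resid = check_pair_consistency(pd.DataFrame(rows), "b-a", "c-a", "c-b")
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-12)

    def test_missing_pair_rejected(self):
        df = pd.DataFrame(
            [{"peptide_id": "1-10", "pair": "b-a", "delta": 1.0}]
        )
        with pytest.raises(ValueError):
            check_pair_consistency(df, "b-a", "c-a", "c-b")


class TestSingleTemperatureDifference:
    def test_identical_states_unchanged(self, times_s):
        a = [make_triexp_curve(times_s, replicate=r) for r in (1, 2)]
        b = [make_triexp_curve(times_s, replicate=r) for r in (1, 2)]
        rec = single_temperature_difference(a, b, threshold=1.0)
        assert rec.direction == "unchanged"
        np.testing.assert_allclose(rec.differences, 0.0)

    def test_larger_nonexchanging_pool_reads_as_protected(self, times_s):
        # state B converts two slow amides to non-exchanging: plateau -2
        a = [make_triexp_curve(times_s, c=4.0)]
        b = [make_triexp_curve(times_s, c=2.0)]
        rec = single_temperature_difference(a, b, threshold=1.0)
        assert rec.direction == "protected"
        assert rec.differences[-1] == pytest.approx(-2.0, abs=0.05)

    def test_smaller_nonexchanging_pool_reads_as_deprotected(self, times_s):
        a = [make_triexp_curve(times_s, c=2.0)]
        b = [make_triexp_curve(times_s, c=4.0)]
        rec = single_temperature_difference(a, b, threshold=1.0)
        assert rec.direction == "deprotected"

    def test_mismatched_time_grids_rejected(self, times_s):
        a = [make_triexp_curve(times_s)]
        b = [make_triexp_curve(times_s[:-1])]
        with pytest.raises(ValueError, match="grids"):
            single_temperature_difference(a, b)
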