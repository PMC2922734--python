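"""Attributable fractions and the counterfactual case recursion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lagcost import (AgeGroupRecord, BASELINE_RRS_WOMEN, NORSTROM_PARAMS,
                     PopulationTable, RelativeRiskSet, ValidationError,
                     aaf_after_decline, aaf_from_prevalence, adjusted_rr,
                     build_schedule, excess_ratio_from_paf, linear_schedule,
                     run_counterfactual)


def literal_aaf(prevalences, rrs):
    """Independent oracle: the attributable-fraction formula evaluated
    literally as numerator over one-plus-denominator, category by category,
    with the abstainer remainder included explicitly."""
    names = list(prevalences)
    p_abst = 1.0 - sum(prevalences.values())
    num = sum(prevalences[n] * (rrs[n] - 1.0) for n in names)
    den = 1.0 + p_abst * (rrs["abstinence"] - 1.0) + num
    return num / den


class TestAafFromPrevalence:
    def test_matches_literal_formula(self):
        prevs = {"low": 0.5, "hazardous": 0.1, "harmful": 0.02}
        aaf = aaf_from_prevalence(prevs, BASELINE_RRS_WOMEN)
        # hand arithmetic: S = 0.5*0.3 + 0.1*8.5 + 0.02*12 = 1.24
        assert aaf == pytest.approx(1.24 / 2.24)
        assert aaf == pytest.approx(literal_aaf(prevs, BASELINE_RRS_WOMEN))

    def test_no_exposure_means_no_attribution(self):
        assert aaf_from_prevalence({}, BASELINE_RRS_WOMEN) == 0.0
        flat = RelativeRiskSet({c: 1.0 for c in ("low", "hazardous", "harmful")})
        assert aaf_from_prevalence({"low": 0.4, "harmful": 0.1}, flat) == 0.0

    def test_invalid_prevalences_rejected(self):
        with pytest.raises(ValidationError):
            aaf_from_prevalence({"low": -0.1}, BASELINE_RRS_WOMEN)
        with pytest.raises(ValidationError):
            aaf_from_prevalence({"low": 0.7, "harmful": 0.5}, BASELINE_RRS_WOMEN)

    @given(st.floats(0, 0.5), st.floats(0, 0.3), st.floats(0, 0.2),
           st.floats(1, 5), st.floats(1, 15), st.floats(1, 30))
    def test_agrees_with_literal_oracle(self, p1, p2, p3, r1, r2, r3):
        prevs = {"low": p1, "hazardous": p2, "harmful": p3}
        rrs = RelativeRiskSet({"low": r1, "hazardous": r2, "harmful": r3})
        assert aaf_from_prevalence(prevs, rrs) == pytest.approx(
            literal_aaf(prevs, rrs), abs=1e-12)


class TestExcessRatio:
    @pytest.mark.parametrize("paf,expected", [
        (0.52, 0.52 / 0.48),   # 18-29 band
        (0.44, 0.44 / 0.56),   # 50-64 band
        (0.0, 0.0),
    ])
    def test_inverts_attributable_fraction(self, paf, expected):
        assert excess_ratio_from_paf(paf) == pytest.approx(expected)

    @pytest.mark.parametrize("paf", [1.0, 1.5, -0.01])
    def test_out_of_range_rejected(self, paf):
        with pytest.raises(ValidationError):
            excess_ratio_from_paf(paf)

    @given(st.floats(0.0, 0.99))
    def test_round_trip_through_aaf(self, paf):
        S = excess_ratio_from_paf(paf)
        assert aaf_after_decline(S, 0.0) == pytest.approx(paf, abs=1e-12)


class TestAafAfterDecline:
    def test_endpoints(self):
        S = excess_ratio_from_paf(0.46)
        assert aaf_after_decline(S, 0.0) == pytest.approx(0.46)
        assert aaf_after_decline(S, 1.0) == 0.0

    @given(st.floats(0, 0.5), st.floats(0, 0.3), st.floats(0, 0.2),
           st.floats(1, 5), st.floats(1, 15), st.floats(1, 30),
           st.floats(0.0, 1.0))
    def test_equals_literal_formula_on_decayed_rrs(self, p1, p2, p3,
                                                   r1, r2, r3, c):
        """Scaling the excess ratio by (1-c) must agree with re-running the
        full attributable-fraction formula on the decayed relative risks —
        the equivalence that justifies the PAF-only input mode."""
        prevs = {"low": p1, "hazardous": p2, "harmful": p3}
        rrs = RelativeRiskSet({"low": r1, "hazardous": r2, "harmful": r3})
        S = sum(prevs[n] * (rrs[n] - 1.0) for n in prevs)
        decayed = RelativeRiskSet({n: adjusted_rr(rrs[n], c) for n in prevs})
        assert aaf_after_decline(S, c) == pytest.approx(
            aaf_from_prevalence(prevs, decayed), abs=1e-12)


def _table(records):
    return PopulationTable(sex="test", records=records)


class TestRunCounterfactual:
    def test_published_year_zero(self, women, schedule10, schedule24):
        """74 of 328 attributable cases avoided immediately; 56 under the
        24-year remaining-life schedule."""
        series = run_counterfactual(women, schedule10)
        assert round(series.avoided_total[0]) == 74
        # 902 total cases minus avoided leaves ~828 at the start of year 1
        assert round(sum(r.total_cases for r in women.records)
                     - series.avoided_total[0]) == 828
        series24 = run_counterfactual(women, schedule24)
        assert round(series24.avoided_total[0]) == 56

    def test_single_year_horizon_avoids_everything(self, women):
        series = run_counterfactual(women, linear_schedule(1))
        assert series.avoided_total[0] == pytest.approx(series.baseline_total)
        assert series.attributable_total[0] == 0.0

    def test_conservation_every_year_and_band(self, women_series10):
        total = women_series10.avoided + women_series10.attributable
        np.testing.assert_allclose(
            total, np.broadcast_to(women_series10.baseline, total.shape),
            rtol=1e-15, atol=1e-15)

    def test_terminal_year_attributable_is_zero(self, women_series10):
        assert np.all(women_series10.attributable[-1] == 0.0)

    def test_monotone_decline(self, women_series10):
        totals = women_series10.attributable_total
        assert np.all(np.diff(totals) < 0)
        assert np.all(np.diff(women_series10.avoided_total) > 0)

    def test_mode_equivalence(self, schedule10):
        """A prevalence-mode table with the same excess ratios yields the
        identical series to machine precision."""
        paf_table = _table([AgeGroupRecord("a", 100, paf=0.46),
                            AgeGroupRecord("b", 200, paf=0.20)])
        prevs = []
        for paf in (0.46, 0.20):
            S = paf / (1 - paf)
            prevs.append({"harmful": S / (BASELINE_RRS_WOMEN["harmful"] - 1)})
        prev_table = PopulationTable(
            sex="test", rrs=BASELINE_RRS_WOMEN,
            records=[AgeGroupRecord("a", 100, prevalences=prevs[0]),
                     AgeGroupRecord("b", 200, prevalences=prevs[1])])
        s1 = run_counterfactual(paf_table, schedule10)
        s2 = run_counterfactual(prev_table, schedule10)
        np.testing.assert_allclose(s1.attributable, s2.attributable,
                                   rtol=0, atol=1e-12)

    def test_scale_equivariance(self, women, schedule10):
        doubled = _table([AgeGroupRecord(r.age_band, 2 * r.total_cases, paf=r.paf)
                          for r in women.records])
        s1 = run_counterfactual(women, schedule10)
        s2 = run_counterfactual(doubled, schedule10)
        np.testing.assert_allclose(s2.attributable, 2 * s1.attributable)
        np.testing.assert_allclose(s2.avoided, 2 * s1.avoided)

    def test_to_frame_includes_baseline_row(self, women_series10):
        frame = women_series10.to_frame()
        assert frame.index[0] == -1
        assert frame.loc[-1, "cases"] == pytest.approx(330.89)
        assert frame.loc[-1, "cases_avoided"] == 0.0


class TestPopulationTable:
    def test_mixed_modes_rejected(self):
        with pytest.raises(ValidationError):
            _table([AgeGroupRecord("a", 10, paf=0.3),
                    AgeGroupRecord("b", 10, prevalences={"low": 0.1})])

    def test_duplicate_bands_rejected(self):
        with pytest.raises(ValidationError):
            _table([AgeGroupRecord("a", 10, paf=0.3),
                    AgeGroupRecord("a", 10, paf=0.2)])

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            _table([])

    def test_prevalence_mode_requires_rrs(self):
        with pytest.raises(ValidationError):
            _table([AgeGroupRecord("a", 10, prevalences={"low": 0.1})])

    def test_record_requires_exactly_one_mode(self):
        with pytest.raises(ValidationError):
            AgeGroupRecord("a", 10)
        with pytest.raises(ValidationError):
            AgeGroupRecord("a", 10, paf=0.3, prevalences={"low": 0.1})
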