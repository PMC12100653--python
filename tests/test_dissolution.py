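"""Dissolution analytics, unit bookkeeping and the Welch comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cocryscreen as cs
from cocryscreen.dissolution import analytics_table

MW_CILP = 492.5
MW_TSA = 171.2


def make_profile(times, api, cof, dose=None, volume=None):
    return cs.DissolutionProfile(
        times=np.asarray(times, float),
        conc_api=np.asarray(api, float),
        conc_coformer=np.asarray(cof, float),
        volume=volume,
        dose=dose,
    )


class TestUnitConversions:
    def test_solubility_in_micromolar(self):
        # ~30 ng/mL of a 492.5 g/mol API is 0.06 μM
        assert cs.ng_ml_to_uM(30, MW_CILP) == pytest.approx(0.06, abs=0.002)

    def test_zero(self):
        assert cs.ng_ml_to_uM(0, MW_CILP) == 0.0

    def test_unit_identity(self):
        assert cs.ng_ml_to_uM(171.2, 171.2) == pytest.approx(1.0)

    @given(c=st.floats(1e-6, 1e6), mw=st.floats(10, 2000))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip(self, c, mw):
        assert cs.uM_to_ng_ml(cs.ng_ml_to_uM(c, mw), mw) == pytest.approx(
            c, rel=1e-12
        )

    @pytest.mark.parametrize(
        "mass_mg, mw, expected_mmol",
        [
            (75, MW_CILP, 0.152),
            (500, MW_TSA, 2.92),
            (20, MW_CILP, 0.041),
        ],
    )
    def test_weighed_masses_to_millimoles(self, mass_mg, mw, expected_mmol):
        assert cs.mass_to_mmol(mass_mg, mw) == pytest.approx(expected_mmol, abs=5e-3)

    def test_equivalents(self):
        assert cs.equivalents(2.92, 0.31) == pytest.approx(9.4, abs=0.05)
        assert cs.equivalents(1.5, 1.5) == 1.0
        assert cs.equivalents(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            cs.equivalents(1.0, 0.0)


class TestDoseComposition:
    def test_reference_cocrystal_dose(self):
        dose = cs.CocrystalDose(
            total_mass=10.8, mw_api=MW_CILP, mw_coformer=MW_TSA, stoichiometry=1.0
        )
        mmol, mg_api, mg_cof = cs.dose_composition(dose)
        assert mmol == pytest.approx(0.016, abs=5e-4)
        assert mg_api == pytest.approx(8.0, abs=0.05)
        assert mg_cof == pytest.approx(2.8, abs=0.05)

    def test_degenerate_api_only(self):
        dose = cs.CocrystalDose(
            total_mass=5.0, mw_api=MW_CILP, mw_coformer=MW_TSA, stoichiometry=0.0
        )
        mmol, mg_api, mg_cof = cs.dose_composition(dose)
        assert mg_api == pytest.approx(5.0)
        assert mg_cof == 0.0

    @given(
        mass=st.floats(0.1, 1000),
        mw_api=st.floats(50, 1000),
        mw_cof=st.floats(50, 1000),
        stoich=st.floats(0, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_conservation(self, mass, mw_api, mw_cof, stoich):
        dose = cs.CocrystalDose(mass, mw_api, mw_cof, stoich)
        _, mg_api, mg_cof = cs.dose_composition(dose)
        assert mg_api + mg_cof == pytest.approx(mass, rel=1e-12)


class TestSupersaturation:
    def test_reported_blank_medium_ratio(self):
        s = cs.SolubilitySummary(mean=4.6e-2, sd=0.6e-2, n=3)
        assert cs.supersaturation_ratio(0.3, s) == pytest.approx(6.5, abs=0.05)

    def test_saturation_is_unity(self):
        s = cs.SolubilitySummary(mean=2.0, sd=0.1, n=3)
        assert cs.supersaturation_ratio(2.0, s) == 1.0

    def test_profile_peak_location(self):
        p = make_profile([5, 10, 20, 40], [0.1, 0.5, 0.3, 0.2], [1, 2, 3, 4])
        ss = cs.supersaturation_profile(p, 0.05)
        assert ss.max_ratio == pytest.approx(10.0)
        assert ss.time_of_max == 10
        assert np.allclose(ss.ratio, np.array([0.1, 0.5, 0.3, 0.2]) / 0.05)

    def test_nonpositive_solubility_rejected(self):
        with pytest.raises(ValueError):
            cs.supersaturation_ratio(1.0, 0.0)


class TestCongruency:
    def test_highly_incongruent_early_release(self):
        # coformer far in excess of API early in dissolution
        p = make_profile([5], [0.01], [3.05])
        cong = cs.congruency_ratio(p)
        assert cong.ratio[0] == pytest.approx(305.0)
        assert cong.ratio[0] > 100

    def test_congruent_profile_is_unity(self):
        p = make_profile([1, 2, 3], [0.5, 1.0, 1.5], [0.5, 1.0, 1.5])
        cong = cs.congruency_ratio(p)
        assert np.allclose(cong.ratio, 1.0)

    def test_zero_api_flagged_not_dropped(self):
        p = make_profile([1, 2], [0.0, 1.0], [0.5, 1.0])
        cong = cs.congruency_ratio(p)
        assert not cong.defined[0] and math.isnan(cong.ratio[0])
        assert cong.defined[1] and cong.ratio[1] == 1.0


class TestPercentDissolved:
    DOSE = cs.CocrystalDose(10.8, MW_CILP, MW_TSA, 1.0)

    def test_zero_concentration(self):
        p = make_profile([5], [0.0], [0.0], dose=self.DOSE, volume=80.0)
        assert cs.percent_dissolved(p)[0] == 0.0

    def test_full_dose_in_solution(self):
        _, _, mg_cof = cs.dose_composition(self.DOSE)
        conc = mg_cof / 80.0 / MW_TSA * 1e6  # mg/mL -> μM
        p = make_profile([5], [0.1], [conc], dose=self.DOSE, volume=80.0)
        assert cs.percent_dissolved(p)[0] == pytest.approx(100.0)

    def test_above_dose_warns(self):
        _, _, mg_cof = cs.dose_composition(self.DOSE)
        conc = 1.2 * mg_cof / 80.0 / MW_TSA * 1e6
        p = make_profile([5], [0.1], [conc], dose=self.DOSE, volume=80.0)
        with pytest.warns(UserWarning, match="exceeds 100%"):
            pct = cs.percent_dissolved(p)
        assert pct[0] == pytest.approx(120.0)  # reported, not clamped

    def test_api_basis_agrees_on_congruent_profile(self):
        # congruent molar series: coformer- and API-based ledgers match
        api = np.array([1.0, 2.0, 3.0])
        p = make_profile([1, 2, 3], api, api, dose=self.DOSE, volume=80.0)
        assert np.allclose(
            cs.percent_dissolved(p, basis="coformer"),
            cs.percent_dissolved(p, basis="api"),
        )

    def test_requires_dose_and_volume(self):
        p = make_profile([5], [0.1], [1.0])
        with pytest.raises(ValueError):
            cs.percent_dissolved(p)


class TestWelchComparison:
    def welch_oracle(self, a, b):
        # hand Welch formula, independent of the scipy-backed path
        se2 = a.sd**2 / a.n + b.sd**2 / b.n
        return (b.mean - a.mean) / math.sqrt(se2)

    def test_identical_summaries(self):
        s = cs.SolubilitySummary(1.0, 0.2, 3)
        res = cs.compare_solubilities(s, s)
        assert res.t == 0.0
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a, b",
        [
            # blank medium: (4.6 ± 0.6)e-2 vs (5.0 ± 0.4)e-2 μM, n=3
            ((4.6e-2, 0.6e-2, 3), (5.0e-2, 0.4e-2, 3)),
            # micellar medium: 25.0 ± 3.9 vs 29.9 ± 3.0 μM, n=3
            ((25.0, 3.9, 3), (29.9, 3.0, 3)),
        ],
        ids=["blank", "micellar"],
    )
    def test_solubility_unchanged_by_dissolved_coformer(self, a, b):
        sa, sb = cs.SolubilitySummary(*a), cs.SolubilitySummary(*b)
        res = cs.compare_solubilities(sa, sb)
        assert abs(res.t) == pytest.approx(abs(self.welch_oracle(sa, sb)), rel=1e-9)
        assert res.p_value > 0.05

    def test_frozen_t_statistics(self):
        blank = cs.compare_solubilities(
            cs.SolubilitySummary(4.6e-2, 0.6e-2, 3),
            cs.SolubilitySummary(5.0e-2, 0.4e-2, 3),
        )
        micellar = cs.compare_solubilities(
            cs.SolubilitySummary(25.0, 3.9, 3),
            cs.SolubilitySummary(29.9, 3.0, 3),
        )
        assert abs(blank.t) == pytest.approx(0.96, abs=0.01)
        assert abs(micellar.t) == pytest.approx(1.72, abs=0.01)

    def test_clearly_different_summaries_detected(self):
        res = cs.compare_solubilities(
            cs.SolubilitySummary(1.0, 0.05, 5),
            cs.SolubilitySummary(2.0, 0.05, 5),
        )
        assert res.p_value < 0.05


class TestProfileIO:
    def test_csv_roundtrip_canonicalises_row_order(self, tmp_path):
        path = tmp_path / "profile.csv"
        path.write_text(
            "time_min,conc_api_uM,conc_coformer_uM\n10,0.2,0.3\n5,0.1,0.2\n"
        )
        p = cs.DissolutionProfile.from_csv(path)
        assert list(p.times) == [5, 10]
        assert list(p.conc_api) == [0.1, 0.2]

    def test_analytics_table_columns(self):
        dose = cs.CocrystalDose(10.8, MW_CILP, MW_TSA, 1.0)
        p = make_profile([5, 10], [0.1, 0.2], [0.1, 0.2], dose=dose, volume=80.0)
        df = analytics_table(p, 0.046)
        assert {
            "supersaturation",
            "congruency_coformer_to_api",
            "percent_dissolved",
        } <= set(df.columns)
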