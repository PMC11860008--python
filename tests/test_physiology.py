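"""Age-dependent physiology: growth, ontogeny, binding proteins, profiles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agepbpk.physiology import (
    AgeSpec,
    PhysiologyError,
    body_surface_area,
    body_weight_height,
    build_physiology,
    classify_population,
    cyp3a_hepatic_ratio,
    cyp3a_intestinal_ratio,
    growth_curve,
    intestinal_radius,
    mppgl,
    plasma_proteins,
    regime_discontinuity,
    unbound_fraction,
)


class TestAgeSpec:
    def test_pma_is_sum_of_gestational_and_postnatal(self):
        spec = AgeSpec(postnatal_age=0.5, gestational_age=30.0 / 52.0)
        assert spec.pma == pytest.approx(0.5 + 30.0 / 52.0)

    def test_default_gestation_is_term(self):
        assert AgeSpec(0.0).gestational_age == pytest.approx(0.76923, rel=1e-4)
        assert not AgeSpec(0.0).is_preterm

    @pytest.mark.parametrize("pna,ga_weeks", [(-0.1, 40), (1.0, 21), (1.0, 45)])
    def test_invalid_ages_rejected(self, pna, ga_weeks):
        with pytest.raises(PhysiologyError):
            AgeSpec(postnatal_age=pna, gestational_age=ga_weeks / 52.0)

    def test_regime_classification(self):
        assert classify_population(AgeSpec(0.01)) == "neonate_preterm"
        assert classify_population(AgeSpec(0.3, gestational_age=30 / 52)) == "neonate_preterm"
        assert classify_population(AgeSpec(5.0)) == "pediatric"
        assert classify_population(AgeSpec(30.0)) == "adult"
        assert classify_population(AgeSpec(70.0)) == "elderly"


class TestGrowth:
    def test_reduces_to_intercept_at_birth(self):
        coeffs = {"a": 3.5, "b": 7.0, "c": 0.2, "d": 0.001}
        assert growth_curve(0.0, coeffs) == pytest.approx(3.5)

    def test_rational_form_arithmetic(self):
        # (3 + 10*1)/(1 + 0.1 + 0.01) = 13/1.11
        coeffs = {"a": 3.0, "b": 10.0, "c": 0.1, "d": 0.01}
        assert growth_curve(1.0, coeffs) == pytest.approx(13.0 / 1.11, rel=1e-12)

    def test_negative_age_and_bad_denominator_rejected(self):
        coeffs = {"a": 3.0, "b": 10.0, "c": 0.1, "d": 0.01}
        with pytest.raises(PhysiologyError):
            growth_curve(-1.0, coeffs)
        with pytest.raises(PhysiologyError):
            growth_curve(10.0, {"a": 1.0, "b": 1.0, "c": -1.0, "d": 0.0})

    def test_adult_reference_size(self):
        bw, h = body_weight_height(30.0)
        assert 65.0 <= bw <= 75.0
        assert 165.0 <= h <= 178.0

    @pytest.mark.parametrize("age,lo,hi", [(0.0, 3.0, 4.0), (1.0, 8.5, 11.0), (10.0, 28.0, 36.0)])
    def test_pediatric_weights_realistic(self, age, lo, hi):
        bw, _ = body_weight_height(age)
        assert lo <= bw <= hi


class TestBodySurface:
    def test_adult_value(self):
        # 0.007184 * 70^0.425 * 170^0.725, evaluated independently
        expected = 0.007184 * math.exp(0.425 * math.log(70) + 0.725 * math.log(170))
        assert body_surface_area(70.0, 170.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.809, abs=2e-3)

    def test_branch_boundary_uses_adult_formula(self):
        adult = 0.007184 * 15.0**0.425 * 100.0**0.725
        child = 0.024265 * 15.0**0.5378 * 100.0**0.3964
        assert body_surface_area(15.0, 100.0) == pytest.approx(adult)
        # the two formulas genuinely disagree at the boundary (by ~1 %)
        assert abs(adult - child) / adult > 0.005

    def test_small_body_limit(self):
        assert body_surface_area(0.001, 30.0) < 0.05

    def test_nonpositive_rejected(self):
        with pytest.raises(PhysiologyError):
            body_surface_area(0.0, 170.0)

    @given(
        bw=st.floats(1.0, 150.0),
        h=st.floats(40.0, 210.0),
        factor=st.floats(1.01, 1.5),
    )
    def test_strictly_increasing(self, bw, h, factor):
        base = body_surface_area(bw, h)
        assert body_surface_area(bw * factor, h) > base
        assert body_surface_area(bw, h * factor) > base


class TestIntestinalRadius:
    def test_intercept(self):
        assert intestinal_radius(0.0) == pytest.approx(0.00795)

    @pytest.mark.parametrize("bsa,expected", [(1.0, 0.01595), (1.809, 0.022422)])
    def test_linear_values(self, bsa, expected):
        assert intestinal_radius(bsa) == pytest.approx(expected, rel=1e-6)


class TestCyp3aOntogeny:
    def test_elderly_at_forty_is_adult(self):
        assert cyp3a_hepatic_ratio(AgeSpec(40.0), "elderly") == pytest.approx(1.0)

    def test_pediatric_one_year(self):
        assert cyp3a_hepatic_ratio(AgeSpec(1.0), "pediatric") == pytest.approx(1.0 / 1.31, rel=1e-9)

    def test_term_newborn(self):
        value = cyp3a_hepatic_ratio(AgeSpec(0.0), "neonate_preterm")
        assert value == pytest.approx(0.003 + 0.1331 * (40.0 / 52.0), rel=1e-9)

    def test_pediatric_monotone_and_saturating(self):
        ages = np.linspace(0.05, 19.9, 80)
        vals = [cyp3a_hepatic_ratio(AgeSpec(a), "pediatric") for a in ages]
        assert np.all(np.diff(vals) > 0)
        assert cyp3a_hepatic_ratio(AgeSpec(19.9), "pediatric") > 0.95

    def test_elderly_eight_percent_per_decade(self):
        assert cyp3a_hepatic_ratio(AgeSpec(60.0), "elderly") == pytest.approx(0.92**2)

    def test_intestinal_normalization_and_monotonicity(self):
        assert cyp3a_intestinal_ratio(25.0) == pytest.approx(1.0, abs=0.05)
        grid = [0, 1, 2, 5, 10, 18]
        vals = [cyp3a_intestinal_ratio(a) for a in grid]
        assert np.all(np.diff(vals) > 0)
        assert vals[0] == pytest.approx(0.42)


class TestMppgl:
    def test_newborn(self):
        assert mppgl(0.0) == pytest.approx(10.0**1.407, rel=1e-12)

    def test_octogenarian_polynomials(self):
        assert mppgl(80.0) == pytest.approx(
            0.0001653 * 80**3 - 0.02739 * 80**2 + 1.143 * 80 + 25.52, rel=1e-12
        )
        assert mppgl(85.0) == pytest.approx(-0.08155 * 85**2 + 14.48 * 85 - 612.7, rel=1e-12)
        # late-life rebound: higher at 85 than at 80
        assert mppgl(85.0) > mppgl(80.0)

    @pytest.mark.parametrize("boundary", [20.0, 80.0])
    def test_crossover_jump_below_15_percent(self, boundary):
        assert regime_discontinuity(mppgl, boundary) < 0.15

    def test_positive_on_lifespan(self):
        ages = np.linspace(0.0, 95.0, 200)
        assert all(mppgl(a) > 0 for a in ages)


class TestPlasmaProteins:
    def test_preterm_hill_asymptote(self):
        alb, _ = plasma_proteins(AgeSpec(0.4, gestational_age=30 / 52), "neonate_preterm")
        alb_large, _ = plasma_proteins(AgeSpec(0.49, gestational_age=44 / 52), "neonate_preterm")
        assert alb < 41.3
        assert alb_large < 41.3
        # asymptote check on the raw curve at large PMA
        pma = 60.0
        assert 41.3 * pma**2.7 / (0.383**2.7 + pma**2.7) == pytest.approx(41.3, rel=1e-3)

    def test_pediatric_log_intercept(self):
        alb, _ = plasma_proteins(AgeSpec(1.0), "pediatric")
        assert alb == pytest.approx(33.746)

    def test_adult_linear_decline(self):
        alb, aag = plasma_proteins(AgeSpec(20.0), "adult")
        assert alb == pytest.approx(51.4 - 0.107 * 20.0)
        assert aag == pytest.approx(0.61)

    def test_elderly_aag_level(self):
        _, aag = plasma_proteins(AgeSpec(70.0), "elderly")
        assert aag == pytest.approx(0.58)

    def test_pediatric_aag_percent_capped(self):
        _, aag_teen = plasma_proteins(AgeSpec(15.0), "pediatric")
        assert aag_teen == pytest.approx(0.61)
        _, aag_infant = plasma_proteins(AgeSpec(0.1), "pediatric")
        assert aag_infant < 0.61


class TestUnboundFraction:
    def test_identity_at_adult_protein(self):
        assert unbound_fraction(0.05, 45.0, 45.0) == pytest.approx(0.05)

    def test_no_protein_means_fully_unbound(self):
        assert unbound_fraction(0.05, 0.0, 45.0) == pytest.approx(1.0)

    def test_reference_value(self):
        assert unbound_fraction(0.02, 30.0, 45.0) == pytest.approx(1.0 / (1.0 + 29.4 / 0.9), rel=1e-12)

    @given(
        fu=st.floats(0.005, 0.99),
        p_adult=st.floats(10.0, 80.0),
        p_lo=st.floats(1.0, 200.0),
        bump=st.floats(1.05, 3.0),
    )
    def test_strictly_decreasing_in_protein(self, fu, p_adult, p_lo, bump):
        assert unbound_fraction(fu, p_lo * bump, p_adult) < unbound_fraction(fu, p_lo, p_adult)

    def test_invalid_fu_rejected(self):
        with pytest.raises(PhysiologyError):
            unbound_fraction(0.0, 45.0, 45.0)


class TestBuildPhysiology:
    def test_deterministic(self):
        a = build_physiology(AgeSpec(7.0))
        b = build_physiology(AgeSpec(7.0))
        assert a.organ_volumes == b.organ_volumes
        assert a.organ_flows == b.organ_flows
        assert a.pbsf == b.pbsf

    def test_pbsf_consistency_across_ages(self):
        rng = np.random.default_rng(0)
        for age in rng.uniform(0.05, 90.0, 20):
            ph = build_physiology(AgeSpec(float(age)))
            assert ph.pbsf == pytest.approx(ph.mppgl * ph.liver_weight, rel=1e-12)

    def test_neonate_smaller_than_adult_everywhere(self):
        neo = build_physiology(AgeSpec(0.01))
        adult = build_physiology(AgeSpec(30.0))
        for tissue, vol in neo.organ_volumes.items():
            assert vol < adult.organ_volumes[tissue], tissue

    def test_flow_balance_within_cardiac_output(self):
        for age in (0.05, 1.0, 10.0, 39.0, 75.0):
            ph = build_physiology(AgeSpec(age))
            non_liver = sum(v for k, v in ph.organ_flows.items() if k != "liver")
            assert non_liver == pytest.approx(ph.cardiac_output, rel=1e-9)
            assert ph.organ_flows["liver"] < ph.cardiac_output

    def test_liver_inflow_composition(self):
        ph = build_physiology(AgeSpec(39.0))
        portal = sum(
            ph.organ_flows[t] for t in ("spleen", "duodenum", "jejunum", "ileum", "cecum", "colon")
        )
        assert ph.organ_flows["liver"] == pytest.approx(ph.organ_flows["hepatic_artery"] + portal)

    def test_elderly_declines(self):
        adult = build_physiology(AgeSpec(39.0))
        old = build_physiology(AgeSpec(90.0))
        # per-kg hepatic perfusion and liver size decline with senescence
        assert old.organ_flows["liver"] / old.body_weight < adult.organ_flows["liver"] / adult.body_weight
        assert old.organ_volumes["liver"] / old.body_weight < adult.organ_volumes["liver"] / adult.body_weight
        assert old.cardiac_output < adult.cardiac_output

    def test_gastric_emptying_bands(self):
        assert build_physiology(AgeSpec(0.01)).gastric_emptying_time == 68.0
        assert build_physiology(AgeSpec(1.0)).gastric_emptying_time == 41.0
        assert build_physiology(AgeSpec(15.0)).gastric_emptying_time == 75.0
        assert build_physiology(AgeSpec(39.0)).gastric_emptying_time == 62.5
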