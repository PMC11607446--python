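"""2H-into-fatty-acid fluxes: per-marker production, community growth,
group rates, fungi:bacteria and storage percentages."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaporsip.errors import DomainError, UndefinedRatioError
from vaporsip.lipid_flux import (
    community_growth,
    compute_lipid_fluxes,
    fa_c_produced,
    fungi_to_bacteria,
    mass_specific_rates,
    nlfa_storage_pct,
)
from vaporsip.types import FattyAcidRecord, Fraction, Group, RunConfig, SampleMeta


def _rec(marker="16:0", fraction=Fraction.PLFA, at_l=0.207, at_n=0.0136, fa_c=100.0):
    return FattyAcidRecord(
        sample_id="s1", marker=marker, fraction=fraction,
        atpct_labelled=at_l, atpct_natural=at_n, fa_c=fa_c,
    )


def _meta(biomass=1000.0, time=48.0):
    return SampleMeta(
        sample_id="s1", plot_id="p1", treatment="ambient", phase="drought",
        soil_dry_mass=0.8, microbial_biomass_c=biomass, incubation_time=time,
    )


class TestFaCProduced:
    def test_hand_evaluated_production(self):
        # campaign-mean enrichments: labelled 0.207 at%, natural 0.0136 at%,
        # soil water 16.1 at%, a_w 0.71, 100 ng FA C
        res = fa_c_produced(_rec(), 16.1, 0.71)
        assert res.produced == pytest.approx(1.691890473274429, rel=1e-9)

    def test_no_enrichment_no_production(self):
        res = fa_c_produced(_rec(at_l=0.0136, at_n=0.0136), 16.1, 0.71)
        assert res.produced == 0.0
        assert not res.clamped

    def test_negative_enrichment_clamps_and_flags(self):
        res = fa_c_produced(_rec(at_l=0.0130, at_n=0.0136), 16.1, 0.71)
        assert res.produced == 0.0
        assert res.clamped

    def test_negative_enrichment_propagates_when_clamping_off(self):
        res = fa_c_produced(_rec(at_l=0.0130, at_n=0.0136), 16.1, 0.71,
                            clamp_negative=False)
        assert res.produced < 0

    @given(a_w=st.floats(min_value=0.1, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_law_in_inverse_a_w(self, a_w):
        full = fa_c_produced(_rec(), 16.1, a_w).produced
        half = fa_c_produced(_rec(), 16.1, a_w / 2).produced
        assert half == pytest.approx(2.0 * full, rel=1e-12)

    def test_zero_soil_water_is_domain_error(self):
        with pytest.raises(DomainError):
            fa_c_produced(_rec(), 0.0, 0.71)


class TestCommunityAndMassSpecific:
    @pytest.fixture()
    def flux(self):
        # one marker, fraction-new chain from the production example:
        # produced/total = 1.69189.../100
        return compute_lipid_fluxes([_rec()], 16.1, RunConfig())

    def test_community_growth_hand_chain(self, flux):
        growth = community_growth(flux, _meta())
        assert growth == pytest.approx(352.47718193217275, rel=1e-9)

    def test_growth_linear_in_biomass(self, flux):
        assert community_growth(flux, _meta(biomass=2000.0)) == pytest.approx(
            2.0 * community_growth(flux, _meta()), rel=1e-12
        )

    def test_mass_specific_rates_hand_chain(self, flux):
        ms = mass_specific_rates(flux, _meta())
        assert ms["community_per_hour"] == pytest.approx(0.00035247718193217274, rel=1e-9)
        assert ms["community_per_day"] == pytest.approx(0.008459452366372145, rel=1e-9)

    def test_zero_production_zero_rates(self):
        flux = compute_lipid_fluxes(
            [_rec(at_l=0.0136), _rec(marker="i15:0", at_l=0.0136)], 16.1, RunConfig()
        )
        ms = mass_specific_rates(flux, _meta())
        assert ms["community_per_day"] == 0.0
        assert all(r == 0.0 for r in ms["group_per_hour"].values())

    def test_internal_standard_excluded_from_sums(self):
        with_is = compute_lipid_fluxes([_rec(), _rec(marker="19:0")], 16.1, RunConfig())
        without = compute_lipid_fluxes([_rec()], 16.1, RunConfig())
        assert with_is.total_plfa_c == without.total_plfa_c
        assert with_is.plfa_c_produced == without.plfa_c_produced

    def test_sum_consistency_invariant(self):
        recs = [
            _rec(marker=m, at_l=0.1 + 0.01 * i, fa_c=50.0 + i)
            for i, m in enumerate(["16:0", "i15:0", "18:2w6,9", "cy17:0"])
        ]
        flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
        tbl = flux.marker_table
        assert flux.plfa_c_produced == pytest.approx(
            tbl[tbl.fraction == "plfa"]["fa_c_produced"].sum(), rel=1e-12
        )
        assert sum(flux.group_plfa_produced.values()) == pytest.approx(
            flux.plfa_c_produced, rel=1e-12
        )


class TestFungiToBacteria:
    def test_simple_ratio(self):
        assert fungi_to_bacteria(
            {Group.FUNGI: 2.0, Group.GRAM_POSITIVE: 1.0, Group.GRAM_NEGATIVE: 1.0}
        ) == pytest.approx(1.0)

    def test_actinobacteria_join_denominator(self):
        assert fungi_to_bacteria(
            {Group.FUNGI: 2.0, Group.GRAM_POSITIVE: 1.0,
             Group.GRAM_NEGATIVE: 1.0, Group.ACTINOBACTERIA: 2.0}
        ) == pytest.approx(0.5)

    def test_amf_and_general_excluded(self):
        base = {Group.FUNGI: 2.0, Group.GRAM_POSITIVE: 2.0, Group.GRAM_NEGATIVE: 2.0}
        inflated = dict(base, **{Group.AMF: 100.0, Group.GENERAL: 100.0})
        assert fungi_to_bacteria(base) == fungi_to_bacteria(inflated)

    def test_zero_fungi_gives_zero(self):
        assert fungi_to_bacteria({Group.GRAM_POSITIVE: 1.0, Group.GRAM_NEGATIVE: 1.0}) == 0.0

    def test_homogeneity(self):
        vals = {Group.FUNGI: 1.5, Group.GRAM_POSITIVE: 0.7, Group.GRAM_NEGATIVE: 0.9}
        scaled = {g: 3.0 * v for g, v in vals.items()}
        assert fungi_to_bacteria(scaled) == pytest.approx(fungi_to_bacteria(vals), rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            fungi_to_bacteria({Group.FUNGI: 1.0})

    def test_halved_bacteria_doubles_rate_ratio(self):
        base = {Group.FUNGI: 1.0, Group.GRAM_POSITIVE: 1.0, Group.GRAM_NEGATIVE: 1.0}
        halved = {Group.FUNGI: 1.0, Group.GRAM_POSITIVE: 0.5, Group.GRAM_NEGATIVE: 0.5}
        assert fungi_to_bacteria(halved) == pytest.approx(2.0 * fungi_to_bacteria(base))


class TestNlfaStoragePct:
    def test_hand_percentage(self):
        recs = [
            _rec(marker="18:2w6,9", at_l=0.207, fa_c=100.0),                      # PLFA
            _rec(marker="18:2w6,9", fraction=Fraction.NLFA, at_l=0.207, fa_c=228.0),
        ]
        flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
        pct = nlfa_storage_pct(flux)
        # identical enrichment, 2.28x the pool: production ratio is 228%
        assert pct[Group.FUNGI] == pytest.approx(228.0, rel=1e-9)

    def test_zero_nlfa_production_zero_pct(self):
        recs = [
            _rec(marker="18:2w6,9"),
            _rec(marker="18:2w6,9", fraction=Fraction.NLFA, at_l=0.014, at_n=0.014),
        ]
        flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
        assert nlfa_storage_pct(flux)[Group.FUNGI] == 0.0

    def test_only_shared_markers_enter_ratio(self):
        recs = [
            _rec(marker="18:2w6,9"),                                  # PLFA only
            _rec(marker="18:1w9c", fraction=Fraction.NLFA),           # NLFA only
        ]
        flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
        assert Group.FUNGI not in nlfa_storage_pct(flux)

    def test_zero_plfa_production_undefined(self):
        recs = [
            _rec(marker="18:2w6,9", at_l=0.0136),                     # no PLFA production
            _rec(marker="18:2w6,9", fraction=Fraction.NLFA),
        ]
        flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
        assert Group.FUNGI not in nlfa_storage_pct(flux)


def test_clamped_record_count_reported():
    recs = [_rec(), _rec(marker="i15:0", at_l=0.0120)]
    flux = compute_lipid_fluxes(recs, 16.1, RunConfig())
    assert flux.n_clamped == 1
    assert (flux.marker_table["fa_c_produced"] >= 0).all()
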