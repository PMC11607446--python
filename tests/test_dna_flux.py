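"""18O-into-DNA fluxes and the shared excess-enrichment kernel."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaporsip.dna_flux import dna_produced, growth_dna
from vaporsip.errors import DegenerateSampleError, DomainError
from vaporsip.flux_kernel import excess_fraction_production
from vaporsip.types import DnaSample, SampleMeta


def _sample(at_l=1.0, at_n=0.203, o=10.0, total=40.0, sw=20.3):
    return DnaSample(
        sample_id="s1", o_dna_extract=o, atpct_labelled=at_l, atpct_natural=at_n,
        total_dna=total, soil_water_atpct=sw,
    )


def _meta(biomass=1000.0, time=48.0):
    return SampleMeta(
        sample_id="s1", plot_id="p1", treatment="ambient", phase="drought",
        soil_dry_mass=0.8, microbial_biomass_c=biomass, incubation_time=time,
    )


class TestSharedKernel:
    """Both tracer equations reduce to produced = pool * excess / denominator."""

    @given(
        at_l=st.floats(min_value=0.01, max_value=5.0),
        at_n=st.floats(min_value=0.01, max_value=0.3),
        denom=st.floats(min_value=1.0, max_value=25.0),
        pool=st.floats(min_value=0.0, max_value=1e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_kernel_linearity_and_sign(self, at_l, at_n, denom, pool):
        res = excess_fraction_production(at_l, at_n, denom, pool, clamp_negative=False)
        assert res.produced == pytest.approx(res.fraction_new * pool, rel=1e-12)
        assert (res.produced >= 0) == (at_l >= at_n) or pool == 0
        doubled = excess_fraction_production(at_l, at_n, denom, 2 * pool,
                                             clamp_negative=False)
        assert doubled.produced == pytest.approx(2 * res.produced, rel=1e-12)

    def test_kernel_clamps_negative_excess(self):
        res = excess_fraction_production(0.1, 0.2, 20.0, 100.0)
        assert res.produced == 0.0 and res.clamped

    def test_kernel_rejects_zero_denominator(self):
        with pytest.raises(DomainError):
            excess_fraction_production(0.2, 0.1, 0.0, 100.0)


class TestDnaProduced:
    def test_hand_evaluated_production(self):
        # O 10 ug, labelled 1.0 at%, natural 0.203 at%, soil water 20.3 at%,
        # oxygen fraction 31.21%
        res = dna_produced(_sample(), 31.21)
        assert res.produced == pytest.approx(1.257964874842754, rel=1e-9)

    def test_no_enrichment_no_production(self):
        res = dna_produced(_sample(at_l=0.203), 31.21)
        assert res.produced == 0.0

    def test_oxygen_fraction_cancels_with_matching_extract(self):
        # when O_extract = total_dna * 0.3121, produced / total equals the
        # excess fraction exactly
        total = 40.0
        s = _sample(o=total * 0.3121, total=total)
        res = dna_produced(s, 31.21)
        excess = (s.atpct_labelled - s.atpct_natural) / s.soil_water_atpct
        assert res.produced / total == pytest.approx(excess, rel=1e-12)

    def test_negative_enrichment_clamped_and_flagged(self):
        res = dna_produced(_sample(at_l=0.200), 31.21)
        assert res.produced == 0.0 and res.clamped

    def test_extract_oxygen_cannot_exceed_dna(self):
        with pytest.raises(DomainError):
            _sample(o=50.0, total=40.0)


class TestGrowthDna:
    def test_hand_arithmetic(self):
        s = _sample(total=40.0)
        # produced/total = 0.05, biomass 1000 ug C/g, 48 h
        growth = growth_dna(s, 2.0, _meta())
        assert growth == pytest.approx(1041.6666666666667, rel=1e-9)

    def test_zero_production_zero_growth(self):
        assert growth_dna(_sample(), 0.0, _meta()) == 0.0

    def test_zero_total_dna_degenerate(self):
        s = DnaSample(sample_id="s1", o_dna_extract=0.0, atpct_labelled=0.3,
                      atpct_natural=0.2, total_dna=0.0, soil_water_atpct=20.0)
        with pytest.raises(DegenerateSampleError):
            growth_dna(s, 1.0, _meta())

    def test_turnover_is_reciprocal_of_daily_mass_specific_rate(self):
        from vaporsip.physiology import turnover_days

        meta = _meta()
        growth = growth_dna(_sample(total=40.0), 2.0, meta)  # 5% of pool in 48 h
        ms_day = growth / (meta.microbial_biomass_c * 1000.0) * 24.0
        assert turnover_days(meta.microbial_biomass_c, growth) == pytest.approx(
            1.0 / ms_day, rel=1e-12
        )


def test_dna_and_plfa_paths_agree_at_unit_assimilation():
    """With a_w = 1 and identical fraction-new, both tracers report the same
    mass-specific growth."""
    from vaporsip.lipid_flux import community_growth, compute_lipid_fluxes
    from vaporsip.types import FattyAcidRecord, Fraction, RunConfig

    meta = _meta()
    f_new = 0.02
    sw2h, sw18o = 16.1, 20.3
    rec = FattyAcidRecord(
        sample_id="s1", marker="16:0", fraction=Fraction.PLFA,
        atpct_labelled=0.0136 + f_new * sw2h, atpct_natural=0.0136, fa_c=100.0,
    )
    flux = compute_lipid_fluxes([rec], sw2h, RunConfig(a_w=1.0))
    g_plfa = community_growth(flux, meta)

    total = 40.0
    s = DnaSample(
        sample_id="s1", o_dna_extract=total * 0.3121,
        atpct_labelled=0.203 + f_new * sw18o, atpct_natural=0.203,
        total_dna=total, soil_water_atpct=sw18o,
    )
    g_dna = growth_dna(s, dna_produced(s, 31.21).produced, meta)
    assert g_plfa == pytest.approx(g_dna, rel=1e-9)
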