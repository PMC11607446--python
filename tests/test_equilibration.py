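"""Water-vapor equilibration: mass balance, exponential fit, time average."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from vaporsip.equilibration import (
    average_enrichment,
    exponential_curve,
    fit_equilibration,
    source_loss_to_soil_atpct,
)
from vaporsip.errors import DataError, MassBalanceError
from vaporsip.types import EquilibrationFit, WaterObservation

TIMES = (0.0, 3.0, 6.0, 16.0, 48.0)


def _series(at_start, at_end, b, times=TIMES, noise=None, rng=None):
    x = exponential_curve(np.array(times), at_start, at_end, b)
    if noise:
        x = np.clip(x + rng.normal(0, noise, len(times)), 1e-4, None)
    return [WaterObservation(time=t, atom_percent=v) for t, v in zip(times, x)]


class TestMassBalance:
    def test_unchanged_source_gives_constant_soil(self):
        src = [WaterObservation(t, 20.0) for t in TIMES]
        soil = source_loss_to_soil_atpct(src, 1.0, 0.25, 0.0155)
        assert all(o.atom_percent == pytest.approx(0.0155) for o in soil)

    def test_equal_masses_hand_balance(self):
        src = [WaterObservation(0.0, 20.0), WaterObservation(48.0, 10.0)]
        soil = source_loss_to_soil_atpct(src, 1.0, 1.0, 0.0155)
        assert soil[-1].atom_percent == pytest.approx(10.0155, rel=1e-12)

    @given(
        ratio=st.floats(min_value=0.05, max_value=5.0),
        drop=st.floats(min_value=0.0, max_value=15.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_total_label_conserved(self, ratio, drop):
        source_mass, soil_mass = 1.0, 1.0 / ratio
        src = [WaterObservation(0.0, 20.0), WaterObservation(24.0, 20.0 - drop / 2),
               WaterObservation(48.0, 20.0 - drop)]
        soil = source_loss_to_soil_atpct(src, source_mass, soil_mass, 0.0155)
        for s_obs, w_obs in zip(src, soil):
            total = source_mass * s_obs.atom_percent + soil_mass * w_obs.atom_percent
            start = source_mass * 20.0 + soil_mass * 0.0155
            assert total == pytest.approx(start, rel=1e-12)

    def test_inconsistent_masses_raise(self):
        # a rising source series implies negative soil enrichment
        src = [WaterObservation(0.0, 10.0), WaterObservation(48.0, 20.0)]
        with pytest.raises(MassBalanceError):
            source_loss_to_soil_atpct(src, 1.0, 0.1, 0.0155)


class TestFitEquilibration:
    def test_noise_free_parameters_recovered(self):
        fit = fit_equilibration(_series(0.0155, 16.1, 0.12))
        assert fit.at_start == pytest.approx(0.0155, rel=1e-6)
        assert fit.at_end == pytest.approx(16.1, rel=1e-6)
        assert fit.b == pytest.approx(0.12, rel=1e-6)
        assert not fit.degenerate

    def test_flat_series_flagged_degenerate(self):
        fit = fit_equilibration([WaterObservation(t, 5.0) for t in TIMES])
        assert fit.degenerate
        assert fit.at_start == fit.at_end == pytest.approx(5.0)
        assert fit.average_atpct == pytest.approx(5.0)

    def test_too_few_points_raise(self):
        with pytest.raises(DataError):
            fit_equilibration(_series(0.0155, 16.1, 0.12, times=(0.0, 48.0)))

    def test_missing_anchor_raises(self):
        with pytest.raises(DataError):
            fit_equilibration(_series(0.0155, 16.1, 0.12, times=(3.0, 6.0, 16.0)))

    def test_noisy_recovery_monte_carlo(self):
        """sd 0.1 at% observation noise: parameters within 5% relative for
        >= 95% of seeded replicates."""
        ok = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(seed)
            fit = fit_equilibration(_series(0.0155, 16.1, 0.12, noise=0.1, rng=rng))
            good = (
                abs(fit.at_end - 16.1) / 16.1 < 0.05
                and abs(fit.b - 0.12) / 0.12 < 0.05
            )
            ok += good
        assert ok / n >= 0.95


class TestAverageEnrichment:
    def test_closed_form_hand_value(self):
        fit = EquilibrationFit(at_start=0.0155, at_end=16.1, b=0.1, window=48.0)
        assert average_enrichment(fit) == pytest.approx(12.776639868002077, rel=1e-9)

    def test_fast_limit_reaches_plateau(self):
        fit = EquilibrationFit(at_start=0.0155, at_end=16.1, b=1e6, window=48.0)
        assert average_enrichment(fit) == pytest.approx(16.1, abs=1e-3)

    def test_slow_limit_stays_at_start(self):
        fit = EquilibrationFit(at_start=0.0155, at_end=16.1, b=1e-9, window=48.0)
        assert average_enrichment(fit) == pytest.approx(0.0155, abs=1e-5)

    @given(
        at_start=st.floats(min_value=0.01, max_value=1.0),
        at_end=st.floats(min_value=1.0, max_value=25.0),
        b=st.floats(min_value=1e-4, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_closed_form_matches_quadrature(self, at_start, at_end, b):
        fit = EquilibrationFit(at_start=at_start, at_end=at_end, b=b, window=48.0)
        closed = average_enrichment(fit)
        numeric, _ = integrate.quad(
            lambda t: at_end + (at_start - at_end) * math.exp(-b * t), 0.0, 48.0,
            epsabs=1e-13, epsrel=1e-13,
        )
        assert closed == pytest.approx(numeric / 48.0, rel=1e-9)

    def test_monotone_in_plateau(self):
        avgs = [
            average_enrichment(EquilibrationFit(at_start=0.0155, at_end=e, b=0.1))
            for e in (5.0, 10.0, 16.1, 20.0)
        ]
        assert avgs == sorted(avgs)

    def test_average_bounded_by_endpoints(self):
        fit = fit_equilibration(_series(0.0155, 16.1, 0.12))
        assert 0.0155 <= fit.average_atpct <= 16.1
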