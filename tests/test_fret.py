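"""Unit and property tests for the sensitized-emission / K_D module."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fretstab import fret, simulate
from fretstab.errors import (
    DegenerateControlError,
    DegenerateDataError,
    DomainError,
    FitFailureError,
    InvalidInputError,
    MissingControlError,
)

from conftest import GRID, make_reading, make_well


def quadratic_bound_fraction(a, X, kd):
    """Independent oracle: root of (a-b)(X-b) = kd*b found numerically."""
    if X == 0:
        return 0.0
    b = brentq(
        lambda bb: (a - bb) * (X - bb) - kd * bb,
        0.0,
        min(a, X),
        xtol=1e-300,
        rtol=8.9e-16,
        maxiter=300,
    )
    return b / a


class TestChannelReading:
    def test_rejects_unknown_channel(self):
        with pytest.raises(InvalidInputError, match="channel"):
            make_reading(channel="XY")

    def test_rejects_negative_concentration(self):
        with pytest.raises(InvalidInputError):
            make_reading(acceptor_conc=-1.0)

    def test_rejects_nonfinite_intensity(self):
        with pytest.raises(InvalidInputError):
            make_reading(intensity=float("nan"))


class TestEstimateCrosstalk:
    def test_zero_bleedthrough(self):
        donor = make_well("D1", dd=1000.0, aa=0.0, da=0.0)
        acceptor = make_well("A1", dd=0.0, aa=800.0, da=240.0)
        xt = fret.estimate_crosstalk(donor, acceptor)
        assert xt.delta == 0.0
        assert xt.alpha == pytest.approx(0.30)

    def test_noiseless_round_trip(self, noiseless_plate):
        xt = fret.estimate_crosstalk(
            noiseless_plate.donor_only, noiseless_plate.acceptor_only
        )
        assert xt.delta == pytest.approx(0.12, rel=1e-12)
        assert xt.alpha == pytest.approx(0.30, rel=1e-12)

    def test_empty_acceptor_list_raises(self):
        donor = make_well("D1", dd=1000.0, aa=0.0, da=120.0)
        with pytest.raises(InvalidInputError, match="empty"):
            fret.estimate_crosstalk(donor, [])

    def test_missing_channel_names_well(self):
        donor = [make_reading(well="D7", channel="DD", intensity=100.0)]
        acceptor = make_well("A1", dd=0.0, aa=800.0, da=240.0)
        with pytest.raises(InvalidInputError, match="D7"):
            fret.estimate_crosstalk(donor, acceptor)

    def test_zero_denominator_is_degenerate(self):
        donor = make_well("D1", dd=0.0, aa=0.0, da=10.0)
        acceptor = make_well("A1", dd=0.0, aa=800.0, da=240.0)
        with pytest.raises(DegenerateControlError):
            fret.estimate_crosstalk(donor, acceptor)


class TestSensitizedEmission:
    def test_donor_only_well_is_zero(self, crosstalk):
        wells = make_well("W1", dd=1000.0, aa=0.0, da=0.12 * 1000.0)
        [res] = fret.sensitized_emission(wells, crosstalk)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_acceptor_only_well_is_zero(self, crosstalk):
        wells = make_well("W1", dd=0.0, aa=500.0, da=0.30 * 500.0)
        [res] = fret.sensitized_emission(wells, crosstalk)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_algebraic_construction(self, crosstalk):
        aa, dd = 321.0, 765.0
        wells = make_well("W1", dd=dd, aa=aa, da=100.0 + 0.30 * aa + 0.12 * dd)
        [res] = fret.sensitized_emission(wells, crosstalk)
        assert res.se == pytest.approx(100.0)

    def test_missing_channel_raises(self, crosstalk):
        wells = make_well("W1", dd=1.0, aa=1.0, da=1.0)[:2]
        with pytest.raises(InvalidInputError, match="lacks channel"):
            fret.sensitized_emission(wells, crosstalk)

    def test_control_subtraction_and_missing_entry(self, crosstalk):
        wells = make_well("W1", dd=0.0, aa=0.0, da=50.0, acceptor_conc=0.5)
        out = fret.sensitized_emission(wells, crosstalk, control_se={0.5: 20.0})
        assert out[0].se == pytest.approx(30.0)
        with pytest.raises(MissingControlError):
            fret.sensitized_emission(wells, crosstalk, control_se={1.0: 20.0})


class TestEq1Model:
    def test_zero_acceptor_gives_zero(self):
        for a, kd in [(0.3, 0.1), (1.0, 1.0), (5.0, 17.0)]:
            assert fret.eq1_model(0.0, a, kd, 123.0) == 0.0

    def test_closed_form_golden_ratio_point(self):
        expected = 1.0 - 2.0 / (1.0 + np.sqrt(5.0))  # == (3 - sqrt 5)/2
        assert fret.eq1_model(1.0, 1.0, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx((3 - np.sqrt(5)) / 2)

    def test_saturation_limit(self):
        kd = 0.4308
        assert fret.eq1_model(1e6 * kd, 1.0, kd, 1.0) == pytest.approx(1.0, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            fret.eq1_model(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(DomainError):
            fret.eq1_model(1.0, 1.0, -1.0, 1.0)

    def test_matches_quadratic_oracle_on_grid(self):
        rng = np.random.default_rng(42)
        a = 10 ** rng.uniform(-3, 3, 300)
        X = 10 ** rng.uniform(-3, 3, 300)
        kd = 10 ** rng.uniform(-3, 3, 300)
        for ai, xi, ki in zip(a, X, kd):
            expected = quadratic_bound_fraction(ai, xi, ki)
            got = fret.eq1_model(xi, ai, ki, 1.0)
            assert got == pytest.approx(expected, rel=1e-10)

    @given(
        a=st.floats(1e-3, 1e3),
        kd=st.floats(1e-3, 1e3),
        x1=st.floats(0, 1e3),
        x2=st.floats(0, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_x_and_kd(self, a, kd, x1, x2):
        lo, hi = sorted((x1, x2))
        assert fret.eq1_model(lo, a, kd, 1.0) <= fret.eq1_model(hi, a, kd, 1.0) + 1e-12
        # larger kd -> weaker binding at fixed X
        assert (
            fret.eq1_model(hi, a, kd * 2, 1.0)
            <= fret.eq1_model(hi, a, kd, 1.0) + 1e-12
        )


class TestFitKd:
    def test_noiseless_round_trip_design_point(self):
        x = np.repeat(GRID, 3)
        se = fret.eq1_model(x, 1.0, 0.4308, 1000.0)
        fit = fret.fit_kd(fret.TitrationSeries(1.0, x, se))
        assert fit.kd == pytest.approx(0.4308, rel=1e-3)
        assert fit.em_fret_max == pytest.approx(1000.0, rel=1e-3)

    def test_scale_equivariance(self):
        x = np.repeat(GRID, 2)
        se = fret.eq1_model(x, 1.0, 0.4308, 1000.0)
        f1 = fret.fit_kd(fret.TitrationSeries(1.0, x, se))
        f7 = fret.fit_kd(fret.TitrationSeries(1.0, x, 7.0 * se))
        assert f7.kd == pytest.approx(f1.kd, rel=1e-6)
        assert f7.em_fret_max == pytest.approx(7.0 * f1.em_fret_max, rel=1e-6)

    def test_noisy_recovery_fixed_seed(self):
        rng = np.random.default_rng(7)
        x = np.repeat(GRID, 3)
        se = fret.eq1_model(x, 1.0, 0.4308, 1000.0)
        se = se * (1.0 + 0.02 * rng.standard_normal(se.size))
        fit = fret.fit_kd(fret.TitrationSeries(1.0, x, se))
        assert abs(fit.kd - 0.4308) <= 3.0 * fit.kd_stderr

    @pytest.mark.parametrize("kd", [0.05, 0.2, 1.0, 5.0, 20.0])
    def test_recovery_across_kd_range(self, kd):
        # grid extended to reach saturation for weak binders
        x = np.concatenate([GRID, [10.0, 40.0, 150.0]])
        se = fret.eq1_model(x, 1.0, kd, 500.0)
        fit = fret.fit_kd(fret.TitrationSeries(1.0, x, se))
        assert fit.kd == pytest.approx(kd, rel=1e-3)
        assert fit.em_fret_max == pytest.approx(500.0, rel=1e-3)

    def test_permutation_invariance_bit_identical(self):
        rng = np.random.default_rng(3)
        x = np.repeat(GRID, 3)
        se = fret.eq1_model(x, 1.0, 0.4308, 1000.0)
        se = se * (1.0 + 0.05 * rng.standard_normal(se.size))
        perm = rng.permutation(x.size)
        f1 = fret.fit_kd(fret.TitrationSeries(1.0, x, se))
        f2 = fret.fit_kd(fret.TitrationSeries(1.0, x[perm], se[perm]))
        assert f1.kd == f2.kd
        assert f1.em_fret_max == f2.em_fret_max
        assert f1.kd_stderr == f2.kd_stderr

    def test_all_zero_se_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fret.fit_kd(fret.TitrationSeries(1.0, GRID, np.zeros(GRID.size)))

    def test_too_few_concentrations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError, match="distinct"):
            fret.fit_kd(fret.TitrationSeries(1.0, x, x))

    def test_plate_round_trip(self, noiseless_series):
        fit = fret.fit_kd(noiseless_series)
        assert fit.kd == pytest.approx(0.4308, rel=1e-3)


class TestKdTimeCourse:
    @staticmethod
    def _series_at(decay_rate, minutes, seed=0):
        cfg = simulate.FretSimConfig(functional_decay_rate=decay_rate, seed=seed)
        plate = simulate.simulate_titration_plate(cfg, incubation_time_min=minutes)
        xt = fret.estimate_crosstalk(plate.donor_only, plate.acceptor_only)
        return fret.TitrationSeries.from_readings(plate.sample, xt)

    def test_identical_series_unit_ratios(self):
        s = self._series_at(0.0, 60.0)
        ts = fret.kd_time_course({15.0: s, 30.0: s, 60.0: s})
        assert ts.kd_ratios == pytest.approx((1.0, 1.0, 1.0))

    def test_decaying_titrator_increases_apparent_kd(self):
        by_time = {t: self._series_at(0.8, t) for t in (15.0, 30.0, 45.0, 60.0)}
        ts = fret.kd_time_course(by_time)
        kds = [f.kd for f in ts.fits]
        assert all(b > a for a, b in zip(kds, kds[1:]))

    def test_single_time_point_raises(self):
        s = self._series_at(0.0, 15.0)
        with pytest.raises(InvalidInputError):
            fret.kd_time_course({15.0: s})

    def test_failure_annotated_with_time_point(self):
        good = self._series_at(0.0, 15.0)
        bad = fret.TitrationSeries(1.0, GRID, np.zeros(GRID.size))
        with pytest.raises(FitFailureError, match="30"):
            fret.kd_time_course({15.0: good, 30.0: bad})
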