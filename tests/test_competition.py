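"""Tests for IC50 fitting, Cheng-Prusoff conversion and hit calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretstab import competition, fret, simulate
from fretstab.errors import (
    DegenerateDataError,
    DomainError,
    InvalidInputError,
    MissingControlError,
)

DOSES = np.array([0.0, 0.05, 0.15, 0.5, 1.5, 5.0, 15.0, 50.0, 150.0])


def make_series(ic50, hill=1.0, top=1.0, bottom=0.0, doses=DOSES, noise=None, seed=0):
    y = np.where(
        doses > 0,
        competition.four_pl(np.where(doses > 0, doses, 1.0), np.log10(ic50), hill, top, bottom),
        top,
    )
    if noise:
        rng = np.random.default_rng(seed)
        y = y + noise * rng.standard_normal(y.size)
    return competition.CompetitionSeries("cmpd", doses, y, donor_conc=1.0, acceptor_conc=1.0)


class TestFitIC50:
    # a perfect noiseless fit has a singular covariance; the stderr is
    # reported as inf and the optimizer warning is expected
    @pytest.mark.filterwarnings("ignore::scipy.optimize.OptimizeWarning")
    def test_noiseless_round_trip_at_published_point(self):
        fit = competition.fit_ic50(make_series(9.81))
        assert fit.ic50 == pytest.approx(9.81, rel=1e-3)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-3)

    def test_midpoint_identity(self):
        fit = competition.fit_ic50(make_series(2.5, hill=1.7, top=1.1, bottom=0.1))
        y_mid = competition.four_pl(
            fit.ic50, np.log10(fit.ic50), fit.hill_slope, fit.top, fit.bottom
        )
        assert y_mid == pytest.approx((fit.top + fit.bottom) / 2.0, rel=1e-9)

    def test_flat_response_is_degenerate(self):
        series = competition.CompetitionSeries(
            "flat", DOSES, np.ones(DOSES.size), 1.0, 1.0
        )
        with pytest.raises(DegenerateDataError):
            competition.fit_ic50(series)

    def test_too_few_doses(self):
        series = competition.CompetitionSeries(
            "few", [0.0, 1.0, 10.0, 100.0], [1.0, 0.9, 0.5, 0.1], 1.0, 1.0
        )
        with pytest.raises(InvalidInputError, match="distinct"):
            competition.fit_ic50(series)

    def test_narrow_dose_span_rejected(self):
        doses = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = competition.four_pl(doses, np.log10(3.0), 1.0, 1.0, 0.0)
        series = competition.CompetitionSeries("narrow", doses, y, 1.0, 1.0)
        with pytest.raises(InvalidInputError, match="log-units"):
            competition.fit_ic50(series)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        s = make_series(3.0, noise=0.01, seed=2)
        perm = rng.permutation(s.inhibitor_concs.size)
        s2 = competition.CompetitionSeries(
            "cmpd", s.inhibitor_concs[perm], s.relative_binding[perm], 1.0, 1.0
        )
        f1, f2 = competition.fit_ic50(s), competition.fit_ic50(s2)
        assert f1.ic50 == f2.ic50
        assert f1.hill_slope == f2.hill_slope


class TestChengPrusoff:
    def test_published_worked_example(self):
        res = competition.cheng_prusoff(1.24, 1.0, 0.4308)
        assert round(res.ki, 2) == 0.37

    def test_no_competition_correction_at_zero_labeled(self):
        res = competition.cheng_prusoff(5.5, 0.0, 0.4308)
        assert res.ki == pytest.approx(5.5)

    def test_arithmetic_example(self):
        res = competition.cheng_prusoff(13.81, 1.0, 0.4308)
        assert res.ki == pytest.approx(4.158, abs=5e-3)

    def test_invalid_kd(self):
        with pytest.raises(DomainError):
            competition.cheng_prusoff(1.0, 1.0, 0.0)

    @given(
        ic50=st.floats(1e-3, 1e3),
        labeled=st.floats(0.0, 1e3),
        kd=st.floats(1e-3, 1e3),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneity(self, ic50, labeled, kd, scale):
        base = competition.cheng_prusoff(ic50, labeled, kd).ki
        scaled = competition.cheng_prusoff(scale * ic50, scale * labeled, scale * kd).ki
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_ki_never_exceeds_ic50(self):
        res = competition.cheng_prusoff(1.24, 1.0, 0.4308)
        assert res.ki <= res.ic50


def _relative_binding_series(readings, crosstalk):
    wells = fret.sensitized_emission(readings, crosstalk)
    conc = {(r.well, r.replicate): r.inhibitor_conc for r in readings}
    norm = np.mean([w.se for w in wells if conc[(w.well, w.replicate)] == 0])
    return competition.CompetitionSeries(
        "cmpd",
        [conc[(w.well, w.replicate)] for w in wells],
        [w.se / norm for w in wells],
        donor_conc=readings[0].donor_conc,
        acceptor_conc=readings[0].acceptor_conc,
    )


class TestEndToEndSelfConsistency:
    @pytest.mark.parametrize("ki_true", [0.2, 0.43, 3.0, 20.0])
    def test_ki_recovery_within_5pct(self, ki_true, crosstalk):
        # low receptor concentration keeps the Cheng-Prusoff regime valid
        cfg = simulate.FretSimConfig(donor_conc=0.02)
        doses = [0.0] + list(np.geomspace(0.01, 300.0, 12) * ki_true)
        readings = simulate.simulate_competition_plate(cfg, ki=ki_true, dose_grid=doses)
        series = _relative_binding_series(readings, crosstalk)
        fit = competition.fit_ic50(series)
        ki = competition.cheng_prusoff(fit.ic50, 1.0, cfg.kd).ki
        assert ki == pytest.approx(ki_true, rel=0.05)

    def test_self_competition_recovers_kd(self, crosstalk):
        cfg = simulate.FretSimConfig(donor_conc=0.02)
        doses = [0.0] + list(np.geomspace(0.005, 150.0, 12))
        readings = simulate.simulate_competition_plate(cfg, ki=cfg.kd, dose_grid=doses)
        series = _relative_binding_series(readings, crosstalk)
        fit = competition.fit_ic50(series)
        ki = competition.cheng_prusoff(fit.ic50, 1.0, cfg.kd).ki
        assert ki == pytest.approx(cfg.kd, rel=0.05)


class TestScreen:
    def test_identical_wells_not_a_hit(self, crosstalk):
        cfg = simulate.FretSimConfig()
        readings = simulate.simulate_competition_plate(
            cfg, ki=1e12, dose_grid=[0.0, 50.0], compound_id="inert"
        )
        [res] = competition.screen_compounds(readings, crosstalk)
        assert res.se_reduction == pytest.approx(0.0, abs=1e-6)
        assert res.donor_dequench == pytest.approx(0.0, abs=1e-6)
        assert not res.is_hit

    def test_full_inhibitor_is_hit_with_predicted_dequench(self, crosstalk):
        cfg = simulate.FretSimConfig()
        readings = simulate.simulate_competition_plate(
            cfg, ki=1e-5, dose_grid=[0.0, 50.0], compound_id="strong"
        )
        [res] = competition.screen_compounds(readings, crosstalk)
        f_bound = simulate.simulate_binding_equilibrium(1.0, 1.0, cfg.kd)
        e = cfg.apparent_fret_efficiency
        expected_dq = e * f_bound / (1.0 - e * f_bound)
        assert res.se_reduction == pytest.approx(1.0, abs=1e-3)
        assert res.donor_dequench == pytest.approx(expected_dq, rel=1e-3)
        assert res.is_hit

    def test_quencher_artifact_rejected_by_dual_criterion(self, crosstalk):
        cfg = simulate.FretSimConfig()
        control = simulate.simulate_competition_plate(
            cfg, ki=1.0, dose_grid=[0.0], compound_id="x"
        )
        quench = simulate.simulate_competition_plate(
            cfg, ki=1.0, dose_grid=[50.0], compound_id="quencher", artifact="quencher"
        )
        [res] = competition.screen_compounds(control + quench, crosstalk)
        assert res.se_reduction > 0.2
        assert res.donor_dequench < 0.2
        assert not res.is_hit

    def test_missing_control_raises(self, crosstalk):
        cfg = simulate.FretSimConfig()
        readings = simulate.simulate_competition_plate(
            cfg, ki=1.0, dose_grid=[50.0], compound_id="c"
        )
        with pytest.raises(MissingControlError):
            competition.screen_compounds(readings, crosstalk)
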