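"""Weighing-series reduction: dry-basis moisture, MR, plateau detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foamdry.drying import (
    NO_PLATEAU, DegenerateRunError, WeighingSeries, build_drying_run,
    detect_equilibrium, moisture_dry_basis, moisture_ratio,
    read_drying_run, read_weighing_series, write_drying_run,
    write_weighing_series,
)


@pytest.mark.parametrize(
    "water, dry, expected",
    [(0.0, 2.0, 0.0), (2.0, 2.0, 100.0), (4.6, 0.4, 1150.0)],
)
def test_moisture_dry_basis_arithmetic(water, dry, expected):
    assert moisture_dry_basis(water, dry) == pytest.approx(expected)


@pytest.mark.parametrize("water, dry", [(1.0, 0.0), (1.0, -2.0), (-0.1, 1.0)])
def test_moisture_dry_basis_rejects_invalid_masses(water, dry):
    with pytest.raises(ValueError):
        moisture_dry_basis(water, dry)


@pytest.mark.parametrize(
    "M, M0, Me, expected",
    [(100.0, 100.0, 10.0, 1.0), (10.0, 100.0, 10.0, 0.0), (55.0, 100.0, 10.0, 0.5)],
)
def test_moisture_ratio_endpoints_and_midpoint(M, M0, Me, expected):
    assert moisture_ratio(M, M0, Me) == pytest.approx(expected)


def test_moisture_ratio_degenerate_run_rejected():
    with pytest.raises(DegenerateRunError):
        moisture_ratio(50.0, 100.0, 100.0)


def test_moisture_ratio_clips_noise_overshoot():
    assert moisture_ratio(101.0, 100.0, 10.0) == 1.0
    assert moisture_ratio(9.0, 100.0, 10.0) == 0.0


@given(
    scale=st.floats(0.01, 100.0),
    M=st.floats(10.0, 99.0),
)
@settings(max_examples=50, derandomize=True)
def test_moisture_ratio_invariant_to_common_rescaling(scale, M):
    """MR is affine-invariant: scaling all moistures leaves it unchanged."""
    base = moisture_ratio(M, 100.0, 5.0)
    scaled = moisture_ratio(M * scale, 100.0 * scale, 5.0 * scale)
    assert scaled == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize(
    "masses, res, expected",
    [
        ([10, 6, 5.00, 5.00, 5.00], 0.01, 2),
        ([10, 9, 8, 7, 6, 5], 0.01, NO_PLATEAU),
        ([10, 5.004, 5.001, 4.999], 0.01, 1),
    ],
)
def test_detect_equilibrium_three_constant_weighings(masses, res, expected):
    assert detect_equilibrium(masses, res) == expected


def test_detect_equilibrium_needs_three_points():
    with pytest.raises(ValueError):
        detect_equilibrium([10.0, 9.0], 0.01)


def _series(net_masses, tare=100.0, dt=60.0, **kw):
    net = np.asarray(net_masses, float)
    return WeighingSeries(
        temperature_C=60.0,
        times=np.arange(len(net)) * dt,
        gross_masses=net + tare,
        tare_mass=tare,
        **kw,
    )


class TestBuildDryingRun:
    def test_direct_arithmetic_example(self):
        run = build_drying_run(_series([10, 6, 5, 5, 5]), dry_mass=5.0)
        np.testing.assert_allclose(run.moisture_db, [100, 20, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(run.MR, [1, 0.2, 0, 0, 0], atol=1e-12)
        assert run.M0 == pytest.approx(100.0)
        assert run.Me == pytest.approx(0.0)
        assert run.plateau_index == 2

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateRunError):
            build_drying_run(_series([5, 5, 5, 5]), dry_mass=4.0)

    def test_dry_mass_must_be_below_smallest_net_mass(self):
        with pytest.raises(ValueError):
            build_drying_run(_series([10, 6, 5, 5, 5]), dry_mass=5.5)

    def test_no_plateau_warns_and_uses_last_mass(self):
        with pytest.warns(UserWarning, match="no three-constant"):
            run = build_drying_run(_series([10, 8, 7, 6]), dry_mass=5.0)
        assert run.plateau_index == NO_PLATEAU
        assert run.Me == pytest.approx(moisture_dry_basis(1.0, 5.0))
        assert run.MR[-1] == pytest.approx(0.0)

    def test_net_masses_recoverable_from_moisture(self):
        """dry_mass*(1 + M/100) reconstructs the weighed masses."""
        series = _series([12.0, 8.5, 6.25, 6.0, 6.0, 6.0])
        run = build_drying_run(series, dry_mass=5.0)
        reconstructed = run.dry_mass * (1.0 + run.moisture_db / 100.0)
        np.testing.assert_allclose(reconstructed, series.net_masses, atol=1e-9)

    def test_mr_is_zero_at_plateau(self):
        run = build_drying_run(_series([20, 11, 8, 7, 7, 7]), dry_mass=6.0)
        np.testing.assert_allclose(run.MR[run.plateau_index:], 0.0, atol=1e-12)


class TestWeighingSeriesValidation:
    def test_rejects_nonmonotonic_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WeighingSeries(60.0, [0, 60, 60], [110, 105, 104], 100.0)

    def test_rejects_nonpositive_net_mass(self):
        with pytest.raises(ValueError, match="positive"):
            WeighingSeries(60.0, [0, 60], [110, 99], 100.0)

    def test_rejects_large_mass_rise(self):
        with pytest.raises(ValueError, match="noise tolerance"):
            WeighingSeries(60.0, [0, 60, 120], [110, 105, 109], 100.0)

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            WeighingSeries(60.0, [20, 40], [110, 105], 100.0)


def test_weighing_series_csv_round_trip(tmp_path):
    series = _series([12.0, 8.5, 6.25, 6.0, 6.0, 6.0])
    path = tmp_path / "run60.csv"
    write_weighing_series(series, path)
    back = read_weighing_series(path, temperature_C=60.0, tare_mass=100.0)
    np.testing.assert_allclose(back.times, series.times)
    np.testing.assert_allclose(back.gross_masses, series.gross_masses)


def test_drying_run_csv_round_trip(tmp_path):
    run = build_drying_run(_series([12.0, 8.5, 6.25, 6.0, 6.0, 6.0]), dry_mass=5.0)
    path = tmp_path / "reduced.csv"
    write_drying_run(run, path)
    back = read_drying_run(path)
    np.testing.assert_allclose(back.MR, run.MR, atol=1e-12)
    np.testing.assert_allclose(back.moisture_db, run.moisture_db, atol=1e-9)
    assert back.Me == pytest.approx(run.Me)
    assert back.temperature_C == run.temperature_C
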