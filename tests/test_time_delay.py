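"""Time-delay estimation: CCF, parabolic refinement, TD matrix and projection."""

import numpy as np
import pytest

from cofluct.io import NetworkPartition, ParcelSignals, ValidationError
from cofluct.preprocess import zscore
from cofluct.synthetic import _bandlimited_noise, _spectral_shift
from cofluct.time_delay import (LaggedCCF, lagged_crosscov, network_td,
                                pair_delay, parabolic_tau, projection_map,
                                td_matrix)


def _z(x):
    return (x - x.mean()) / x.std()


def naive_crosscov(x_i, x_j, max_lag):
    """Double-loop oracle for the overlap-normalized lagged cross-covariance."""
    t = len(x_i)
    out = {}
    for d in range(-max_lag, max_lag + 1):
        acc, n = 0.0, 0
        for k in range(t):
            if 0 <= k + d < t:
                acc += x_i[k] * x_j[k + d]
                n += 1
        out[d] = acc / n
    return out


def naive_pair_tau(x_i, x_j, max_lag, tr):
    """Independent per-pair delay: argmax |ccf|, three-point parabola."""
    ccf = naive_crosscov(x_i, x_j, max_lag)
    lags = list(range(-max_lag, max_lag + 1))
    vals = [ccf[d] for d in lags]
    p = int(np.argmax(np.abs(vals)))
    peak = lags[p]
    if abs(peak) == max_lag:
        return peak * tr
    c_m, c_0, c_p = vals[p - 1], vals[p], vals[p + 1]
    denom = c_m - 2 * c_0 + c_p
    if abs(denom) < 1e-12:
        return peak * tr
    frac = np.clip((c_m - c_p) / (2 * denom), -0.5, 0.5)
    return (peak + frac) * tr


class TestLaggedCrossCov:
    def test_matches_double_loop_oracle(self, rng):
        x = _z(rng.standard_normal(100))
        y = _z(rng.standard_normal(100))
        ccf = lagged_crosscov(x, y, 5)
        oracle = naive_crosscov(x, y, 5)
        for lag, val in zip(ccf.lags, ccf.values):
            assert val == pytest.approx(oracle[lag], abs=1e-12)

    def test_identical_series_peak_at_zero(self, rng):
        x = _z(rng.standard_normal(200))
        ccf = lagged_crosscov(x, x, 3)
        assert ccf.peak_lag == 0
        assert ccf.values[3] == pytest.approx(1.0, abs=1e-12)

    def test_integer_shift_gives_positive_lag_when_i_leads(self, rng):
        s = np.convolve(rng.standard_normal(210), np.ones(8) / 8, mode="valid")
        x_i = _z(s[1:])   # x_i(t) = s(t)
        x_j = _z(s[:-1])  # x_j(t) = s(t - 1): x_i leads
        ccf = lagged_crosscov(x_i, x_j, 3)
        assert ccf.peak_lag == 1
        assert not ccf.boundary_flag

    def test_short_series_errors(self):
        with pytest.raises(ValidationError, match="insufficient"):
            lagged_crosscov(np.zeros(10), np.zeros(10), 3)


class TestParabolicTau:
    def test_symmetric_peak_gives_zero(self):
        ccf = LaggedCCF(np.arange(-1, 2), np.array([0.5, 1.0, 0.5]), 0, False)
        assert parabolic_tau(ccf, tr=2.0).tau_seconds == 0.0

    def test_exact_on_sampled_parabola(self):
        # c(d) = 1 - (d - 0.3)^2 at d in {-1, 0, 1}: vertex at 0.3 exactly
        d = np.arange(-1, 2)
        ccf = LaggedCCF(d, 1.0 - (d - 0.3) ** 2, 0, False)
        assert parabolic_tau(ccf, tr=1.0).tau_seconds == pytest.approx(
            0.3, abs=1e-12)

    def test_integer_peak_added_to_fraction(self):
        d = np.arange(-3, 4)
        ccf = LaggedCCF(d, 1.0 - 0.1 * (d - 1.3) ** 2, 1, False)
        est = parabolic_tau(ccf, tr=2.0)
        assert est.tau_seconds == pytest.approx(2.0 * 1.3, abs=1e-9)

    def test_negative_extremum_uses_signed_values(self):
        # anticorrelated pair: extremum is a minimum; vertex still recovered
        d = np.arange(-1, 2)
        ccf = LaggedCCF(d, -(1.0 - (d - 0.2) ** 2), 0, False)
        assert parabolic_tau(ccf, tr=1.0).tau_seconds == pytest.approx(
            0.2, abs=1e-12)

    def test_boundary_peak_skips_interpolation(self):
        d = np.arange(-2, 3)
        ccf = LaggedCCF(d, np.array([1.0, 0.5, 0.1, 0.05, 0.01]), -2, True)
        est = parabolic_tau(ccf, tr=2.0)
        assert est.tau_seconds == -4.0 and est.flag == "boundary"

    def test_flat_curvature_keeps_integer_lag(self):
        d = np.arange(-1, 2)
        ccf = LaggedCCF(d, np.array([1.0, 1.0, 1.0]), 0, False)
        est = parabolic_tau(ccf, tr=2.0)
        assert est.tau_seconds == 0.0 and est.flag == "flat"


class TestTDMatrix:
    def _signals(self, data, tr=2.0):
        ids = [f"p{i}" for i in range(data.shape[1])]
        return zscore(ParcelSignals("s", data, ids, tr))

    def test_identical_signals_zero_matrix(self, rng):
        x = rng.standard_normal(100)
        z = self._signals(np.column_stack([x, x, x]))
        td = td_matrix(z, 3)
        np.testing.assert_allclose(td.data, 0.0, atol=1e-12)

    def test_antisymmetry(self, rng):
        z = self._signals(rng.standard_normal((120, 8)))
        td = td_matrix(z, 3)
        np.testing.assert_allclose(td.data + td.data.T, 0.0, atol=1e-9)
        np.testing.assert_allclose(np.diag(td.data), 0.0)

    def test_matches_naive_oracle(self, rng):
        tr = 2.0
        data = rng.standard_normal((150, 6))
        z = self._signals(data, tr)
        td = td_matrix(z, 3)
        for i in range(6):
            for j in range(i + 1, 6):
                tau_ij = naive_pair_tau(z.data[:, i], z.data[:, j], 3, tr)
                assert td.data[i, j] == pytest.approx(-tau_ij, abs=1e-9)

    def test_shifted_source_sign_pattern(self, rng):
        # node 0 leads node 1 by 1 frame and node 2 by 2 frames (TR = 2 s)
        tr = 2.0
        s = _bandlimited_noise(260, tr, rng, 0.01, 0.1)
        data = np.column_stack([s[4:244], s[3:243], s[2:242]])
        data = data + 0.02 * rng.standard_normal(data.shape)
        z = self._signals(data, tr)
        td = td_matrix(z, 3)
        # entry [i, j] = lead of j over i: node 0 leads -> positive column 0
        assert td.data[1, 0] == pytest.approx(2.0, abs=0.2)
        assert td.data[2, 0] == pytest.approx(4.0, abs=0.2)
        assert td.data[2, 1] == pytest.approx(2.0, abs=0.2)
        pm = projection_map(td)
        assert pm.values[0] > pm.values[1] > pm.values[2]

    def test_time_reversal_flips_sign(self, rng):
        tr = 2.0
        s = _bandlimited_noise(260, tr, rng, 0.01, 0.1)
        data = np.column_stack([s[2:242], s[0:240]])
        z = self._signals(data, tr)
        rev = self._signals(data[::-1])
        tau_fwd = td_matrix(z, 3).data[1, 0]
        tau_rev = td_matrix(rev, 3).data[1, 0]
        assert tau_fwd == pytest.approx(-tau_rev, abs=1e-6)


class TestFractionalLagRecovery:
    @pytest.mark.parametrize("delta_frames", [0.25, 0.5, 0.75, 1.5])
    def test_median_error_small_at_good_snr(self, delta_frames):
        tr = 2.0
        errors = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            s = _bandlimited_noise(240, tr, rng, 0.01, 0.1)
            lead = _spectral_shift(s, delta_frames * tr, tr)
            x_i = _z(lead + 0.3 * rng.standard_normal(240))
            x_j = _z(s + 0.3 * rng.standard_normal(240))
            est = pair_delay(x_i, x_j, 3, tr)
            errors.append(abs(est.tau_seconds - delta_frames * tr))
        assert np.median(errors) < 0.15 * tr


class TestProjectionAndNetwork:
    def test_zero_matrix_zero_map(self):
        from cofluct.time_delay import TDMatrix

        td = TDMatrix(np.zeros((4, 4)), [f"p{i}" for i in range(4)])
        assert not projection_map(td).values.any()

    def test_map_mean_zero_for_antisymmetric_input(self, rng):
        from cofluct.time_delay import TDMatrix

        a = rng.standard_normal((7, 7))
        a = a - a.T
        pm = projection_map(TDMatrix(a, [f"p{i}" for i in range(7)]))
        assert abs(pm.values.mean()) < 1e-9

    def test_network_td_equals_brute_force_mean(self, rng):
        from cofluct.time_delay import ProjectionMap

        ids = [f"p{i}" for i in range(6)]
        part = NetworkPartition(dict(zip(ids, ["SMN", "SMN", "DMN",
                                               "DMN", "OTHER", "OTHER"])))
        vals = rng.standard_normal(6)
        pm = ProjectionMap(vals, ids)
        assert network_td(pm, part, "SMN") == pytest.approx(vals[:2].mean())

    def test_constant_network_value_returned(self):
        from cofluct.time_delay import ProjectionMap

        ids = ["a", "b", "c"]
        part = NetworkPartition({"a": "SMN", "b": "SMN", "c": "OTHER"})
        pm = ProjectionMap(np.array([1.0, 1.0, -2.0]), ids)
        assert network_td(pm, part, "SMN") == 1.0

    def test_empty_network_errors(self):
        from cofluct.time_delay import ProjectionMap

        part = NetworkPartition({"a": "OTHER"})
        pm = ProjectionMap(np.zeros(1), ["a"])
        with pytest.raises(ValidationError, match="DMN"):
            network_td(pm, part, "DMN")
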