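"""PLI and orthogonalized-AEC estimators and their invariances."""

import numpy as np
import pytest

import vigilnet as v
from vigilnet.connectivity import (
    _aecc_matrix,
    _pli_matrix,
    aec_orthogonalized,
    analytic_signal,
    connectivity_matrix_from_data,
    global_and_regional_fc,
    pli,
)
from vigilnet.core_io import ArgumentError, BandDefinition, DegenerateInputError
from vigilnet.synthetic import envelope_coupled_pair, phase_lag_pair

FS = 312.5
N = 4096
ALPHA2 = BandDefinition("alpha2", 10, 13)


def narrowband(rng, n=N, band=ALPHA2, fs=FS):
    return v.brickwall_filter(rng.standard_normal(n), band, fs)


class TestAnalyticSignal:
    def test_cosine_envelope_and_phase_rate(self):
        t = np.arange(N) / FS
        z = analytic_signal(np.cos(2 * np.pi * 10 * t))
        inner = slice(N // 8, -N // 8)
        np.testing.assert_allclose(np.abs(z)[inner], 1.0, atol=5e-3)
        rate = np.diff(np.unwrap(np.angle(z)))[inner] * FS / (2 * np.pi)
        np.testing.assert_allclose(rate, 10.0, atol=0.05)

    def test_slow_modulator_recovered(self):
        t = np.arange(N) / FS
        a = 1.0 + 0.4 * np.sin(2 * np.pi * 0.3 * t)
        z = analytic_signal(a * np.cos(2 * np.pi * 11 * t))
        inner = slice(N // 8, -N // 8)
        np.testing.assert_allclose(np.abs(z)[inner], a[inner], rtol=0.02)

    def test_zero_series(self):
        assert np.all(np.abs(analytic_signal(np.zeros(N))) == 0)


class TestPLI:
    def test_constant_lag_half_pi_gives_one(self):
        ph = np.linspace(0, 100, N)
        assert pli(ph, ph - np.pi / 2) == 1.0

    @pytest.mark.parametrize("lag", [0.0, np.pi])
    def test_zero_and_antiphase_lag_invisible(self, lag):
        ph = np.linspace(0, 100, N)
        assert pli(ph, ph - lag) == pytest.approx(0.0, abs=1e-12)

    def test_common_phase_offset_invariance(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, N))
        assert pli(a + 1.234, b + 1.234) == pytest.approx(pli(a, b), abs=1e-12)

    def test_swap_invariance(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, N))
        assert pli(a, b) == pytest.approx(pli(b, a), abs=1e-12)

    def test_uniform_phase_noise_floor(self):
        # |mean of n iid signs| has expectation ~ sqrt(2/(pi n))
        vals = [
            abs(np.mean(np.sign(np.sin(
                np.random.default_rng(s).uniform(-np.pi, np.pi, N)))))
            for s in range(200)
        ]
        expected = np.sqrt(2 / (np.pi * N))
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            pli(np.zeros(10), np.zeros(11))


class TestAECc:
    def test_pure_common_source_rescales_to_half(self, rng):
        x = narrowband(rng)
        assert aec_orthogonalized(x, 0.7 * x) == pytest.approx(0.5, abs=1e-12)

    def test_independent_pairs_center_at_half(self):
        vals = [
            aec_orthogonalized(
                narrowband(np.random.default_rng(2 * s)),
                narrowband(np.random.default_rng(2 * s + 1)),
            )
            for s in range(50)
        ]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_planted_envelope_correlation_recovered(self):
        vals = []
        for s in range(25):
            rng = np.random.default_rng(s)
            a, b, e1, e2 = envelope_coupled_pair(rng, N, FS, ALPHA2, 0.6)
            assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(0.6, abs=1e-6)
            af = v.brickwall_filter(a, ALPHA2, FS)
            bf = v.brickwall_filter(b, ALPHA2, FS)
            vals.append(aec_orthogonalized(af, bf, rescale=False))
        assert np.mean(vals) == pytest.approx(0.6, abs=0.05)

    def test_scaling_invariance(self, rng):
        a, b = narrowband(rng), narrowband(np.random.default_rng(1))
        r1 = aec_orthogonalized(a, b, rescale=False)
        r2 = aec_orthogonalized(3.7 * a, 0.2 * b, rescale=False)
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_zero_variance_envelope_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            aec_orthogonalized(np.zeros(N), narrowband(rng))


class TestMatrix:
    def test_planted_lag_pair_dominates(self, rng):
        data = 0.1 * rng.standard_normal((3, N))
        s_i, s_j = phase_lag_pair(rng, N, FS, ALPHA2, np.pi / 2)
        data[0] += s_i
        data[2] += s_j
        cm = connectivity_matrix_from_data(data, ALPHA2, "PLI", FS)
        assert cm.values[0, 2] > 0.9
        assert cm.values[0, 1] < 0.5
        assert cm.values[1, 2] < 0.5

    def test_identical_channels_have_zero_pli(self, rng):
        row = rng.standard_normal(N)
        cm = connectivity_matrix_from_data(
            np.vstack([row, row, rng.standard_normal(N)]), ALPHA2, "PLI", FS)
        assert cm.values[0, 1] == 0.0

    @pytest.mark.parametrize("measure", ["PLI", "AECc"])
    def test_symmetry_zero_diagonal_and_range(self, rng, measure):
        data = rng.standard_normal((5, N))
        cm = connectivity_matrix_from_data(data, ALPHA2, measure, FS)
        np.testing.assert_allclose(cm.values, cm.values.T)
        assert np.all(np.diag(cm.values) == 0)
        off = cm.values[~np.eye(5, dtype=bool)]
        assert np.all((off >= 0) & (off <= 1))

    @pytest.mark.parametrize("measure", ["PLI", "AECc"])
    def test_permutation_equivariance(self, rng, measure):
        data = rng.standard_normal((4, N))
        perm = np.array([2, 0, 3, 1])
        cm = connectivity_matrix_from_data(data, ALPHA2, measure, FS)
        cmp_ = connectivity_matrix_from_data(data[perm], ALPHA2, measure, FS)
        np.testing.assert_allclose(cmp_.values, cm.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_matrix_agrees_with_pairwise_calls(self, rng):
        data = rng.standard_normal((4, N))
        filt = v.brickwall_filter(data, ALPHA2, FS)
        z = analytic_signal(filt)
        m_pli = _pli_matrix(z)
        m_aec = _aecc_matrix(z, 1 / 16)
        for i in range(4):
            for j in range(i + 1, 4):
                assert m_pli[i, j] == pytest.approx(
                    pli(np.angle(z[i]), np.angle(z[j])), abs=1e-12)
                assert m_aec[i, j] == pytest.approx(
                    aec_orthogonalized(filt[i], filt[j]), abs=1e-9)


class TestGlobalRegional:
    def test_constant_matrix(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 0)
        g, r = global_and_regional_fc(m)
        assert g == pytest.approx(0.3)
        np.testing.assert_allclose(r, 0.3)

    def test_global_is_mean_of_regional(self, rng):
        m = rng.uniform(0, 1, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g, r = global_and_regional_fc(m)
        assert g == pytest.approx(r.mean())

    def test_matches_brute_force_double_loop(self, rng):
        n = 7
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        g, r = global_and_regional_fc(m)
        for i in range(n):
            expected = np.mean([m[i, j] for j in range(n) if j != i])
            assert r[i] == pytest.approx(expected)
        assert g == pytest.approx(
            np.mean([m[i, j] for i in range(n) for j in range(n) if i != j]))
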