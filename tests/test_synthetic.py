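"""Generator determinism, state-dependent spectra and planted couplings."""

import numpy as np
import pytest

import vigilnet as v
from vigilnet.core_io import ArgumentError, BandDefinition, StateLabel as S
from vigilnet.spectral import aggregate_spectral, band_power_table
from vigilnet.synthetic import (
    CouplingSpec,
    StateProfile,
    default_profiles,
    generate_eog,
    generate_recording,
    one_over_f_noise,
)

from conftest import SMALL_LABELS

ALPHA2 = BandDefinition("alpha2", 10, 13)


class TestProfiles:
    def test_drowsy_dropout_must_stay_below_half(self):
        with pytest.raises(ArgumentError):
            StateProfile(S.D_EC, alpha_amp=1, theta_amp=1, dropout_fraction=0.5)
        with pytest.raises(ArgumentError):
            StateProfile(S.A_EC, alpha_amp=1, theta_amp=1, dropout_fraction=0.1)

    def test_blinks_restricted_to_eyes_open(self):
        with pytest.raises(ArgumentError):
            StateProfile(S.A_EC, alpha_amp=1, theta_amp=1, blink_rate=0.3)

    def test_coupling_validation(self):
        with pytest.raises(ArgumentError):
            CouplingSpec((2, 2), "phase_lag", ALPHA2)
        with pytest.raises(ArgumentError):
            CouplingSpec((0, 1), "nonsense", ALPHA2)
        assert CouplingSpec((0, 1), "phase_lag", ALPHA2, lag_radians=0.0).pli_invisible
        assert not CouplingSpec((0, 1), "phase_lag", ALPHA2,
                                lag_radians=np.pi / 2).pli_invisible


class TestDeterminism:
    def test_identical_arguments_bitwise_identical(self):
        profs = default_profiles()
        spec = [(profs[S.A_EC], 2), (profs[S.D_EC], 1)]
        coup = [CouplingSpec((0, 5), "phase_lag", ALPHA2)]
        r1, l1 = generate_recording(spec, coup, seed=9, roi_labels=SMALL_LABELS)
        r2, l2 = generate_recording(spec, coup, seed=9, roi_labels=SMALL_LABELS)
        assert np.array_equal(r1.data, r2.data)
        assert l1 == l2

    def test_different_seed_differs(self):
        profs = default_profiles()
        r1, _ = generate_recording([(profs[S.A_EC], 1)], seed=1,
                                   roi_labels=SMALL_LABELS)
        r2, _ = generate_recording([(profs[S.A_EC], 1)], seed=2,
                                   roi_labels=SMALL_LABELS)
        assert not np.array_equal(r1.data, r2.data)

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ArgumentError):
            generate_recording([])


class TestSpectralStructure:
    def test_zero_amplitudes_give_noise_band_integrals(self):
        # with no oscillations, relative power follows the 1/f band integrals
        prof = StateProfile(S.A_EC, alpha_amp=0.0, theta_amp=0.0)
        fracs = []
        for seed in range(10):
            rec, _ = generate_recording([(prof, 5)], seed=seed,
                                        roi_labels=SMALL_LABELS, with_eog=False)
            for ep in v.segment_epochs(rec):
                fracs.append(band_power_table(ep).rel_power.values.mean(axis=0))
        fracs = np.mean(fracs, axis=0)
        edges = [(0.5, 4), (4, 8), (8, 10), (10, 13), (13, 30), (30, 48)]
        expected = np.array([np.log(hi / lo) for lo, hi in edges])
        expected /= expected.sum()
        np.testing.assert_allclose(fracs, expected, atol=0.02)

    def test_directional_fidelity_of_state_contrasts(self):
        """Group spectral means over 20 seeds reproduce every directional
        contrast: drowsy raises theta and lowers alpha2, beta and peak
        frequency; eyes-open lowers alpha and raises delta."""
        profs = default_profiles()
        spec = [(profs[S.A_EC], 3), (profs[S.D_EC], 3), (profs[S.EO], 3)]
        acc = {s: [] for s in (S.A_EC, S.D_EC, S.EO)}
        for seed in range(20):
            rec, labels = generate_recording(spec, seed=seed,
                                             roi_labels=SMALL_LABELS,
                                             with_eog=False)
            eps = v.segment_epochs(rec)
            for state in acc:
                tables = [band_power_table(ep)
                          for ep, lab in zip(eps, labels) if lab == state]
                _, gp, _, peak = aggregate_spectral(tables)
                acc[state].append([*gp.values, peak])
        m = {s: np.mean(acc[s], axis=0) for s in acc}
        delta, theta, alpha1, alpha2, beta, gamma, peak = range(7)
        assert m[S.D_EC][theta] > m[S.A_EC][theta]
        assert m[S.D_EC][alpha2] < m[S.A_EC][alpha2]
        assert m[S.D_EC][beta] < m[S.A_EC][beta]
        assert m[S.EO][alpha1] < m[S.A_EC][alpha1]
        assert m[S.EO][alpha2] < m[S.A_EC][alpha2]
        assert m[S.EO][delta] > m[S.A_EC][delta]
        assert m[S.A_EC][peak] > m[S.D_EC][peak]
        assert m[S.A_EC][peak] > m[S.EO][peak]

    def test_one_over_f_noise_spectrum_slope(self, rng):
        x = one_over_f_noise(rng, (50, 8192), gamma=1.0)
        spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
        freqs = np.fft.rfftfreq(8192)
        sel = (freqs > 0.01) & (freqs < 0.4)
        slope = np.polyfit(np.log(freqs[sel]), np.log(spec.mean(axis=0)[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)


class TestCouplings:
    def test_phase_lag_pair_recovered_by_pli(self):
        """A planted constant-lag pair exceeds the 95th percentile of all
        uncoupled pairs in the PLI matrix."""
        coup = [CouplingSpec((0, 8), "phase_lag", ALPHA2, lag_radians=np.pi / 2)]
        prof = default_profiles()[S.A_EC]
        rec, _ = generate_recording([(prof, 1)], coup, seed=3,
                                    roi_labels=SMALL_LABELS, with_eog=False)
        ep = v.segment_epochs(rec)[0]
        cm = v.connectivity_matrix(ep, ALPHA2, "PLI")
        iu = np.triu_indices(16, k=1)
        vals = cm.values[iu]
        others = vals[~((iu[0] == 0) & (iu[1] == 8))]
        assert cm.values[0, 8] > np.percentile(others, 95)
        assert cm.values[0, 8] > 0.8

    def test_envelope_share_pair_recovered_by_aecc(self):
        # planted in beta, away from the spatially shared alpha rhythm whose
        # residual envelope correlations raise the alpha-band background
        beta = BandDefinition("beta", 13, 30)
        coup = [CouplingSpec((0, 8), "envelope_share", beta, envelope_corr=0.6)]
        prof = default_profiles()[S.A_EC]
        hits = []
        for seed in range(5):
            rec, _ = generate_recording([(prof, 1)], coup, seed=seed,
                                        roi_labels=SMALL_LABELS, with_eog=False)
            ep = v.segment_epochs(rec)[0]
            cm = v.connectivity_matrix(ep, beta, "AECc")
            iu = np.triu_indices(16, k=1)
            vals = cm.values[iu]
            others = vals[~((iu[0] == 0) & (iu[1] == 8))]
            hits.append(cm.values[0, 8] > np.percentile(others, 95))
        assert np.mean(hits) >= 0.8


class TestDropout:
    def test_drowsy_epoch_contains_one_dropout_window(self):
        """The planted contiguous alpha-dropout window is visible in the
        posterior alpha envelope at roughly the planted fraction."""
        from vigilnet.state_scoring import extract_features
        prof = default_profiles()[S.D_EC]
        fracs = []
        for seed in range(10):
            rec, _ = generate_recording([(prof, 1)], seed=seed,
                                        roi_labels=SMALL_LABELS)
            ep = v.segment_epochs(rec)[0]
            fracs.append(extract_features(ep).alpha_dropout_frac)
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.08)


class TestEOG:
    def test_drowsy_eog_power_is_sub_1hz(self):
        prof = default_profiles()[S.D_EC]
        eog = generate_eog(prof, 4096, 312.5, seed_or_rng=0)
        slow = v.band_power(eog, BandDefinition("slow", 0.05, 1.0), 312.5)
        fast = v.band_power(eog, BandDefinition("fast", 1.0, 40.0), 312.5)
        assert slow > 5 * fast

    def test_eyes_open_blink_count_near_rate(self):
        prof = default_profiles()[S.EO]
        counts = []
        for seed in range(30):
            eog = generate_eog(prof, 4096, 312.5, seed_or_rng=seed)
            # count excursions above half the blink amplitude
            counts.append(np.sum(np.diff((eog > 6).astype(int)) == 1))
        expected = 0.3 * 4096 / 312.5  # rate x duration ~ 3.9
        assert np.mean(counts) == pytest.approx(expected, rel=0.25)

    def test_alert_eog_is_quiet(self):
        prof = default_profiles()[S.A_EC]
        eog = generate_eog(prof, 4096, 312.5, seed_or_rng=0)
        assert eog.std() < 0.1
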