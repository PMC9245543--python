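"""Synthetic source-space recordings with state-dependent spectra and
planted couplings.

Each epoch of each ROI is 1/f-shaped broadband noise plus state-scaled
band-limited oscillations:

* an ~10 Hz posterior dominant rhythm, strongest on the occipito-parietal
  ROI set, strongly attenuated with eyes open;
* 4-8 Hz theta activity on all ROIs, elevated when drowsy;
* in drowsy epochs, one contiguous alpha-dropout window covering a stated
  fraction (<0.5) of the epoch;
* with eyes open, blink transients on frontal ROIs and the EOG channel;
* when drowsy, slow (<1 Hz) roving eye movements on the EOG channel.

Couplings between chosen ROI pairs are planted so that the downstream
estimators have ground truth to recover: a shared narrowband carrier with a
constant phase lag (detected by the PLI) or amplitude envelopes mixed from a
common slow modulator to an exact target correlation (detected by the AECc).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .core_io import (
    AAL78_LABELS,
    ArgumentError,
    BandDefinition,
    PipelineConfig,
    Recording,
    StateLabel,
    match_labels,
)
from .spectral import brickwall_filter


@dataclass(frozen=True)
class StateProfile:
    """Generative parameters of one vigilance state.

    Amplitudes are standard deviations relative to the unit-variance 1/f
    noise background of each ROI.
    """

    state: StateLabel
    alpha_amp: float
    theta_amp: float
    dropout_fraction: float = 0.0
    blink_rate: float = 0.0   # blinks per second, eyes-open only
    sem_amp: float = 0.0      # slow-eye-movement EOG amplitude, drowsy only

    def __post_init__(self) -> None:
        if self.state == StateLabel.D_EC:
            if not (0.0 < self.dropout_fraction < 0.5):
                raise ArgumentError(
                    "drowsy dropout_fraction must lie in (0, 0.5): at >=0.5 "
                    "the epoch reaches the NREM1 boundary and is no longer D-EC"
                )
        elif self.dropout_fraction != 0.0:
            raise ArgumentError("dropout_fraction must be 0 outside D-EC")
        if self.blink_rate != 0.0 and self.state != StateLabel.EO:
            raise ArgumentError("blink_rate must be 0 unless state is EO")


def default_profiles() -> dict[StateLabel, StateProfile]:
    """The study conditions the generator emulates.

    Alert eyes-closed: a clear posterior alpha rhythm, modest theta.
    Drowsy eyes-closed: theta elevated, alpha attenuated with a 30% dropout
    window, slow roving eye movements.  Eyes-open: alpha suppressed, blinks
    at 0.3/s.
    """
    return {
        StateLabel.A_EC: StateProfile(StateLabel.A_EC, alpha_amp=1.0, theta_amp=0.3),
        StateLabel.D_EC: StateProfile(
            StateLabel.D_EC, alpha_amp=0.8, theta_amp=0.9,
            dropout_fraction=0.3, sem_amp=1.0,
        ),
        StateLabel.EO: StateProfile(
            StateLabel.EO, alpha_amp=0.15, theta_amp=0.3, blink_rate=0.3,
        ),
    }


@dataclass(frozen=True)
class CouplingSpec:
    """One planted ROI-pair coupling.

    ``phase_lag``: both ROIs share a narrowband carrier offset by a constant
    ``lag_radians`` (a lag of 0 or pi is permitted but is invisible to the
    PLI by construction).  ``envelope_share``: the two ROIs carry
    independent-phase carriers whose amplitude envelopes are mixed to the
    exact target Pearson correlation ``envelope_corr``.
    """

    roi_pair: tuple[int, int]
    kind: str  # "phase_lag" | "envelope_share"
    carrier_band: BandDefinition
    lag_radians: float = np.pi / 2
    envelope_corr: float = 0.6
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        i, j = self.roi_pair
        if i == j:
            raise ArgumentError("coupled ROIs must differ")
        if self.kind not in ("phase_lag", "envelope_share"):
            raise ArgumentError(f"unknown coupling kind {self.kind!r}")
        if not (-np.pi < self.lag_radians <= np.pi):
            raise ArgumentError("lag_radians must lie in (-pi, pi]")
        if not (0.0 <= self.envelope_corr <= 1.0):
            raise ArgumentError("envelope_corr must lie in [0, 1]")

    @property
    def pli_invisible(self) -> bool:
        """True for phase lags of 0 or pi, which the PLI cannot detect."""
        return self.kind == "phase_lag" and (
            self.lag_radians == 0.0 or abs(self.lag_radians) == np.pi
        )


# ---------------------------------------------------------------------------
# signal primitives


def one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], gamma: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with a 1/f^gamma power spectrum (DC-free)."""
    n = shape[-1]
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(nf)
    amp[1:] = freqs[1:] ** (-gamma / 2.0)
    spec = amp * (
        rng.standard_normal((*shape[:-1], nf))
        + 1j * rng.standard_normal((*shape[:-1], nf))
    )
    spec[..., 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def narrowband_oscillation(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    f_lo: float,
    f_hi: float,
    fs: float,
) -> np.ndarray:
    """Unit-variance band-limited noise in [f_lo, f_hi) Hz."""
    white = rng.standard_normal(shape)
    x = brickwall_filter(white, BandDefinition("nb", f_lo, f_hi), fs)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _slow_modulator(rng: np.random.Generator, n: int, fs: float,
                    bw_hz: float = 0.7, depth: float = 0.35) -> np.ndarray:
    """Positive slow (sub-``bw_hz``) amplitude modulator around 1."""
    m = one_over_f_noise(rng, (n,), gamma=0.0)  # white
    m = brickwall_filter(m, BandDefinition("lp", fs / n, bw_hz), fs)
    sd = m.std()
    if sd > 0:
        m = m / sd
    return np.clip(1.0 + depth * m, 0.05, None)


def _blink_train(rng: np.random.Generator, n: int, fs: float,
                 rate_hz: float, width_s: float = 0.08,
                 amp: float = 8.0) -> tuple[np.ndarray, int]:
    """Poisson train of Gaussian blink transients; returns (series, count)."""
    out = np.zeros(n)
    count = rng.poisson(rate_hz * n / fs)
    t = np.arange(n) / fs
    times = rng.uniform(0.2, n / fs - 0.2, size=count)
    for t0 in times:
        out += amp * np.exp(-0.5 * ((t - t0) / width_s) ** 2)
    return out, int(count)


def _dropout_mask(rng: np.random.Generator, n: int, fs: float,
                  fraction: float, floor: float = 0.05,
                  ramp_s: float = 0.2) -> np.ndarray:
    """One contiguous attenuation window covering ``fraction`` of the epoch,
    with cosine ramps to limit spectral splatter."""
    mask = np.ones(n)
    d = int(round(fraction * n))
    if d == 0:
        return mask
    start = int(rng.integers(0, n - d + 1))
    mask[start:start + d] = floor
    ramp = max(1, int(ramp_s * fs))
    ramp = min(ramp, d // 2) or 1
    up = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp)))
    mask[start:start + ramp] = floor + (1 - floor) * up
    mask[start + d - ramp:start + d] = floor + (1 - floor) * up[::-1]
    return mask


def solve_envelope_mixing(u1: np.ndarray, u2: np.ndarray, common: np.ndarray,
                          target: float) -> float:
    """Mixing weight w such that corr((1-w)u1 + w*common, (1-w)u2 + w*common)
    equals ``target`` exactly on the given samples.

    Solved numerically (Brent) on [0, 1]; w=1 collapses both envelopes onto
    the common modulator (correlation 1).
    """

    def corr_at(w: float) -> float:
        e1 = (1 - w) * u1 + w * common
        e2 = (1 - w) * u2 + w * common
        return float(np.corrcoef(e1, e2)[0, 1])

    if target >= 1.0:
        return 1.0
    f = lambda w: corr_at(w) - target
    lo, hi = 0.0, 1.0
    if f(lo) >= 0:  # residual modulators happen to correlate above target
        return 0.0
    return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-10))


def envelope_coupled_pair(
    rng: np.random.Generator,
    n: int,
    fs: float,
    carrier_band: BandDefinition,
    target_corr: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two narrowband signals with envelope correlation ``target_corr``.

    Carriers have independent phases; the envelopes are mixes of a common
    and two independent slow modulators, with the mixing weight solved so
    that the sample correlation of the *planted* envelopes equals the target
    exactly.  Returns (x1, x2, env1, env2).
    """
    u1 = _slow_modulator(rng, n, fs)
    u2 = _slow_modulator(rng, n, fs)
    common = _slow_modulator(rng, n, fs)
    w = solve_envelope_mixing(u1, u2, common, target_corr)
    e1 = (1 - w) * u1 + w * common
    e2 = (1 - w) * u2 + w * common
    fc = 0.5 * (carrier_band.f_lo + carrier_band.f_hi)
    t = np.arange(n) / fs
    # quadrature carriers: a zero-lag (collinear) pair is exactly what the
    # orthogonalization discards, so the shared-envelope pair is planted at
    # a 90-degree carrier lag, the configuration the corrected AEC detects;
    # small independent phase jitter avoids a perfectly rigid relation
    jitter_scale = 0.02
    ph1 = 2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi) + np.cumsum(
        rng.standard_normal(n)) * jitter_scale / np.sqrt(fs)
    ph2 = ph1 + np.pi / 2 + np.cumsum(
        rng.standard_normal(n)) * jitter_scale / np.sqrt(fs)
    return e1 * np.cos(ph1), e2 * np.cos(ph2), e1, e2


def phase_lag_pair(
    rng: np.random.Generator,
    n: int,
    fs: float,
    carrier_band: BandDefinition,
    lag_radians: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two signals sharing one narrowband carrier at a constant phase lag."""
    fc = 0.5 * (carrier_band.f_lo + carrier_band.f_hi)
    t = np.arange(n) / fs
    env = _slow_modulator(rng, n, fs, depth=0.3)
    phase = 2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi)
    return env * np.cos(phase), env * np.cos(phase - lag_radians)


# ---------------------------------------------------------------------------
# EOG and epoch assembly


def generate_eog(
    profile: StateProfile, length: int, fs: float, seed_or_rng
) -> np.ndarray:
    """One EOG epoch matching the state.

    Eyes-open: blink transients at the profile's rate.  Drowsy: slow
    (~0.3 Hz) roving-eye waves of amplitude ``sem_amp``.  Alert: quiet
    low-amplitude noise.
    """
    if length <= 0:
        raise ArgumentError("length must be positive")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    noise = 0.05 * rng.standard_normal(length)
    if profile.state == StateLabel.EO and profile.blink_rate > 0:
        blinks, _ = _blink_train(rng, length, fs, profile.blink_rate, amp=12.0)
        return noise + blinks
    if profile.state == StateLabel.D_EC and profile.sem_amp > 0:
        t = np.arange(length) / fs
        f_sem = rng.uniform(0.2, 0.5)  # slow roving eye movements, <1 Hz
        phase = 2 * np.pi * f_sem * t + rng.uniform(0, 2 * np.pi)
        am = _slow_modulator(rng, length, fs, depth=0.3)
        return noise + profile.sem_amp * am * np.sin(phase)
    return noise


#: Alpha weight of non-posterior ROIs relative to the posterior set.
NONPOSTERIOR_ALPHA_WEIGHT = 0.4

#: Band carrying the posterior dominant rhythm (centered on ~10 Hz).
ALPHA_CARRIER = (8.5, 11.5)

#: Band carrying theta activity.  Spans the full canonical theta band so
#: that theta amplitude changes rescale the in-band spectrum without
#: reshaping it (a reshaped within-band spectrum would shift the
#: finite-sample bias of phase-based connectivity estimates between states).
THETA_CARRIER = (4.0, 8.0)

#: Variance fraction of the alpha rhythm shared (zero-lag) across ROIs.
#: A partially spatially coherent posterior rhythm matches eyes-closed
#: electrophysiology; a zero-lag common component is invisible to the PLI
#: by construction.
ALPHA_COHERENCE = 0.5


def _generate_epoch(
    profile: StateProfile,
    rng: np.random.Generator,
    n_rois: int,
    length: int,
    fs: float,
    posterior: np.ndarray,
    frontal: np.ndarray,
    couplings: list[CouplingSpec],
) -> np.ndarray:
    """(n_rois x length) ROI signals for one epoch."""
    x = one_over_f_noise(rng, (n_rois, length), gamma=1.0)

    shared = narrowband_oscillation(rng, (length,), *ALPHA_CARRIER, fs)
    indep = narrowband_oscillation(rng, (n_rois, length), *ALPHA_CARRIER, fs)
    alpha = np.sqrt(ALPHA_COHERENCE) * shared + np.sqrt(1 - ALPHA_COHERENCE) * indep
    weights = np.full(n_rois, NONPOSTERIOR_ALPHA_WEIGHT)
    weights[posterior] = 1.0
    if profile.state == StateLabel.D_EC:
        alpha = alpha * _dropout_mask(rng, length, fs, profile.dropout_fraction)
    x += profile.alpha_amp * weights[:, None] * alpha

    theta = narrowband_oscillation(rng, (n_rois, length), *THETA_CARRIER, fs)
    x += profile.theta_amp * theta

    if profile.state == StateLabel.EO and profile.blink_rate > 0:
        blinks, _ = _blink_train(rng, length, fs, profile.blink_rate, amp=6.0)
        x[frontal] += blinks

    for spec in couplings:
        i, j = spec.roi_pair
        if spec.kind == "phase_lag":
            s_i, s_j = phase_lag_pair(rng, length, fs, spec.carrier_band,
                                      spec.lag_radians)
        else:
            s_i, s_j, _, _ = envelope_coupled_pair(
                rng, length, fs, spec.carrier_band, spec.envelope_corr)
        x[i] += spec.amplitude * s_i
        x[j] += spec.amplitude * s_j
    return x


def generate_recording(
    profiles: list[tuple[StateProfile, int]],
    couplings: list[CouplingSpec] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    roi_labels: tuple[str, ...] = AAL78_LABELS,
    subject_id: str = "sim",
    with_eog: bool = True,
) -> tuple[Recording, list[StateLabel]]:
    """Generate a labelled multi-state recording.

    ``profiles`` is an ordered list of (StateProfile, n_epochs); epochs are
    laid out in that order on the epoch grid.  Returns the recording (EOG
    appended as the last channel when ``with_eog``) and the true per-epoch
    state labels.  Bit-identical output for identical arguments.
    """
    if not profiles:
        raise ArgumentError("need at least one (profile, n_epochs) entry")
    for _, n_ep in profiles:
        if n_ep < 1:
            raise ArgumentError("every profile needs n_epochs >= 1")
    config = config or PipelineConfig()
    couplings = list(couplings or [])
    length, fs = config.epoch_length, config.fs
    n_rois = len(roi_labels)
    for spec in couplings:
        if max(spec.roi_pair) >= n_rois:
            raise ArgumentError(f"coupling {spec.roi_pair} outside {n_rois} ROIs")
    posterior = np.asarray(
        match_labels(roi_labels, config.posterior_patterns), dtype=int)
    frontal = np.asarray(
        match_labels(roi_labels, config.frontal_patterns), dtype=int)
    rng = np.random.default_rng(seed)

    blocks: list[np.ndarray] = []
    eog_blocks: list[np.ndarray] = []
    labels: list[StateLabel] = []
    for profile, n_ep in profiles:
        for _ in range(n_ep):
            blocks.append(_generate_epoch(
                profile, rng, n_rois, length, fs, posterior, frontal, couplings))
            if with_eog:
                eog_blocks.append(generate_eog(profile, length, fs, rng))
            labels.append(profile.state)

    data = np.concatenate(blocks, axis=1)
    all_labels = list(roi_labels)
    eog_index = None
    if with_eog:
        data = np.vstack([data, np.concatenate(eog_blocks)])
        all_labels.append("EOG")
        eog_index = n_rois
    rec = Recording(data=data, fs=fs, roi_labels=all_labels,
                    eog_index=eog_index, subject_id=subject_id)
    return rec, labels


def standard_session(
    n_epochs_per_state: int = 5,
    couplings: list[CouplingSpec] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    roi_labels: tuple[str, ...] = AAL78_LABELS,
    subject_id: str = "sim",
) -> tuple[Recording, list[StateLabel]]:
    """An eyes-open block followed by interleaved alert/drowsy eyes-closed
    epochs, mirroring the recording protocol (EO first, then eyes closed)."""
    p = default_profiles()
    profiles = [(p[StateLabel.EO], n_epochs_per_state)]
    for _ in range(n_epochs_per_state):
        profiles.append((p[StateLabel.A_EC], 1))
        profiles.append((p[StateLabel.D_EC], 1))
    return generate_recording(profiles, couplings, config, seed,
                              roi_labels, subject_id)
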