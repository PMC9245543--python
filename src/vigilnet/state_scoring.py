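"""Rule-based vigilance-state scoring of epochs.

Operationalizes the visual scoring criteria: an epoch from the eyes-closed
block is *drowsy* (D-EC) when it shows a transient alpha dropout (covering
less than half the epoch), elevated theta power relative to the other
eyes-closed epochs of the same recording, and/or slow roving eye movements
on the EOG -- the three criteria combined by logical OR.  Epochs whose
dropout reaches 50% of the epoch meet NREM1 sleep territory and are flagged
``SLEEP-BOUNDARY`` and excluded from the drowsy class.  Epochs without a
visible posterior dominant rhythm but with blink transients are protocol
deviations (eyes opened during the eyes-closed block).  Everything else is
alert eyes-closed (A-EC).  Epochs from the eyes-open block are labelled EO.

Feature extraction uses only the spectral and connectivity primitives: the
alpha envelope is the Hilbert envelope of the 8-13 Hz brickwall-filtered
posterior mean signal, smoothed over 0.5 s; "dropout" samples fall below a
configurable fraction (default 0.35) of the epoch's own median envelope,
a relative-to-self criterion robust across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .connectivity import analytic_signal
from .core_io import (
    ArgumentError,
    BandDefinition,
    Epoch,
    PipelineConfig,
    Recording,
    StateLabel,
    VigilnetError,
    match_labels,
    segment_epochs,
)
from .spectral import band_power, brickwall_filter, relative_power


class ConfigurationError(VigilnetError):
    """The recording lacks something the scorer needs (posterior ROI set)."""


#: The full alpha range used for the posterior-rhythm envelope.
ALPHA_BAND = BandDefinition("alpha", 8.0, 13.0)

#: Sub-1 Hz band quantifying slow eye movements on the EOG.
SEM_BAND = BandDefinition("sem", 0.1, 1.0)

#: Band used for blink detection on the EOG.
BLINK_BAND = BandDefinition("blink", 0.5, 5.0)


@dataclass
class EpochFeatures:
    """Per-epoch scoring features."""

    alpha_dropout_frac: float
    theta_rel_power: float
    theta_z: float            # filled in at recording level; NaN until then
    pdr_visible: bool
    blink_count: int
    sem_power: float
    sem_ratio: float          # sem_power / recording median; NaN until then


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def alpha_envelope(
    epoch_roi_data: np.ndarray,
    posterior_idx: np.ndarray,
    fs: float,
    smooth_s: float = 0.5,
) -> np.ndarray:
    """Smoothed alpha-band Hilbert envelope of the posterior mean signal."""
    post_mean = epoch_roi_data[posterior_idx].mean(axis=0)
    filt = brickwall_filter(post_mean, ALPHA_BAND, fs)
    env = np.abs(analytic_signal(filt))
    return _smooth(env, int(round(smooth_s * fs)))


def detect_blinks(
    eog: np.ndarray,
    fs: float,
    threshold: float,
    refractory_s: float = 0.4,
) -> int:
    """Count blink transients: peaks of the 0.5-5 Hz-filtered |EOG| above
    ``threshold``, at least ``refractory_s`` apart."""
    filt = brickwall_filter(eog, BLINK_BAND, fs)
    peaks, _ = scipy.signal.find_peaks(
        np.abs(filt), height=threshold,
        distance=max(1, int(refractory_s * fs)),
    )
    return int(len(peaks))


def extract_features(
    epoch: Epoch,
    config: PipelineConfig | None = None,
    blink_threshold: float | None = None,
) -> EpochFeatures:
    """Scoring features of one epoch.

    ``theta_z`` and ``sem_ratio`` need recording-level context and are NaN
    here; :func:`score_recording` fills them in.  ``blink_threshold`` is an
    absolute EOG amplitude; when None it defaults to ``blink_mad_factor``
    times the epoch's own median absolute EOG deviation.
    """
    config = config or PipelineConfig()
    data = epoch.roi_data
    fs = epoch.fs
    posterior = np.asarray(
        match_labels(epoch.parent.roi_names, config.posterior_patterns), dtype=int)
    if posterior.size == 0:
        raise ConfigurationError(
            "no posterior ROIs match the configured label patterns"
        )

    env = alpha_envelope(data, posterior, fs, config.envelope_smooth_s)
    med = np.median(env)
    dropout_frac = float(np.mean(env < config.dropout_env_threshold * med)) \
        if med > 0 else 1.0

    # mean posterior per-ROI relative alpha power decides whether a PDR is
    # visible (per-ROI fractions, so spatially coherent components do not
    # dominate the way they would in the posterior mean signal)
    rel = relative_power(data, config.bands, fs)
    alpha_frac = float((rel[posterior, 2] + rel[posterior, 3]).mean())
    theta_frac = float(rel[:, 1].mean())
    pdr_visible = alpha_frac >= config.pdr_alpha_floor

    blink_count = 0
    sem_power = 0.0
    eog = epoch.eog
    if eog is not None:
        if blink_threshold is None:
            mad = float(np.median(np.abs(eog - np.median(eog))))
            blink_threshold = config.blink_mad_factor * max(mad, 1e-12)
        blink_count = detect_blinks(eog, fs, blink_threshold,
                                    config.blink_refractory_s)
        sem_power = float(band_power(eog, SEM_BAND, fs))

    return EpochFeatures(
        alpha_dropout_frac=dropout_frac,
        theta_rel_power=theta_frac,
        theta_z=float("nan"),
        pdr_visible=pdr_visible,
        blink_count=blink_count,
        sem_power=sem_power,
        sem_ratio=float("nan"),
    )


def classify_epoch(
    f: EpochFeatures,
    part: str,
    config: PipelineConfig | None = None,
) -> StateLabel:
    """Assign a state label from features.

    ``part`` is ``"eyes_open_block"`` or ``"eyes_closed_block"``.  In the
    eyes-open block every epoch is EO.  In the eyes-closed block: missing
    posterior rhythm plus blinks marks a protocol deviation
    (EC-EYES-OPENED); dropout >= 50% of the epoch marks the sleep boundary
    (excluded); otherwise an epoch is drowsy if any of the three drowsiness
    criteria holds (dropout, theta elevation, slow eye movements), else
    alert.  A pure function of (features, thresholds).
    """
    config = config or PipelineConfig()
    if part == "eyes_open_block":
        return StateLabel.EO
    if part != "eyes_closed_block":
        raise ArgumentError(f"unknown recording part {part!r}")
    if not f.pdr_visible and f.blink_count > 0:
        return StateLabel.EC_EYES_OPENED
    if f.alpha_dropout_frac >= 0.5:
        return StateLabel.SLEEP_BOUNDARY
    dropout_crit = config.dropout_min_fraction <= f.alpha_dropout_frac < 0.5
    theta_crit = np.isfinite(f.theta_z) and f.theta_z >= config.theta_z_threshold
    sem_crit = np.isfinite(f.sem_ratio) and f.sem_ratio >= config.sem_power_factor
    if dropout_crit or theta_crit or sem_crit:
        return StateLabel.D_EC
    return StateLabel.A_EC


def score_recording(
    rec: Recording,
    n_eo_epochs: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[list[StateLabel], pd.DataFrame]:
    """Score every epoch of a recording.

    The first ``n_eo_epochs`` epochs belong to the eyes-open block (the
    protocol records eyes open first); the rest to the eyes-closed block.
    Theta z-scores are computed against all eyes-closed-block epochs of this
    recording, the slow-eye-movement ratio against the recording's median
    sub-1 Hz EOG power, and the blink threshold against the recording-level
    EOG amplitude scale.  Returns (labels, feature table).
    """
    config = config or PipelineConfig()
    epochs = segment_epochs(rec, config.epoch_length)
    if not epochs:
        raise ArgumentError("recording shorter than one epoch")

    blink_threshold = None
    if rec.eog is not None:
        mad = float(np.median(np.abs(rec.eog - np.median(rec.eog))))
        blink_threshold = config.blink_mad_factor * max(mad, 1e-12)

    feats = [extract_features(ep, config, blink_threshold) for ep in epochs]

    ec = list(range(n_eo_epochs, len(epochs)))
    theta = np.array([feats[k].theta_rel_power for k in ec])
    if len(ec) >= 2 and theta.std() > 0:
        z = (theta - theta.mean()) / theta.std()
        for k, zk in zip(ec, z):
            feats[k].theta_z = float(zk)
    if rec.eog is not None and ec:
        med_sem = float(np.median([feats[k].sem_power for k in ec]))
        for k in ec:
            feats[k].sem_ratio = feats[k].sem_power / max(med_sem, 1e-300)

    labels = [
        classify_epoch(
            f, "eyes_open_block" if k < n_eo_epochs else "eyes_closed_block",
            config,
        )
        for k, f in enumerate(feats)
    ]
    table = pd.DataFrame(
        [{
            "epoch_index": k,
            "state": lab.value,
            "alpha_dropout_frac": f.alpha_dropout_frac,
            "theta_rel_power": f.theta_rel_power,
            "theta_z": f.theta_z,
            "pdr_visible": f.pdr_visible,
            "blink_count": f.blink_count,
            "sem_power": f.sem_power,
            "sem_ratio": f.sem_ratio,
        } for k, (lab, f) in enumerate(zip(labels, feats))]
    )
    return labels, table


def round_half_up_percent(count: int, total: int) -> int:
    """Percentage rounded half-up (so 54.76% -> 55, 0.5 rounds up)."""
    if total <= 0:
        raise ArgumentError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def scoring_report(
    labels: list[StateLabel],
    n_eo_epochs: int | None = None,
) -> dict:
    """Counts and round-half-up percentages per state.

    The percentage denominator is the number of scored *eyes-closed* epochs
    (EO-block epochs are excluded; with the study's printed counts, 793
    drowsy of 1,448 eyes-closed epochs gives 55%).  ``n_eo_epochs`` defaults
    to the number of EO labels.
    """
    if not labels:
        raise ArgumentError("need at least one labelled epoch")
    if n_eo_epochs is None:
        n_eo_epochs = sum(1 for lab in labels if lab == StateLabel.EO)
    ec_labels = [lab for lab in labels if lab != StateLabel.EO]
    total_ec = len(ec_labels)
    counts: dict[str, int] = {}
    for lab in ec_labels:
        counts[lab.value] = counts.get(lab.value, 0) + 1
    percent = {
        k: round_half_up_percent(v, total_ec) for k, v in counts.items()
    } if total_ec else {}
    return {
        "n_epochs": len(labels),
        "n_eyes_open": n_eo_epochs,
        "n_eyes_closed_scored": total_ec,
        "counts": counts,
        "percent": percent,
    }


def sufficiency_check(
    labels_by_subject: dict[str, list[StateLabel]],
    n_required: int = 5,
    states: tuple[StateLabel, ...] = (StateLabel.EO, StateLabel.A_EC, StateLabel.D_EC),
) -> dict[str, bool]:
    """Per-subject check for at least ``n_required`` epochs in every state."""
    out = {}
    for subject, labels in labels_by_subject.items():
        out[subject] = all(
            sum(1 for lab in labels if lab == s) >= n_required for s in states
        )
    return out
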