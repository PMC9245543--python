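"""Domain types and file I/O shared by every analysis stage.

A *recording* is a labelled multichannel source-space ROI time series
(optionally with one EOG channel) with an explicit sampling rate.  On disk a
recording is a tab-delimited text matrix (``<name>.tsv``, channels x samples)
plus a JSON sidecar (``<name>.json``) carrying the sampling rate, channel
labels, the EOG channel index and a subject identifier.  The text format is
canonical: it is diffable, reviewable and round-trips to the declared
precision.

Analyses operate on non-overlapping *epochs* of 4,096 samples.  At the
default sampling rate of 312.5 Hz (1,250 Hz downsampled by 4) one epoch
spans exactly 13.1072 s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger("vigilnet")

#: Minimum number of samples a recording must contain (one epoch).
MIN_SAMPLES = 4096

#: Default epoch length in samples.
EPOCH_LENGTH = 4096

#: Default sampling rate in Hz (1,250 Hz acquisition downsampled by 4).
DEFAULT_FS = 312.5


class VigilnetError(Exception):
    """Base class for all package errors."""


class FormatError(VigilnetError):
    """A recording file or sidecar is missing or malformed."""


class ConsistencyError(VigilnetError):
    """Metadata disagrees with the data it describes."""


class ArgumentError(VigilnetError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(VigilnetError):
    """Input is valid but degenerate (e.g. zero variance where spread is required)."""


class StateLabel(str, Enum):
    """Per-epoch vigilance-state label.

    ``EO``
        eyes-open condition (first block of the protocol).
    ``A_EC``
        alert eyes-closed resting state: clear posterior dominant rhythm,
        no dropout, no slowing.
    ``D_EC``
        drowsy eyes-closed: transient alpha dropout (<50% of the epoch),
        elevated theta and/or slow roving eye movements, below the NREM1
        sleep boundary.
    ``ARTIFACT``
        excluded for a technical/physiological artifact.
    ``EC_EYES_OPENED``
        protocol deviation: the subject opened the eyes during the
        eyes-closed block.
    ``SLEEP_BOUNDARY``
        alpha dropout covering >=50% of the epoch; such epochs meet NREM1
        territory and are excluded from the drowsy class.
    """

    EO = "EO"
    A_EC = "A-EC"
    D_EC = "D-EC"
    ARTIFACT = "ARTIFACT"
    EC_EYES_OPENED = "EC-EYES-OPENED"
    SLEEP_BOUNDARY = "SLEEP-BOUNDARY"


@dataclass(frozen=True)
class BandDefinition:
    """One frequency band, half-open interval [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ArgumentError(
                f"band {self.name}: need 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi})"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name} ({self.f_lo}-{self.f_hi} Hz)"


#: The six canonical EEG/MEG bands: contiguous, non-overlapping under the
#: half-open convention, jointly spanning 0.5-48 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


# 78 cortical regions of the AAL atlas: the 90-region parcellation minus the
# six bilateral subcortical structures (hippocampus, amygdala, caudate,
# putamen, pallidum, thalamus).
_AAL_PAIR_STEMS = (
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "ParaHippocampal",
    "Calcarine", "Cuneus", "Lingual", "Occipital_Sup", "Occipital_Mid",
    "Occipital_Inf", "Fusiform", "Postcentral", "Parietal_Sup",
    "Parietal_Inf", "SupraMarginal", "Angular", "Precuneus",
    "Paracentral_Lobule", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
)

AAL78_LABELS: tuple[str, ...] = tuple(
    f"{stem}_{side}" for stem in _AAL_PAIR_STEMS for side in ("L", "R")
)
assert len(AAL78_LABELS) == 78

#: Label substrings identifying the posterior (occipito-parietal) ROI set
#: carrying the posterior dominant rhythm.
POSTERIOR_PATTERNS: tuple[str, ...] = (
    "Occipital", "Calcarine", "Cuneus", "Lingual", "Parietal",
    "SupraMarginal", "Angular",
)

#: Label substrings identifying frontal ROIs (eye-blink artifact projection).
FRONTAL_PATTERNS: tuple[str, ...] = ("Frontal", "Rectus", "Olfactory")


def match_labels(labels: Sequence[str], patterns: Sequence[str]) -> list[int]:
    """Indices of ``labels`` containing any of the given substrings."""
    return [i for i, lab in enumerate(labels)
            if any(p.lower() in lab.lower() for p in patterns)]


@dataclass
class Recording:
    """A labelled multichannel time series with sampling rate.

    ``data`` has shape (n_channels, n_samples); ``roi_labels`` names every
    row.  If ``eog_index`` is set, that row is the EOG channel and is
    excluded from the ROI analyses; all remaining rows are cortical ROIs.
    """

    data: np.ndarray
    fs: float
    roi_labels: list[str]
    eog_index: int | None = None
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConsistencyError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ConsistencyError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[1] < MIN_SAMPLES:
            raise ConsistencyError(
                f"recording has {self.data.shape[1]} samples; "
                f"need at least {MIN_SAMPLES} (one epoch)"
            )
        if len(self.roi_labels) != self.data.shape[0]:
            raise ConsistencyError(
                f"{len(self.roi_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ConsistencyError("channel labels must be unique")
        if self.eog_index is not None and not (
            0 <= self.eog_index < self.data.shape[0]
        ):
            raise ConsistencyError(f"eog_index {self.eog_index} out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def roi_indices(self) -> list[int]:
        """Row indices counting toward the ROI analyses (EOG excluded)."""
        return [i for i in range(self.n_channels) if i != self.eog_index]

    @property
    def roi_data(self) -> np.ndarray:
        """(n_roi, n_samples) view of the cortical ROI rows."""
        return self.data[self.roi_indices]

    @property
    def roi_names(self) -> list[str]:
        return [self.roi_labels[i] for i in self.roi_indices]

    @property
    def eog(self) -> np.ndarray | None:
        return None if self.eog_index is None else self.data[self.eog_index]


@dataclass
class Epoch:
    """One analysis window on a parent recording."""

    parent: Recording
    start_sample: int
    length: int = EPOCH_LENGTH
    state: StateLabel | None = None
    index: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ArgumentError(f"epoch length must be positive, got {self.length}")
        if self.start_sample < 0 or self.start_sample + self.length > self.parent.n_samples:
            raise ConsistencyError(
                f"epoch [{self.start_sample}, {self.start_sample + self.length}) "
                f"outside recording of {self.parent.n_samples} samples"
            )

    @property
    def fs(self) -> float:
        return self.parent.fs

    @property
    def data(self) -> np.ndarray:
        """All channels of this window (including EOG if present)."""
        return self.parent.data[:, self.start_sample:self.start_sample + self.length]

    @property
    def roi_data(self) -> np.ndarray:
        return self.parent.roi_data[:, self.start_sample:self.start_sample + self.length]

    @property
    def eog(self) -> np.ndarray | None:
        e = self.parent.eog
        return None if e is None else e[self.start_sample:self.start_sample + self.length]

    @property
    def duration(self) -> float:
        return epoch_duration(self.length, self.parent.fs)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, JSON-serializable.

    The defaults reproduce the study conditions: six canonical bands, peak
    frequency searched in 4-13 Hz, five epochs per vigilance state per
    subject, FDR correction over 78 regional comparisons at alpha 0.05.
    """

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    peak_range: tuple[float, float] = (4.0, 13.0)
    n_epochs_per_state: int = 5
    alpha_level: float = 0.05
    fdr_m: int = 78
    rng_seed: int = 0
    epoch_length: int = EPOCH_LENGTH
    fs: float = DEFAULT_FS
    # connectivity
    envelope_edge_fraction: float = 1.0 / 16.0
    # state scoring
    dropout_env_threshold: float = 0.5    # fraction of the epoch's median alpha envelope
    dropout_min_fraction: float = 0.2     # minimum dropout fraction counting as drowsy
    envelope_smooth_s: float = 0.5
    theta_z_threshold: float = 1.5
    sem_power_factor: float = 3.0
    pdr_alpha_floor: float = 0.15
    blink_refractory_s: float = 0.4
    blink_mad_factor: float = 5.0
    posterior_patterns: tuple[str, ...] = POSTERIOR_PATTERNS
    frontal_patterns: tuple[str, ...] = FRONTAL_PATTERNS

    def __post_init__(self) -> None:
        if self.n_epochs_per_state < 1:
            raise ArgumentError("n_epochs_per_state must be >= 1")
        lo = min(b.f_lo for b in self.bands)
        hi = max(b.f_hi for b in self.bands)
        if not (lo <= self.peak_range[0] < self.peak_range[1] <= hi):
            raise ArgumentError(
                f"peak_range {self.peak_range} outside band span [{lo}, {hi}]"
            )

    def to_dict(self) -> dict:
        d = {
            "bands": [[b.name, b.f_lo, b.f_hi] for b in self.bands],
            "peak_range": list(self.peak_range),
            "n_epochs_per_state": self.n_epochs_per_state,
            "alpha_level": self.alpha_level,
            "fdr_m": self.fdr_m,
            "rng_seed": self.rng_seed,
            "epoch_length": self.epoch_length,
            "fs": self.fs,
            "envelope_edge_fraction": self.envelope_edge_fraction,
            "dropout_env_threshold": self.dropout_env_threshold,
            "dropout_min_fraction": self.dropout_min_fraction,
            "envelope_smooth_s": self.envelope_smooth_s,
            "theta_z_threshold": self.theta_z_threshold,
            "sem_power_factor": self.sem_power_factor,
            "pdr_alpha_floor": self.pdr_alpha_floor,
            "blink_refractory_s": self.blink_refractory_s,
            "blink_mad_factor": self.blink_mad_factor,
            "posterior_patterns": list(self.posterior_patterns),
            "frontal_patterns": list(self.frontal_patterns),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(BandDefinition(*b) for b in d["bands"])
        for key in ("peak_range", "posterior_patterns", "frontal_patterns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        try:
            d = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise FormatError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(d)


def epoch_duration(length: int, fs: float) -> float:
    """Duration in seconds of ``length`` samples at rate ``fs``.

    4,096 samples at 312.5 Hz (1,250 Hz / 4) give exactly 13.1072 s.
    """
    if fs <= 0:
        raise ArgumentError(f"sampling rate must be positive, got {fs}")
    return length / fs


def segment_epochs(rec: Recording, length: int = EPOCH_LENGTH) -> list[Epoch]:
    """Split a recording into consecutive non-overlapping epochs.

    The grid starts at sample 0; trailing samples that do not fill a whole
    epoch are discarded.  Returns ``floor(n_samples / length)`` epochs.
    """
    if length <= 0:
        raise ArgumentError(f"epoch length must be positive, got {length}")
    if length > rec.n_samples:
        return []
    n = rec.n_samples // length
    return [
        Epoch(parent=rec, start_sample=k * length, length=length, index=k)
        for k in range(n)
    ]


# text precision of the on-disk matrix: 10 significant digits
_FMT = "%.10g"


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.tsv`` (matrix) and ``<path>.json`` (sidecar)."""
    base = Path(path)
    if base.suffix == ".tsv":
        base = base.with_suffix("")
    tsv = base.with_suffix(".tsv")
    sidecar = base.with_suffix(".json")
    np.savetxt(tsv, rec.data, fmt=_FMT, delimiter="\t")
    sidecar.write_text(json.dumps({
        "fs_hz": rec.fs,
        "labels": list(rec.roi_labels),
        "eog_index": rec.eog_index,
        "subject_id": rec.subject_id,
    }, indent=2))
    logger.info("wrote recording %s (%d ch x %d samples)", tsv, *rec.data.shape)
    return tsv, sidecar


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may name the ``.tsv``, the ``.json`` or the common stem.
    Raises :class:`FormatError` if either file is missing or unparsable and
    :class:`ConsistencyError` if the sidecar disagrees with the matrix.
    """
    base = Path(path)
    if base.suffix in (".tsv", ".json"):
        base = base.with_suffix("")
    tsv = base.with_suffix(".tsv")
    sidecar = base.with_suffix(".json")
    if not tsv.exists():
        raise FormatError(f"missing data matrix {tsv}")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("fs_hz", "labels"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key '{key}'")
    data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    return Recording(
        data=data,
        fs=float(meta["fs_hz"]),
        roi_labels=list(meta["labels"]),
        eog_index=meta.get("eog_index"),
        subject_id=meta.get("subject_id", "anon"),
    )


def configure_logging(verbose: bool = False) -> None:
    """Timestamped log lines to stderr; ``verbose`` raises the level."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
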