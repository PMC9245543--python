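"""Epoch-level functional connectivity: PLI and orthogonalized AEC.

Both measures start from the analytic signal of the band-filtered series
(Hilbert transform): its modulus is the amplitude envelope, its argument
the instantaneous phase.

The phase lag index (PLI) quantifies the asymmetry of the distribution of
instantaneous phase differences::

    PLI = | mean_t sign(sin(phi_i(t) - phi_j(t))) |

with sign(0) = 0.  A constant nonzero lag gives 1; zero-lag (or anti-phase)
coupling -- the signature of volume conduction / field spread -- gives 0.

The corrected amplitude envelope correlation (AECc) removes, at every
sample, the component of one analytic signal collinear with the other
(pairwise orthogonalization), correlates the resulting envelopes, repeats
with the roles swapped and averages the two Pearson coefficients.  The raw
value in [-1, 1] is mapped to [0, 1] via (r + 1)/2, so that independent
signals score ~0.5 and a pure common source scores ~0.5 as well (its
orthogonalized residual carries no shared envelope).

To suppress Hilbert edge artifacts, the first and last 1/16 of the envelope
samples are excluded from the correlations (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core_io import (
    ArgumentError,
    BandDefinition,
    DegenerateInputError,
    Epoch,
    PipelineConfig,
)
from .spectral import brickwall_filter

#: Fraction of samples trimmed from each end of the envelopes before
#: computing amplitude correlations.
DEFAULT_EDGE_FRACTION = 1.0 / 16.0


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal (Hilbert transform) of an already band-limited series.

    Acts along the last axis; returns a complex array of the same shape.
    """
    x = np.asarray(x, dtype=float)
    return scipy.signal.hilbert(x, axis=-1)


#: Sine magnitudes at or below this are numerical zeros: sign(0) = 0.
_SIN_TOL = 1e-12


def pli(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """Phase lag index of two instantaneous-phase series.

    ``|mean sign(sin(phase_i - phase_j))|``; invariant to adding a common
    constant to both series and to swapping the inputs.
    """
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape:
        raise ArgumentError(
            f"phase series lengths differ: {phase_i.shape} vs {phase_j.shape}"
        )
    if phase_i.shape[-1] < 2:
        raise ArgumentError("need at least 2 samples")
    s = np.sin(phase_i - phase_j)
    # exact-zero (and floating-point-zero) phase differences contribute 0
    s = np.where(np.abs(s) <= _SIN_TOL, 0.0, s)
    return float(np.abs(np.mean(np.sign(s))))


def _trim(n: int, edge_fraction: float) -> slice:
    k = int(n * edge_fraction)
    return slice(k, n - k if k > 0 else n)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when either side has (numerically) zero variance.

    A zero-variance *residual* envelope arises from exact collinearity of
    the inputs: no shared envelope structure remains, so its correlation is
    taken as 0 by convention.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def _orthogonalized_envelope(z: np.ndarray, z_ref: np.ndarray) -> np.ndarray:
    """Envelope of ``z`` after removing its component collinear with ``z_ref``.

    Sample-wise: the part of z(t) along the unit phasor of z_ref(t) is
    discarded; what remains is |Im(z(t) * conj(z_ref(t)) / |z_ref(t)||)|.
    Supports a (channels x samples) ``z`` against a single reference row.
    """
    mod = np.abs(z_ref)
    if np.any(mod == 0):
        raise DegenerateInputError("reference analytic signal vanishes at some sample")
    unit = z_ref / mod
    return np.abs(np.imag(z * np.conj(unit)))


_RESIDUAL_TOL = 1e-9


def _negligible(residual: np.ndarray, envelope: np.ndarray) -> bool:
    """True when a residual envelope is float noise relative to the signal."""
    ref = np.sqrt(np.mean(envelope ** 2, axis=-1))
    rms = np.sqrt(np.mean(residual ** 2, axis=-1))
    return bool(np.all(rms <= _RESIDUAL_TOL * ref))


def aec_orthogonalized(
    x_i: np.ndarray,
    x_j: np.ndarray,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
    rescale: bool = True,
) -> float:
    """Corrected amplitude envelope correlation of two band-filtered series.

    Orthogonalizes each analytic signal with respect to the other,
    correlates envelopes in both directions and averages.  With
    ``rescale=True`` (default) the raw mean correlation in [-1, 1] is mapped
    to [0, 1] as (r + 1)/2.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ArgumentError("series lengths differ")
    z_i = analytic_signal(x_i)
    z_j = analytic_signal(x_j)
    sl = _trim(x_i.shape[-1], edge_fraction)
    env_i = np.abs(z_i)[sl]
    env_j = np.abs(z_j)[sl]
    if env_i.std() == 0 or env_j.std() == 0:
        raise DegenerateInputError("input envelope has zero variance")
    res_ji = _orthogonalized_envelope(z_j, z_i)[sl]
    res_ij = _orthogonalized_envelope(z_i, z_j)[sl]
    # residuals that are pure floating-point residue of an exactly collinear
    # pair carry no envelope structure: their correlation is 0 by convention
    r1 = 0.0 if _negligible(res_ji, env_j) else _pearson(env_i, res_ji)
    r2 = 0.0 if _negligible(res_ij, env_i) else _pearson(env_j, res_ij)
    raw = 0.5 * (r1 + r2)
    return 0.5 * (raw + 1.0) if rescale else raw


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI connectivity for one epoch, band and measure."""

    values: np.ndarray
    measure: str  # "PLI" or "AECc"
    band: BandDefinition
    epoch_ref: Epoch | None = None
    roi_labels: list[str] | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _pli_matrix(z: np.ndarray) -> np.ndarray:
    """All-pairs PLI from analytic signals (n_ch x n_samples)."""
    n = z.shape[0]
    out = np.zeros((n, n))
    mod = np.abs(z)
    mod[mod == 0] = 1.0
    u = z / mod  # unit phasors: Im(u_j * conj(u_i)) = sin(phi_j - phi_i)
    for i in range(n - 1):
        s = np.imag(u[i + 1:] * np.conj(u[i]))
        s = np.where(np.abs(s) <= _SIN_TOL, 0.0, s)
        vals = np.abs(np.sign(s).mean(axis=-1))
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    return out


def _aecc_matrix(z: np.ndarray, edge_fraction: float) -> np.ndarray:
    """All-pairs rescaled AECc from analytic signals (n_ch x n_samples)."""
    n, t = z.shape
    sl = _trim(t, edge_fraction)
    env = np.abs(z)[:, sl]
    envc = env - env.mean(axis=-1, keepdims=True)
    env_norm = np.sqrt((envc ** 2).sum(axis=-1))
    r_dir = np.zeros((n, n))  # r_dir[i, j]: corr(env_i, env of z_j orthogonalized to z_i)
    for i in range(n):
        resid = _orthogonalized_envelope(z, z[i])[:, sl]
        residc = resid - resid.mean(axis=-1, keepdims=True)
        resid_norm = np.sqrt((residc ** 2).sum(axis=-1))
        denom = env_norm[i] * resid_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (residc @ envc[i]) / denom
        r[denom == 0] = 0.0
        # collinear channels leave only floating-point residue: no association
        resid_rms = np.sqrt((resid ** 2).mean(axis=-1))
        env_rms = np.sqrt((env ** 2).mean(axis=-1))
        r[resid_rms <= _RESIDUAL_TOL * env_rms] = 0.0
        r_dir[i] = r
    raw = 0.5 * (r_dir + r_dir.T)
    out = 0.5 * (raw + 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def connectivity_matrix(
    epoch: Epoch,
    band: BandDefinition,
    measure: str,
    config: PipelineConfig | None = None,
) -> ConnectivityMatrix:
    """All-pairs functional connectivity of one epoch in one band.

    ``measure`` is ``"PLI"`` or ``"AECc"``.  The returned matrix is
    symmetric with a zero diagonal.
    """
    config = config or PipelineConfig()
    data = epoch.roi_data
    return connectivity_matrix_from_data(
        data, band, measure, epoch.fs,
        edge_fraction=config.envelope_edge_fraction,
        epoch_ref=epoch, roi_labels=epoch.parent.roi_names,
    )


def connectivity_matrix_from_data(
    data: np.ndarray,
    band: BandDefinition,
    measure: str,
    fs: float,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
    epoch_ref: Epoch | None = None,
    roi_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """As :func:`connectivity_matrix` but on a bare (n_roi x n_samples) array."""
    measure = measure.upper().replace("AECC", "AECc")
    if measure not in ("PLI", "AECc"):
        raise ArgumentError(f"unknown measure {measure!r}; expected PLI or AECc")
    filtered = brickwall_filter(np.asarray(data, dtype=float), band, fs)
    z = analytic_signal(filtered)
    if measure == "PLI":
        values = _pli_matrix(z)
    else:
        values = _aecc_matrix(z, edge_fraction)
    return ConnectivityMatrix(
        values=values, measure=measure, band=band,
        epoch_ref=epoch_ref, roi_labels=roi_labels,
    )


def global_and_regional_fc(m: ConnectivityMatrix | np.ndarray) -> tuple[float, np.ndarray]:
    """Global FC (mean of all off-diagonal entries) and regional FC
    (per-ROI mean connectivity to all other ROIs)."""
    values = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ArgumentError("need at least 2 ROIs")
    offdiag_sum = values.sum(axis=1) - np.diag(values)
    regional = offdiag_sum / (n - 1)
    glob = float(regional.mean())
    return glob, regional
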