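"""Raw EEG/GSR -> per-band instantaneous phase.

Pipeline order: zero-mean + linear detrend, decimation to 8 Hz, spherical
spline surface Laplacian (EEG only), narrow-band zero-phase Hamming FIR,
Hilbert phase.  Band b spans [f_b, f_b + band_width] Hz with the nominal
frequency as the lower edge.

The FIR is applied forward-backward (equivalently, convolution with the
filter's autocorrelation) so the passband is phase-neutral; one filter
length at each end of every session is flagged invalid, since filter and
Hilbert transients corrupt phases there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.special import eval_legendre

from .synth import Recording, _wrap

__all__ = [
    "PhaseTensor",
    "detrend_zero_mean",
    "downsample",
    "surface_laplacian",
    "csd_matrices",
    "bandpass_fir",
    "fir_length",
    "hilbert_phase",
    "preprocess_recording",
    "band_edges",
]

DEFAULT_FS_OUT = 8.0
DEFAULT_TRANSITION = 0.005  # Hz
DEFAULT_BAND_WIDTH = 0.01  # Hz
CSD_M = 4
CSD_LAMBDA = 1e-5
CSD_LEGENDRE_ORDER = 50


class InsufficientDataError(ValueError):
    pass


@dataclass
class PhaseTensor:
    """Per-channel, per-band instantaneous phases at the analysis rate.

    ``phases`` has shape (n_channels, n_samples, n_bands), values in
    (-pi, pi].  ``valid_mask`` (n_bands, n_samples) excludes filter/Hilbert
    edge transients.  ``bandpassed`` optionally carries the narrowband
    signals the phases were derived from (needed for functional
    connectivity).
    """

    phases: np.ndarray
    fs: float
    band_edges: list
    valid_mask: np.ndarray
    bandpassed: np.ndarray | None = None

    @property
    def n_channels(self):
        return self.phases.shape[0]

    @property
    def n_bands(self):
        return self.phases.shape[2]


def band_edges(bands, width: float = DEFAULT_BAND_WIDTH, centered: bool = False):
    """(low, high) edges per band; nominal frequency is the lower edge by
    default, or the center when ``centered`` is true."""
    if centered:
        return [(f - width / 2.0, f + width / 2.0) for f in bands]
    return [(f, f + width) for f in bands]


def detrend_zero_mean(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (and hence the mean) from a signal."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise InsufficientDataError("detrending needs at least 3 samples")
    return signal.detrend(x, type="linear", axis=-1)


def downsample(x: np.ndarray, fs_in: float, fs_out: float = DEFAULT_FS_OUT):
    """Anti-aliased decimation (flat-passband Hamming FIR, forward-backward).

    ``fs_in`` must be an integer multiple of ``fs_out``; the anti-alias
    cutoff is 0.4x the output rate, so DC and slow oscillations pass with
    unit gain.  Output length is ceil(n * fs_out/fs_in).
    """
    x = np.asarray(x, dtype=float)
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"fs_in={fs_in} is not an integer multiple of fs_out={fs_out}")
    if q == 1:
        return x.copy()
    ntaps = 30 * q + 1
    b = signal.firwin(ntaps, 0.8 / q)  # cutoff 0.4 * fs_out, Hamming
    bb = np.convolve(b, b)  # forward-backward equivalent, zero phase
    y = signal.fftconvolve(x, bb[None, :] if x.ndim == 2 else bb, mode="full", axes=-1)
    y = y[..., ntaps - 1 : ntaps - 1 + x.shape[-1]]
    return y[..., ::q]


def _legendre_series(cosang: np.ndarray, m: int, order: int):
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, order + 1):
        p_n = eval_legendre(n, cosang)
        denom = float(n * (n + 1)) ** m
        g += (2 * n + 1) / denom * p_n
        h += (2 * n + 1) / (float(n * (n + 1)) ** (m - 1)) * p_n
    return g / (4.0 * np.pi), h / (4.0 * np.pi)


def csd_matrices(
    montage: np.ndarray,
    m: int = CSD_M,
    order: int = CSD_LEGENDRE_ORDER,
):
    """Perrin-style spherical-spline G and H matrices for a unit-sphere montage."""
    montage = np.asarray(montage, dtype=float)
    cosang = np.clip(montage @ montage.T, -1.0, 1.0)
    off = cosang - np.eye(len(montage))
    if np.any(off > 1.0 - 1e-12):
        i, j = np.argwhere(off > 1.0 - 1e-12)[0]
        raise ValueError(f"duplicate electrode positions (channels {i} and {j})")
    return _legendre_series(cosang, m, order)


def surface_laplacian(
    eeg: np.ndarray,
    montage: np.ndarray,
    m: int = CSD_M,
    lam: float = CSD_LAMBDA,
    order: int = CSD_LEGENDRE_ORDER,
) -> np.ndarray:
    """Spherical-spline surface Laplacian (current source density) estimate.

    Solves, per sample, the smoothed spline system with the constant
    constraint (sum of spline coefficients = 0), then evaluates the
    Laplacian through the H kernel.  Spatially constant inputs map to zero
    and a per-sample common offset leaves the output unchanged.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    n_ch = eeg.shape[0]
    if n_ch < 4:
        raise ValueError("surface Laplacian needs at least 4 channels")
    g, h = csd_matrices(montage, m=m, order=order)
    a = np.zeros((n_ch + 1, n_ch + 1))
    a[:n_ch, :n_ch] = g + lam * np.eye(n_ch)
    a[:n_ch, n_ch] = 1.0
    a[n_ch, :n_ch] = 1.0
    rhs = np.vstack([eeg, np.zeros((1, eeg.shape[1]))])
    sol = np.linalg.solve(a, rhs)
    return h @ sol[:n_ch]


def fir_length(fs: float, transition: float = DEFAULT_TRANSITION) -> int:
    """Hamming FIR tap count for a given transition width (odd, ~3.3/df)."""
    n = int(np.ceil(3.3 / transition * fs))
    return n + 1 if n % 2 == 0 else n


def bandpass_fir(
    x: np.ndarray,
    band: tuple,
    fs: float,
    transition: float = DEFAULT_TRANSITION,
) -> np.ndarray:
    """Zero-phase Hamming-window FIR bandpass.

    Forward-backward application is realized as a single convolution with
    the autocorrelation of the FIR kernel; output length equals input
    length.  Samples within one filter length of either end are edge-
    contaminated (see :func:`fir_length`).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2")
    ntaps = fir_length(fs, transition)
    if x.shape[-1] <= ntaps:
        raise InsufficientDataError(
            f"signal ({x.shape[-1]} samples) shorter than filter ({ntaps} taps)"
        )
    # transition bands are centered on the band edges, so the passband
    # [lo, hi] keeps ~unit gain and lo - transition / hi + transition are
    # fully in the stopband
    cut = [max(lo - transition / 2.0, 1e-6), min(hi + transition / 2.0, fs / 2 - 1e-6)]
    b = signal.firwin(ntaps, cut, pass_zero=False, window="hamming", fs=fs)
    bb = np.convolve(b, b)  # symmetric -> zero phase at delay ntaps-1
    y = signal.fftconvolve(x, bb[None, :] if x.ndim == 2 else bb, mode="full", axes=-1)
    start = ntaps - 1
    return y[..., start : start + x.shape[-1]]


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (argument of the analytic signal), in (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("phase undefined for all-zero input")
    return _wrap(np.angle(signal.hilbert(x, axis=-1)))


def preprocess_recording(
    rec: Recording,
    bands,
    fs_out: float = DEFAULT_FS_OUT,
    transition: float = DEFAULT_TRANSITION,
    band_width: float = DEFAULT_BAND_WIDTH,
    centered_bands: bool = False,
    apply_csd: bool = True,
    csd_m: int = CSD_M,
    csd_lambda: float = CSD_LAMBDA,
    csd_order: int = CSD_LEGENDRE_ORDER,
    keep_bandpassed: bool = False,
) -> tuple:
    """Full per-session pipeline; returns (eeg PhaseTensor, gsr PhaseTensor).

    The GSR receives identical detrend/downsample/bandpass/Hilbert treatment
    but never the surface Laplacian (single channel).  Stage failures are
    re-raised with the stage name attached.
    """
    edges = band_edges(bands, width=band_width, centered=centered_bands)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:
            raise type(e)(f"[stage {name}] {e}") from e

    eeg = _stage("detrend", detrend_zero_mean, rec.eeg)
    gsr = _stage("detrend", detrend_zero_mean, rec.gsr)
    if rec.fs != fs_out:
        eeg = _stage("downsample", downsample, eeg, rec.fs, fs_out)
        gsr = _stage("downsample", downsample, gsr, rec.fs, fs_out)
    if apply_csd:
        eeg = _stage(
            "surface_laplacian",
            surface_laplacian,
            eeg,
            rec.montage,
            m=csd_m,
            lam=csd_lambda,
            order=csd_order,
        )

    n = eeg.shape[1]
    n_bands = len(edges)
    ntaps = fir_length(fs_out, transition)
    eeg_ph = np.empty((eeg.shape[0], n, n_bands))
    gsr_ph = np.empty((1, n, n_bands))
    eeg_bp = np.empty_like(eeg_ph) if keep_bandpassed else None
    valid = np.zeros((n_bands, n), dtype=bool)
    for b, edge in enumerate(edges):
        ebp = _stage("bandpass", bandpass_fir, eeg, edge, fs_out, transition)
        gbp = _stage("bandpass", bandpass_fir, gsr, edge, fs_out, transition)
        eeg_ph[:, :, b] = _stage("hilbert", hilbert_phase, ebp)
        gsr_ph[0, :, b] = _stage("hilbert", hilbert_phase, gbp)
        if keep_bandpassed:
            eeg_bp[:, :, b] = ebp
        valid[b, ntaps : n - ntaps] = True

    eeg_pt = PhaseTensor(eeg_ph, fs_out, edges, valid, bandpassed=eeg_bp)
    gsr_pt = PhaseTensor(gsr_ph, fs_out, edges, valid.copy())
    return eeg_pt, gsr_pt
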