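"""Time-frequency decomposition and phase-based connectivity.

Morlet wavelet transform (3-cycle complex wavelets, 4-30 Hz in 1 Hz steps),
event-related desynchronization (ERD, percent power change from a prestimulus
baseline), and the weighted phase-lag index (WPLI) averaged over the alpha
band (8-13 Hz) and the 500-1400 ms post-stimulus window.

WPLI at one time-frequency point over trials k, with cross-spectrum
X_k = c_i(k) * conj(c_j(k)):

    WPLI = | mean_k Im(X_k) |  /  mean_k | Im(X_k) |        (0/0 -> 0)

It is insensitive to zero-lag (volume-conduction) coupling and invariant to
positive rescaling of either channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .epochs import EpochSet

__all__ = [
    "TFDecomposition",
    "ERDMap",
    "ConnectivityMatrix",
    "morlet_wavelet",
    "morlet_transform",
    "compute_erd",
    "compute_wpli",
]

ALPHA_BAND = (8.0, 13.0)
WPLI_WINDOW_MS = (500.0, 1400.0)
ERD_BASELINE_MS = (-624.0, -376.0)


@dataclass
class TFDecomposition:
    """Complex Morlet coefficients, (trials, channels, freqs, times)."""

    coefs: np.ndarray = field(repr=False)
    freqs: np.ndarray
    times_ms: np.ndarray
    n_cycles: float
    channels: tuple[str, ...]
    subject_id: str = ""
    condition: str | None = None

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefs) ** 2

    def edge_guard_ms(self, freq: float) -> float:
        """Half-width (ms) of the wavelet support to exclude at epoch edges."""
        return 1000.0 * self.n_cycles / (2.0 * freq)

    def valid_time_mask(self, start_ms: float, stop_ms: float, min_freq: float) -> np.ndarray:
        """Samples in [start_ms, stop_ms) clear of edge contamination at min_freq."""
        guard = self.edge_guard_ms(min_freq)
        t = self.times_ms
        lo = max(start_ms, t[0] + guard)
        hi = min(stop_ms, t[-1] - guard)
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError(
                f"window [{start_ms}, {stop_ms}) ms empty after edge guard of {guard:.0f} ms"
            )
        return mask


@dataclass
class ERDMap:
    """Percent power change relative to baseline, (channels, freqs, times)."""

    values: np.ndarray = field(repr=False)
    freqs: np.ndarray
    times_ms: np.ndarray
    baseline_ms: tuple[float, float]
    channels: tuple[str, ...]

    def band_mean(self, band: tuple[float, float], window_ms: tuple[float, float]) -> np.ndarray:
        fmask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        tmask = (self.times_ms >= window_ms[0]) & (self.times_ms < window_ms[1])
        return self.values[:, fmask][:, :, tmask].mean(axis=(1, 2))


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject, per-condition WPLI matrix over channels."""

    subject_id: str
    condition: str
    values: np.ndarray = field(repr=False)
    channels: tuple[str, ...]
    band: tuple[float, float] = ALPHA_BAND
    window_ms: tuple[float, float] = WPLI_WINDOW_MS
    n_trials: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.channels),) * 2:
            raise ValueError("connectivity matrix shape does not match channels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if (v.min() < -1e-12) or (v.max() > 1 + 1e-12):
            raise ValueError("WPLI entries must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def edge(self, ch_i: str, ch_j: str) -> float:
        i = self.channels.index(ch_i)
        j = self.channels.index(ch_j)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Morlet transform
# ---------------------------------------------------------------------------

def morlet_wavelet(freq: float, sample_rate: float, n_cycles: float = 3.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at ``freq`` Hz.

    Gaussian envelope with sigma_t = n_cycles / (2*pi*f), truncated at
    +/- 5 sigma; discrete L2 norm 1 so that band power is comparable across
    frequencies.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return w / np.linalg.norm(w)


def morlet_transform(
    epochs: EpochSet,
    freqs=None,
    n_cycles: float = 3.0,
    condition: str | None = None,
) -> TFDecomposition:
    """Convolve every retained trial and channel with complex Morlet wavelets.

    ``freqs`` defaults to 4..30 Hz in 1 Hz steps.  Rejected trials are
    excluded; pass ``condition`` to restrict to one stimulus condition.
    """
    if freqs is None:
        freqs = np.arange(4.0, 31.0)
    freqs = np.asarray(freqs, dtype=float)
    nyq = epochs.sample_rate / 2.0
    if freqs.max() >= nyq:
        raise ValueError(f"max frequency {freqs.max()} Hz must be below Nyquist {nyq} Hz")
    duration_s = epochs.n_samples / epochs.sample_rate
    if freqs.min() < 2.0 * n_cycles / duration_s:
        raise ValueError("lowest frequency has fewer than two wavelet supports per epoch")
    sub = epochs.retained(condition)
    coefs = np.empty((sub.n_trials, sub.n_channels, len(freqs), sub.n_samples), dtype=complex)
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, sub.sample_rate, n_cycles)
        coefs[:, :, fi, :] = fftconvolve(sub.data, w[None, None, :], mode="same", axes=-1)
    return TFDecomposition(
        coefs=coefs,
        freqs=freqs,
        times_ms=sub.times_ms,
        n_cycles=n_cycles,
        channels=sub.channels,
        subject_id=sub.subject_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# ERD
# ---------------------------------------------------------------------------

def compute_erd(tf: TFDecomposition, baseline_ms: tuple[float, float] = ERD_BASELINE_MS) -> ERDMap:
    """Percent change of trial-mean power relative to the baseline window.

    ERD%(c, f, t) = 100 * (P(c, f, t) - B(c, f)) / B(c, f) with P the
    trial-mean power and B its mean over the baseline samples; negative values
    mark desynchronization.
    """
    pbar = tf.power.mean(axis=0)  # (channels, freqs, times)
    bmask = tf.valid_time_mask(baseline_ms[0], baseline_ms[1], float(tf.freqs.min()))
    base = pbar[:, :, bmask].mean(axis=-1)  # (channels, freqs)
    if np.any(base <= 0):
        raise ValueError("zero baseline power: cannot normalize ERD")
    values = 100.0 * (pbar - base[:, :, None]) / base[:, :, None]
    return ERDMap(values=values, freqs=tf.freqs, times_ms=tf.times_ms,
                  baseline_ms=tuple(baseline_ms), channels=tf.channels)


# ---------------------------------------------------------------------------
# WPLI
# ---------------------------------------------------------------------------

def wpli_from_imag(im_x: np.ndarray, debias: bool = False) -> np.ndarray:
    """WPLI over the leading (trial) axis of Im(cross-spectrum) values.

    ``im_x`` has shape (trials, ...); returns shape (...).  The 0/0 case (no
    imaginary energy at all) is defined as 0: no evidence of lagged coupling.
    """
    im_x = np.asarray(im_x, dtype=float)
    n = im_x.shape[0]
    if debias:
        s = im_x.sum(axis=0)
        ssq = (im_x ** 2).sum(axis=0)
        sabs = np.abs(im_x).sum(axis=0)
        num = s ** 2 - ssq
        den = sabs ** 2 - ssq
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return np.clip(out, 0.0, 1.0)
    num = np.abs(im_x.mean(axis=0))
    den = np.abs(im_x).mean(axis=0)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def compute_wpli(
    tf: TFDecomposition,
    band: tuple[float, float] = ALPHA_BAND,
    window_ms: tuple[float, float] = WPLI_WINDOW_MS,
    debias: bool = False,
) -> ConnectivityMatrix:
    """Band- and window-averaged WPLI matrix across trials.

    WPLI is computed across trials at every (frequency, time) grid point in
    ``band`` x ``window_ms`` and the matrix entry is the unweighted mean over
    those points.  Requires >= 2 trials.
    """
    n_trials = tf.coefs.shape[0]
    if n_trials < 2:
        raise ValueError("WPLI across trials is undefined for a single trial")
    fmask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    if not fmask.any():
        raise ValueError(f"band {band} not covered by decomposition frequencies")
    tmask = tf.valid_time_mask(window_ms[0], window_ms[1], float(tf.freqs[fmask].min()))
    sel = tf.coefs[:, :, fmask][:, :, :, tmask]  # (trials, ch, nf, nt)
    n_ch = sel.shape[1]
    values = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        # vectorized over all partners j > i at once
        cross = sel[:, i, None] * np.conj(sel[:, i + 1:])  # (trials, n_ch-i-1, nf, nt)
        if cross.shape[1] == 0:
            continue
        im_x = np.imag(cross)
        # an imaginary part negligible against the cross-spectrum magnitude is
        # floating-point residue (e.g. identical signals under FMA hardware),
        # not evidence of lag: zero it so the 0/0 -> 0 convention applies
        im_x = np.where(np.abs(im_x) > 1e-12 * np.abs(cross), im_x, 0.0)
        w = wpli_from_imag(im_x, debias=debias).mean(axis=(-2, -1))
        values[i, i + 1:] = w
        values[i + 1:, i] = w
    return ConnectivityMatrix(
        subject_id=tf.subject_id,
        condition=tf.condition or "",
        values=values,
        channels=tf.channels,
        band=tuple(band),
        window_ms=tuple(window_ms),
        n_trials=n_trials,
    )
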