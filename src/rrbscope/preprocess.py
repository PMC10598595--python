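"""EEG preprocessing chain.

Stages, in pipeline order: band-pass filter (0.1-30 Hz), 50 Hz line-noise
removal, baseline correction, +/-100 uV threshold rejection, spherical-spline
interpolation of bad channels, average reference, and a surface-Laplacian
(current source density, CSD) transform.  All stages are pure functions of an
:class:`~rrbscope.epochs.EpochSet` and return a new one.

The spherical-spline machinery (Perrin-style g/h Legendre series) backs both
bad-channel interpolation and the CSD transform and is exposed so that the
series can be checked term by term.
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal

from .epochs import EpochSet, InsufficientDataError
from .montage import Montage

__all__ = [
    "bandpass_filter",
    "remove_line_noise",
    "baseline_correct",
    "reject_artifacts",
    "interpolate_bad_channels",
    "average_reference",
    "surface_laplacian",
    "g_series",
    "h_series",
    "preprocess",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# temporal filtering
# ---------------------------------------------------------------------------

def bandpass_filter(epochs: EpochSet, hp: float = 0.1, lp: float = 30.0) -> EpochSet:
    """Zero-phase 4th-order Butterworth band-pass.

    The squared Butterworth magnitude response (the forward-backward
    equivalent) is applied in the frequency domain.  Time-domain filtfilt is
    unusable here: with a 0.1 Hz high-pass the filter state settles over
    ~10 s, longer than a 3 s epoch, so its initial-condition transient would
    dominate the output.  Frequency-domain application has exactly zero
    phase — the 500-1400 ms analysis window must not be latency-shifted —
    and removes DC exactly (the digital high-pass has a zero at z = 1).
    """
    nyq = epochs.sample_rate / 2.0
    if lp >= nyq:
        raise ValueError(f"low-pass {lp} Hz must be below Nyquist {nyq} Hz")
    if hp >= lp:
        raise ValueError("high-pass cutoff must lie below the low-pass cutoff")
    sos = signal.butter(4, [hp, lp], btype="bandpass", fs=epochs.sample_rate, output="sos")
    n = epochs.n_samples
    grid = np.fft.rfftfreq(n, 1.0 / epochs.sample_rate)
    _, h = signal.sosfreqz(sos, worN=grid, fs=epochs.sample_rate)
    gain = np.abs(h) ** 2
    spectrum = np.fft.rfft(epochs.data, axis=-1)
    return epochs.with_data(np.fft.irfft(spectrum * gain, n=n, axis=-1))


def remove_line_noise(epochs: EpochSet, base: float = 50.0, n_harmonics: int = 2) -> EpochSet:
    """Remove mains interference at ``base`` Hz and its harmonics.

    Per trial and channel, a sine+cosine pair at each harmonic is fitted by
    least squares over the whole epoch and subtracted.  For a deterministic
    sinusoid this removes the line exactly; broadband content at other
    frequencies is untouched (the regressors are near-orthogonal to it).
    """
    nyq = epochs.sample_rate / 2.0
    if base >= nyq:
        raise ValueError(f"line frequency {base} Hz must be below Nyquist {nyq} Hz")
    freqs = [base * (k + 1) for k in range(n_harmonics) if base * (k + 1) < nyq]
    t = np.arange(epochs.n_samples) / epochs.sample_rate
    cols = []
    for f in freqs:
        cols.append(np.sin(2 * np.pi * f * t))
        cols.append(np.cos(2 * np.pi * f * t))
    design = np.column_stack(cols)  # (samples, 2*n_lines)
    # One pinv solves every trial x channel at once.
    pinv = np.linalg.pinv(design)
    flat = epochs.data.reshape(-1, epochs.n_samples)  # (trials*channels, samples)
    coefs = flat @ pinv.T
    cleaned = flat - coefs @ design.T
    return epochs.with_data(cleaned.reshape(epochs.data.shape))


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-1000.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms, half-open)."""
    mask = epochs.time_mask(*window)
    baseline = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - baseline)


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------

def reject_artifacts(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Flag trials with any sample outside the closed interval [-threshold, +threshold].

    Only non-bad channels are inspected.  Raises
    :class:`~rrbscope.epochs.InsufficientDataError` if every trial of a
    condition would be lost.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    good = np.array([c not in epochs.bad_channels for c in epochs.channels])
    exceeds = np.abs(epochs.data[:, good, :]) > threshold
    flag = exceeds.any(axis=(1, 2))
    rejected = epochs.rejected | flag
    for cond in np.unique(epochs.conditions):
        sel = epochs.conditions == cond
        if rejected[sel].all():
            raise InsufficientDataError(
                f"subject {epochs.subject_id}: all {int(sel.sum())} trials of "
                f"condition {cond} exceed +/-{threshold} uV"
            )
    n_new = int(flag.sum())
    if n_new:
        logger.info("subject %s: rejected %d/%d trials at +/-%g uV",
                    epochs.subject_id, n_new, epochs.n_trials, threshold)
    out = epochs.with_data(epochs.data)
    out.rejected = rejected
    return out


# ---------------------------------------------------------------------------
# spherical splines (Perrin g/h series)
# ---------------------------------------------------------------------------

def _legendre_weights(m: int, n_terms: int, order: int) -> np.ndarray:
    """Series coefficients (2n+1)/(n(n+1))^order for n = 1..n_terms, /4π."""
    n = np.arange(1, n_terms + 1, dtype=float)
    return (2 * n + 1) / (n * (n + 1)) ** order / (4 * np.pi)


def _legval(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    coefs = np.concatenate(([0.0], weights))  # P_0 excluded from the series
    return npleg.legval(np.asarray(x, dtype=float), coefs)


def g_series(x, m: int = 4, n_terms: int = 50):
    """Spline kernel g(x) = Σ_{n≥1} (2n+1) / (n(n+1))^m · P_n(x) / 4π."""
    return _legval(x, _legendre_weights(m, n_terms, m))


def h_series(x, m: int = 4, n_terms: int = 50):
    """Laplacian kernel h(x) = Σ_{n≥1} (2n+1) / (n(n+1))^(m-1) · P_n(x) / 4π."""
    return _legval(x, _legendre_weights(m, n_terms, m - 1))


def _spline_coefficients(G: np.ndarray, data: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Solve the constrained spline system for coefficients c and offset c0.

    ``data`` is (n_channels, n_obs).  The system is the KKT form of the
    regularized interpolation problem with the Σc = 0 constraint, which makes
    the fit (and hence the CSD) exactly invariant to a common offset.
    """
    n = G.shape[0]
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    rhs = np.vstack([data, np.zeros((1, data.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    return sol[:-1], sol[-1]  # c (n, n_obs), c0 (n_obs,)


def interpolate_bad_channels(
    epochs: EpochSet,
    montage: Montage,
    m: int = 4,
    lam: float = 1e-5,
    n_terms: int = 50,
) -> EpochSet:
    """Replace bad channels by spherical-spline interpolation from good ones.

    Good channels are untouched.  Requires >= 4 good channels; warns above
    25% bad.
    """
    if not epochs.bad_channels:
        return epochs
    if tuple(montage.channels) != tuple(epochs.channels):
        montage = montage.subset(epochs.channels)
    bad_idx = montage.index(epochs.bad_channels)
    good_idx = np.setdiff1d(np.arange(len(montage)), bad_idx)
    if good_idx.size == 0:
        raise InsufficientDataError("no good channels left to interpolate from")
    if good_idx.size < 4:
        raise InsufficientDataError(
            f"only {good_idx.size} good channels; >= 4 required for spline interpolation"
        )
    if len(bad_idx) > 0.25 * len(montage):
        logger.warning("subject %s: %d/%d channels bad (>25%%) — interpolation may be poor",
                       epochs.subject_id, len(bad_idx), len(montage))
    cosang = montage.cosine_angles()
    G = g_series(cosang[np.ix_(good_idx, good_idx)], m=m, n_terms=n_terms)
    Gb = g_series(cosang[np.ix_(bad_idx, good_idx)], m=m, n_terms=n_terms)
    flat = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    c, c0 = _spline_coefficients(G, flat[good_idx], lam)
    est = Gb @ c + c0  # (n_bad, n_obs)
    out = flat.copy()
    out[bad_idx] = est
    data = out.reshape(epochs.n_channels, epochs.n_trials, epochs.n_samples).transpose(1, 0, 2)
    result = epochs.with_data(data)
    result.bad_channels = ()
    return result


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across channels."""
    return epochs.with_data(epochs.data - epochs.data.mean(axis=1, keepdims=True))


def surface_laplacian(
    epochs: EpochSet,
    montage: Montage,
    m: int = 4,
    lam: float = 1e-5,
    n_terms: int = 50,
) -> EpochSet:
    """Current-source-density estimate via spherical splines.

    A spline with the Σc = 0 constraint is fitted through all channels at each
    time point and its surface Laplacian is read off the h-series; the result
    is reference-free (adding a constant to every channel changes nothing) and
    vanishes for a spatially uniform potential.
    """
    if tuple(montage.channels) != tuple(epochs.channels):
        montage = montage.subset(epochs.channels)
    if len(montage) < 8:
        raise ValueError("surface Laplacian needs >= 8 channels with positions")
    cosang = montage.cosine_angles()
    off_diag = cosang[~np.eye(len(montage), dtype=bool)]
    if np.any(off_diag > 1 - 1e-12):
        raise ValueError("duplicate electrode positions in montage")
    G = g_series(cosang, m=m, n_terms=n_terms)
    H = h_series(cosang, m=m, n_terms=n_terms)
    flat = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    c, _ = _spline_coefficients(G, flat, lam)
    csd = H @ c
    data = csd.reshape(epochs.n_channels, epochs.n_trials, epochs.n_samples).transpose(1, 0, 2)
    return epochs.with_data(data)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess(
    epochs: EpochSet,
    montage: Montage,
    hp: float = 0.1,
    lp: float = 30.0,
    line: float = 50.0,
    n_harmonics: int = 2,
    baseline: tuple[float, float] = (-1000.0, 0.0),
    reject_uv: float = 100.0,
    csd: bool = True,
) -> EpochSet:
    """Run the full preprocessing chain in the canonical order."""
    out = bandpass_filter(epochs, hp=hp, lp=lp)
    out = remove_line_noise(out, base=line, n_harmonics=n_harmonics)
    out = baseline_correct(out, window=baseline)
    out = reject_artifacts(out, threshold=reject_uv)
    out = interpolate_bad_channels(out, montage)
    out = average_reference(out)
    if csd:
        out = surface_laplacian(out, montage)
    return out
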