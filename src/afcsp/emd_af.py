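"""Empirical mode decomposition and amplitude-frequency (AF) matrices.

EMD sifts a signal S(t) into intrinsic mode functions (IMFs) C_i(t) plus a
monotone residual R_n(t), S = sum_i C_i + R_n, ordered fastest to slowest.
For sensorimotor EEG the mu (8-13 Hz) and beta (13-30 Hz) rhythms land
almost entirely in IMF1 and IMF2 at 128 Hz, so the per-trial feature
matrix X_i stacks the one-sided FFT amplitude spectra of IMF1 and IMF2 of
the four motor channels, restricted to the 8-30 Hz bins:

    rows 0-3: IMF1 spectra of FC5, F3, F4, FC6
    rows 4-7: IMF2 spectra of FC5, F3, F4, FC6

With the default 1-4 s analysis window at 128 Hz (384 samples, 1/3 Hz bin
spacing) the closed interval [8, 30] Hz contains M = 67 bins.

Sifting uses cubic-spline envelopes through the extrema with two extrema
mirrored beyond each end (suppresses end swings on short windows), the
Cauchy SD stopping criterion (threshold 0.2) and a 10-sift cap per IMF;
decomposition stops when the residual is monotone or has fewer than three
extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from afcsp.synth import MOTOR_CHANNELS


@dataclass
class IMFDecomposition:
    imfs: list[np.ndarray]
    residual: np.ndarray
    source_channel: str = ""

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residual


@dataclass
class AFMatrix:
    """8 x M amplitude-frequency matrix for one trial."""

    values: np.ndarray
    freq_bins: np.ndarray
    trial_label: str = ""

    ROW_ORDER = tuple(f"IMF{k}:{c}" for k in (1, 2) for c in MOTOR_CHANNELS)

    def __post_init__(self) -> None:
        if self.values.shape[0] != 8:
            raise ValueError(f"AF matrix must have 8 rows, got {self.values.shape[0]}")
        if self.values.shape[1] != len(self.freq_bins):
            raise ValueError("freq_bins length does not match column count")


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    Plateaus are reduced to their midpoint so repeated samples do not
    produce duplicate spline knots.
    """
    dx = np.diff(x)
    # collapse exact plateaus: carry the previous nonzero slope sign
    sign = np.sign(dx)
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int,
                   n_mirror: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to `n_mirror` extrema beyond each end of [0, n-1]."""
    k = min(n_mirror, len(idx))
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    xi = np.concatenate([left_i, idx, right_i]).astype(float)
    vi = np.concatenate([left_v, val, right_v])
    xi, order = np.unique(xi, return_index=True)
    return xi, vi[order]


def _mean_envelope(x: np.ndarray) -> tuple[np.ndarray | None, int]:
    """Mean of upper/lower cubic-spline envelopes; None if too few extrema."""
    n = len(x)
    maxima, minima = _extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return None, len(maxima) + len(minima)
    t = np.arange(n, dtype=float)
    xi, vi = _mirror_extend(maxima, x[maxima], n)
    upper = CubicSpline(xi, vi)(t)
    xi, vi = _mirror_extend(minima, x[minima], n)
    lower = CubicSpline(xi, vi)(t)
    return 0.5 * (upper + lower), len(maxima) + len(minima)


def emd(x: np.ndarray, max_imfs: int | None = None, sd_threshold: float = 0.2,
        max_sifts: int = 10, source_channel: str = "") -> IMFDecomposition:
    """Decompose `x` into IMFs plus a residual.

    The residual is computed as input minus the IMF sum, so the
    reconstruction identity holds to round-off by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise ValueError(f"EMD needs a 1-D signal of >= 64 samples, got {x.shape}")
    if np.ptp(x) == 0:
        raise ValueError("EMD undefined for a constant signal")

    imfs: list[np.ndarray] = []
    residual = x.copy()
    limit = max_imfs if max_imfs is not None else len(x)
    while len(imfs) < limit:
        env, n_ext = _mean_envelope(residual)
        if env is None or n_ext < 3:
            break  # residual is (near-)monotone: done
        h = residual - env
        for _ in range(max_sifts - 1):
            env, n_ext = _mean_envelope(h)
            if env is None:
                break
            h_new = h - env
            denom = np.sum(h * h)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return IMFDecomposition(imfs=imfs, residual=x - np.sum(imfs, axis=0)
                            if imfs else x.copy(),
                            source_channel=source_channel)


def amplitude_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum (rectangular window, no padding).

    Scaled by 2/N (1/N at DC and Nyquist) so a unit-amplitude sinusoid at
    a bin centre yields magnitude ~= 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    mags = np.abs(np.fft.rfft(x)) * (2.0 / n)
    mags[0] /= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    return np.fft.rfftfreq(n, d=1.0 / fs), mags


def band_bins(n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of one-sided FFT bins inside the closed interval `band`."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = band
    return np.where((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))[0]


def build_af_matrix(trial: np.ndarray, fs: float = 128.0,
                    window: tuple[float, float] = (1.0, 4.0),
                    band: tuple[float, float] = (8.0, 30.0),
                    label: str = "", sd_threshold: float = 0.2,
                    max_sifts: int = 10) -> AFMatrix:
    """AF matrix of one preprocessed (4 x samples) trial.

    EMD runs on each channel's analysis-window segment; the amplitude
    spectra of IMF1 and IMF2 are then restricted to the `band` bins.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != 4:
        raise ValueError("expected a (4 x samples) preprocessed trial")
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    if i1 > trial.shape[1] or i1 - i0 < 64:
        raise ValueError(
            f"trial ({trial.shape[1]} samples) does not cover the "
            f"analysis window {window}")
    seg = trial[:, i0:i1]
    n = seg.shape[1]
    cols = band_bins(n, fs, band)
    spectra = []  # per channel: (IMF1 bins, IMF2 bins)
    for j, chan in enumerate(MOTOR_CHANNELS):
        dec = emd(seg[j], max_imfs=2, sd_threshold=sd_threshold,
                  max_sifts=max_sifts, source_channel=chan)
        if len(dec.imfs) < 2:
            raise ValueError(
                f"EMD produced {len(dec.imfs)} IMF(s) on channel {chan}; "
                "need at least 2")
        spectra.append(tuple(amplitude_spectrum(imf, fs)[1][cols]
                             for imf in dec.imfs[:2]))
    rows = [spectra[j][k] for k in (0, 1) for j in range(4)]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[cols]
    return AFMatrix(values=np.array(rows), freq_bins=freqs, trial_label=label)


def build_af_matrices(trials: list[np.ndarray], labels: list[str],
                      fs: float = 128.0,
                      window: tuple[float, float] = (1.0, 4.0),
                      band: tuple[float, float] = (8.0, 30.0),
                      ) -> list[AFMatrix]:
    """AF matrices for a trial list; enforces a common column count M.

    M is frozen from the first trial; any later mismatch (which would make
    the feature tensor ragged) raises.
    """
    out: list[AFMatrix] = []
    m_frozen: int | None = None
    for trial, label in zip(trials, labels):
        af = build_af_matrix(trial, fs=fs, window=window, band=band, label=label)
        if m_frozen is None:
            m_frozen = af.values.shape[1]
        elif af.values.shape[1] != m_frozen:
            raise ValueError(
                f"AF column count changed from {m_frozen} to "
                f"{af.values.shape[1]} at trial {len(out)}")
        out.append(af)
    return out
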