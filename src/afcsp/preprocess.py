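"""Line-noise removal and common average referencing.

Order follows the pipeline narrative: 50 Hz notch first, then CAR over the
four selected motor channels (FC5, F3, F4, FC6).  Full-montage CAR is
available via ``car_scope="all"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from afcsp.synth import MOTOR_CHANNELS, TrialSet


@dataclass(frozen=True)
class FilterSpec:
    """Notch design: second-order IIR notch, applied forward-backward.

    Q=30 keeps the stopband narrow enough not to erode the upper edge of
    the beta band (30 Hz).
    """

    notch_freq: float = 50.0
    notch_q: float = 30.0
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.notch_freq:
            raise ValueError(
                f"notch at {self.notch_freq} Hz requires fs > "
                f"{2 * self.notch_freq} Hz (got fs={self.fs})")


def notch_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase notch along the last axis; output length equals input."""
    x = np.asarray(x, dtype=float)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=spec.fs)
    warmup = 3 * max(len(a), len(b))
    if x.shape[-1] <= warmup:
        raise ValueError(f"signal too short for notch filtering "
                         f"(need > {warmup} samples, got {x.shape[-1]})")
    return signal.filtfilt(b, a, x, axis=-1)


def car_reference(X: np.ndarray, n_channels: int | None = 4) -> np.ndarray:
    """Common average reference: subtract the instantaneous channel mean.

    With the default ``n_channels=4`` the input must be exactly the four
    selected motor channels; pass ``n_channels=None`` to reference an
    arbitrary montage (full-scalp CAR).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a (channels x samples) matrix")
    if n_channels is not None and X.shape[0] != n_channels:
        raise ValueError(
            f"CAR expected {n_channels} channels, got {X.shape[0]}")
    return X - X.mean(axis=0, keepdims=True)


def preprocess_trial(trial: np.ndarray, channel_names: tuple[str, ...],
                     spec: FilterSpec, car_scope: str = "selected4",
                     ) -> np.ndarray:
    """Notch + CAR, returning the (4 x samples) motor-channel matrix.

    ``car_scope="selected4"`` references over FC5/F3/F4/FC6 only (the
    printed formula); ``"all"`` references over the full montage before
    selecting the four channels.
    """
    if car_scope not in ("selected4", "all"):
        raise ValueError(f"car_scope must be 'selected4' or 'all', got {car_scope!r}")
    try:
        idx = [channel_names.index(c) for c in MOTOR_CHANNELS]
    except ValueError as exc:
        raise ValueError(f"montage lacks a selected motor channel: {exc}") from exc
    filtered = notch_filter(np.asarray(trial, dtype=float), spec)
    if car_scope == "all":
        return car_reference(filtered, n_channels=None)[idx]
    return car_reference(filtered[idx], n_channels=4)


def preprocess_trialset(ts: TrialSet, spec: FilterSpec | None = None,
                        car_scope: str = "selected4") -> list[np.ndarray]:
    """Apply :func:`preprocess_trial` to every trial of a set."""
    if spec is None:
        spec = FilterSpec(fs=ts.fs)
    return [preprocess_trial(t, tuple(ts.channel_names), spec, car_scope)
            for t in ts.trials]
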