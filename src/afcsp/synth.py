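"""Synthetic motor-imagery EEG with class-dependent mu/beta ERD.

Motor imagery attenuates the mu (8-13 Hz) and beta (13-30 Hz) rhythms over
sensorimotor cortex (event-related desynchronization, ERD).  The generator
emulates the statistical structure a single-joint three-class decoding
pipeline relies on: each trial is, per channel,

    pink background + 50 Hz line interference
        + mu-band oscillation * (1 - erd_depth[class, channel])
        + beta-band oscillation * (1 - erd_depth[class, channel])

Class information is injected only on the frontocentral channels FC5, F3,
F4 and FC6; the remaining montage channels carry identical statistics for
every class.  Band oscillations are amplitude-modulated sinusoids with a
random centre frequency and phase per trial so that empirical mode
decomposition yields non-degenerate intrinsic mode functions.

Trials are 5 s at 128 Hz, 20 per class by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASSES: tuple[str, ...] = ("flexion", "extension", "abduction")

MOTOR_CHANNELS: tuple[str, ...] = ("FC5", "F3", "F4", "FC6")

#: Emotiv Epoc+ 14-electrode montage, 10-20 positions.
EMOTIV_MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


def default_erd_pattern(depth: float = 0.5) -> dict[str, dict[str, float]]:
    """Class -> channel -> ERD depth mapping used by default.

    Each class desynchronizes a distinct subset of the four motor channels
    (a crude lateralisation surrogate), so all three pairwise contrasts are
    informative.  ``depth`` scales the whole pattern.
    """
    d = float(depth)
    return {
        "flexion": {"FC5": d, "F3": 0.5 * d},
        "extension": {"FC6": d, "F4": 0.5 * d},
        "abduction": {"F3": d, "F4": d},
    }


@dataclass
class SimConfig:
    """Generator configuration.

    Amplitudes are in microvolts.  ``erd_depth[label][channel]`` is the
    fractional band-amplitude attenuation in [0, 1) applied to both the mu
    and beta oscillations of that channel for trials of that class.
    """

    n_channels: int = 14
    fs: float = 128.0
    trial_dur: float = 5.0
    n_trials_per_class: int = 20
    class_labels: tuple[str, ...] = CLASSES
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    mu_amp: float = 6.0
    beta_amp: float = 4.0
    erd_depth: dict[str, dict[str, float]] = field(
        default_factory=default_erd_pattern)
    line_noise_amp: float = 1.0
    pink_noise_amp: float = 3.0
    seed: int = 0
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_channels < 4 or self.n_channels > len(EMOTIV_MONTAGE):
            raise ValueError(
                f"n_channels must be in [4, {len(EMOTIV_MONTAGE)}]")
        for label, per_chan in self.erd_depth.items():
            for chan, d in per_chan.items():
                if not 0.0 <= d < 1.0:
                    raise ValueError(
                        f"erd_depth[{label}][{chan}]={d} outside [0, 1)")
        n = self.fs * self.trial_dur
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * trial_dur must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_dur))

    @property
    def channel_names(self) -> tuple[str, ...]:
        names = EMOTIV_MONTAGE[: self.n_channels]
        missing = [c for c in MOTOR_CHANNELS if c not in names]
        if missing:
            raise ValueError(f"montage truncation drops motor channels {missing}")
        return names


@dataclass
class TrialSet:
    """Labeled multichannel EEG trials with shared geometry."""

    trials: list[np.ndarray]
    labels: list[str]
    channel_names: tuple[str, ...]
    fs: float
    subject_id: str = "sim"

    def __post_init__(self) -> None:
        shapes = {t.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent trial shapes: {shapes}")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        if len(self.trials) != len(self.labels):
            raise ValueError("trials/labels length mismatch")

    def __len__(self) -> int:
        return len(self.trials)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in CLASSES}

    # ----- trial-set CSV: one row per (trial, channel), long format ------

    def to_csv(self, path_or_buf) -> None:
        """Write `subject,trial,label,channel,t0..t{n-1}` rows."""
        n = self.trials[0].shape[1]
        cols = ["subject", "trial", "label", "channel"] + [f"t{k}" for k in range(n)]
        rows = []
        for i, (trial, label) in enumerate(zip(self.trials, self.labels)):
            for j, chan in enumerate(self.channel_names):
                rows.append([self.subject_id, i, label, chan] + trial[j].tolist())
        pd.DataFrame(rows, columns=cols).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, fs: float = 128.0) -> "TrialSet":
        df = pd.read_csv(path_or_buf)
        required = {"subject", "trial", "label", "channel"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"trial CSV missing columns {sorted(required - set(df.columns))}")
        tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
        tcols.sort(key=lambda c: int(c[1:]))
        trials, labels = [], []
        channel_names: tuple[str, ...] | None = None
        for trial_id, grp in df.groupby("trial", sort=True):
            chans = tuple(grp["channel"])
            if channel_names is None:
                channel_names = chans
            elif chans != channel_names:
                raise ValueError(f"trial {trial_id}: channel order mismatch")
            trials.append(grp[tcols].to_numpy(dtype=float))
            lab = grp["label"].iloc[0]
            labels.append(str(lab))
        subject = str(df["subject"].iloc[0])
        return cls(trials, labels, channel_names, fs, subject)


def _pink_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    """White noise shaped to a 1/f amplitude profile, scaled to `rms`."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)  # bin index scale; only the shape matters
    shape = 1.0 / np.maximum(f, f[1])
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _band_oscillation(band: tuple[float, float], amp: float, t: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Two AM sinusoids with jittered centre frequencies inside `band`.

    Modulation rate stays below 1 Hz so AM sidebands remain within a
    +/- 1 Hz guard around the band edges; centre frequencies keep a 1 Hz
    margin from the edges for the same reason.
    """
    lo, hi = band
    out = np.zeros_like(t)
    for _ in range(2):
        f0 = rng.uniform(lo + 1.0, hi - 1.0)
        f0 += rng.uniform(-0.5, 0.5)  # trial-to-trial jitter
        f0 = min(max(f0, lo + 0.55), hi - 0.55)
        phase = rng.uniform(0, 2 * np.pi)
        fm = rng.uniform(0.2, 0.9)
        pm = rng.uniform(0, 2 * np.pi)
        env = 1.0 + 0.3 * np.sin(2 * np.pi * fm * t + pm)
        out += 0.5 * amp * env * np.sin(2 * np.pi * f0 * t + phase)
    return out


def generate_trial(label: str, cfg: SimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One (channels x samples) trial of class `label`.

    Deterministic given the state of `rng`.  Channels outside the four
    motor channels receive no class-dependent modulation.
    """
    if label not in cfg.class_labels:
        raise ValueError(f"unknown label {label!r}; expected one of "
                         f"{cfg.class_labels}")
    t = np.arange(cfg.n_samples) / cfg.fs
    depth = cfg.erd_depth.get(label, {})
    X = np.empty((cfg.n_channels, cfg.n_samples))
    for j, chan in enumerate(cfg.channel_names):
        scale = 1.0 - depth.get(chan, 0.0) if chan in MOTOR_CHANNELS else 1.0
        x = _pink_noise(cfg.n_samples, cfg.pink_noise_amp, rng)
        if cfg.line_noise_amp > 0:
            x = x + cfg.line_noise_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        x = x + scale * _band_oscillation(cfg.mu_band, cfg.mu_amp, t, rng)
        x = x + scale * _band_oscillation(cfg.beta_band, cfg.beta_amp, t, rng)
        X[j] = x
    return X


def generate_trialset(cfg: SimConfig) -> TrialSet:
    """Balanced trial set: `n_trials_per_class` per class, shuffled order.

    Reproducible: two calls with the same config produce identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    trials, labels = [], []
    for label in cfg.class_labels:
        for _ in range(cfg.n_trials_per_class):
            trials.append(generate_trial(label, cfg, rng))
            labels.append(label)
    order = rng.permutation(len(trials))
    return TrialSet(
        trials=[trials[i] for i in order],
        labels=[labels[i] for i in order],
        channel_names=cfg.channel_names,
        fs=cfg.fs,
        subject_id=cfg.subject_id,
    )


def load_edf(path, trial_dur: float = 5.0) -> TrialSet:
    """Optional EDF import: fixed-length epochs, labels from annotations.

    Requires :mod:`mne`.  Channels are matched by name against the Emotiv
    10-20 montage; annotations whose description equals a class label mark
    trial onsets.
    """
    import mne  # local import: EDF support is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    keep = [c for c in raw.ch_names if c.upper() in
            {m.upper() for m in EMOTIV_MONTAGE}]
    if len(keep) < 4:
        raise ValueError("EDF file has fewer than 4 recognisable montage channels")
    raw.pick(keep)
    fs = raw.info["sfreq"]
    n = int(round(fs * trial_dur))
    data = raw.get_data() * 1e6  # volts -> microvolts
    trials, labels = [], []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc not in CLASSES:
            continue
        start = int(round(onset * fs))
        if start + n <= data.shape[1]:
            trials.append(data[:, start:start + n].copy())
            labels.append(desc)
    if not trials:
        raise ValueError("no class-labeled annotations found in EDF")
    return TrialSet(trials, labels, tuple(keep), fs, subject_id="edf")
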