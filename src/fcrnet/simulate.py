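"""Synthetic motor-imagery EEG sessions with known spatio-spectral structure.

The generator emulates a four-class motor-imagery recording session in the
style of a 22-electrode, 250 Hz cued-trial protocol: each class modulates the
variance of one narrow-band latent oscillator (mu-band ~10 Hz for the two hand
classes, beta-band ~22 Hz for feet/tongue), the oscillators are mixed into the
electrode montage through a full-column-rank mixing matrix, and broadband
(white or 1/f "pink") background noise is added at a configurable SNR.

Because the mixing matrix and per-class source bands are known, downstream
spatial-filtering stages can be validated by parameter recovery rather than by
eyeballing accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "IV2A_CHANNELS",
    "SimulationConfig",
    "EpochedRecording",
    "SimulationTruth",
    "generate_session",
    "generate_session_with_truth",
]

#: Standard 22-channel motor-imagery montage (frontal / central / parietal rows).
IV2A_CHANNELS = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)

DEFAULT_CLASS_NAMES = ("left_hand", "right_hand", "feet", "tongue")

#: Per-class source bands in Hz: mu rhythm for the hand classes, beta for
#: feet/tongue.  Two classes sharing a band are separated spatially.
DEFAULT_SOURCE_BANDS = ((8.0, 12.0), (8.0, 12.0), (20.0, 24.0), (20.0, 24.0))

#: Cued-trial timing (seconds): fixation, cue, motor-imagery period.
FIXATION_S = 2.0
CUE_S = 1.25
MI_S = 4.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic session.

    ``trial_duration`` is the motor-imagery window length; when
    ``include_pre_trial`` is set, each epoch is prefixed with the fixation and
    cue segments so that time windows quoted relative to trial start (e.g.
    2.5-6 s) can be indexed directly.
    """

    n_classes: int = 4
    trials_per_class: int = 72
    n_channels: int = 22
    fs: float = 250.0
    trial_duration: float = MI_S
    include_pre_trial: bool = False
    source_bands: tuple = DEFAULT_SOURCE_BANDS
    mixing_matrix: object = "random-orthonormal"
    snr_db: float = 6.0
    noise_model: str = "white"
    class_gain: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.trials_per_class < 1 or self.n_channels < 1:
            raise ConfigurationError("counts must be positive")
        if self.fs <= 0 or self.trial_duration <= 0:
            raise ConfigurationError("fs and trial_duration must be positive")
        if len(self.source_bands) < self.n_classes:
            raise ConfigurationError(
                f"need one source band per class ({self.n_classes}), "
                f"got {len(self.source_bands)}"
            )
        nyq = self.fs / 2.0
        for lo, hi in self.source_bands[: self.n_classes]:
            if not (0.0 < lo < hi < nyq):
                raise ConfigurationError(
                    f"band ({lo}, {hi}) Hz must lie strictly inside (0, {nyq})"
                )
        if self.noise_model not in ("white", "pink"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if self.class_gain <= 1.0:
            raise ConfigurationError("class_gain must exceed 1 for a contrast")
        if not isinstance(self.mixing_matrix, str):
            A = np.asarray(self.mixing_matrix, dtype=float)
            if A.ndim != 2 or A.shape[0] != self.n_channels:
                raise ConfigurationError(
                    "mixing matrix must be [n_channels x n_sources]"
                )
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ConfigurationError("mixing matrix must have full column rank")

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def epoch_duration(self) -> float:
        pre = FIXATION_S + CUE_S if self.include_pre_trial else 0.0
        return pre + self.trial_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.fs))


@dataclass
class EpochedRecording:
    """Labeled trial tensor ``[n_trials x n_channels x n_samples]``.

    ``trial_onset`` is the time (s) of each epoch's first sample relative to
    cue onset (negative when the fixation period is included).
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple
    class_names: tuple = DEFAULT_CLASS_NAMES
    trial_onset: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.signals.ndim != 3:
            raise ValueError("signals must be [n_trials x n_channels x n_samples]")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain NaN/Inf")
        n_trials, n_channels, _ = self.signals.shape
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must equal n_trials")
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("labels must lie in {0..n_classes-1}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def pick_channels(self, names) -> "EpochedRecording":
        """Sub-select channels by montage name (order as given)."""
        idx = []
        for name in names:
            try:
                idx.append(self.channel_names.index(name)
                           if isinstance(self.channel_names, list)
                           else list(self.channel_names).index(name))
            except ValueError:
                raise KeyError(f"channel {name!r} not in montage") from None
        return EpochedRecording(
            signals=self.signals[:, idx, :],
            labels=self.labels.copy(),
            fs=self.fs,
            channel_names=tuple(names),
            class_names=tuple(self.class_names),
            trial_onset=self.trial_onset,
        )


@dataclass
class SimulationTruth:
    """Ground truth of a generated session, for parameter-recovery checks."""

    mixing_matrix: np.ndarray          # [n_channels x n_sources]
    unmixing_matrix: np.ndarray        # pinv(mixing) [n_sources x n_channels]
    source_bands: tuple                # per-source (low, high) Hz
    class_of_source: np.ndarray        # source index -> class index
    mi_sample_range: tuple             # (start, stop) samples of the MI window


def _bandpass_noise(rng: np.random.Generator, band, fs, n, size) -> np.ndarray:
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal(size + (n,))
    y = signal.sosfiltfilt(sos, x, axis=-1)
    # unit variance per series so class gains are interpretable
    y /= y.std(axis=-1, keepdims=True) + 1e-30
    return y


def _pink_noise(rng: np.random.Generator, size) -> np.ndarray:
    """1/f amplitude-shaped Gaussian noise along the last axis."""
    n = size[-1]
    white = rng.standard_normal(size)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = shaping[1]
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True) + 1e-30
    return pink


def _band_power_fraction(x: np.ndarray, fs: float, band) -> float:
    """Fraction of the array's power inside ``band`` (exact for the sample)."""
    n = x.shape[-1]
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    total = spec.sum()
    return float(spec[..., sel].sum() / total) if total > 0 else 0.0


def generate_session_with_truth(config: SimulationConfig):
    """Generate one session and return ``(EpochedRecording, SimulationTruth)``.

    One latent oscillator per class, band-passed to the class band; on trials
    of its own class the oscillator's standard deviation is multiplied by
    ``class_gain`` (variance contrast is ``class_gain**2``).  Sources are mixed
    into channels and background noise is added, scaled so that the ratio of
    total source power to background power inside the source bands equals
    ``snr_db`` (class-band SNR).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_trials = config.n_trials
    n_samples = config.n_samples
    n_sources = config.n_classes
    fs = config.fs

    labels = np.repeat(np.arange(config.n_classes), config.trials_per_class)
    rng.shuffle(labels)

    if isinstance(config.mixing_matrix, str):
        if config.mixing_matrix != "random-orthonormal":
            raise ConfigurationError(
                f"unknown mixing matrix spec {config.mixing_matrix!r}"
            )
        gauss = rng.standard_normal((config.n_channels, n_sources))
        A, _ = np.linalg.qr(gauss)
        A = A[:, :n_sources]
    else:
        A = np.asarray(config.mixing_matrix, dtype=float)

    pre = FIXATION_S + CUE_S if config.include_pre_trial else 0.0
    mi_start = int(round(pre * fs))
    mi_stop = int(round((pre + config.trial_duration) * fs))

    sources = np.empty((n_trials, n_sources, n_samples))
    for s in range(n_sources):
        band = config.source_bands[s]
        osc = _bandpass_noise(rng, band, fs, n_samples, (n_trials,))
        gain = np.ones((n_trials, 1))
        own = labels == s
        if config.include_pre_trial:
            # class-dependent modulation only inside the MI window
            g = np.ones((n_trials, n_samples))
            g[own, mi_start:mi_stop] = config.class_gain
            osc = osc * g
        else:
            gain[own, 0] = config.class_gain
            osc = osc * gain
        sources[:, s, :] = osc

    clean = np.einsum("cs,tsn->tcn", A, sources)

    if config.noise_model == "white":
        noise = rng.standard_normal(clean.shape)
    else:
        noise = _pink_noise(rng, clean.shape)
    # snr_db is the class-band SNR: the ratio of source power to background
    # power within the source bands (the meaningful quantity for narrowband
    # rhythms — broadband SNR would leave the bands nearly background-free).
    p_signal = np.mean(clean ** 2)
    bands = config.source_bands[: config.n_classes]
    p_noise_inband = np.mean(
        [_band_power_fraction(noise, fs, band) for band in set(bands)]
    ) * np.mean(noise ** 2)
    target = p_signal / (10.0 ** (config.snr_db / 10.0))
    noise *= np.sqrt(target / p_noise_inband)

    recording = EpochedRecording(
        signals=clean + noise,
        labels=labels,
        fs=fs,
        channel_names=tuple(IV2A_CHANNELS[: config.n_channels])
        if config.n_channels <= len(IV2A_CHANNELS)
        else tuple(f"CH{i}" for i in range(config.n_channels)),
        class_names=tuple(DEFAULT_CLASS_NAMES[: config.n_classes])
        if config.n_classes <= len(DEFAULT_CLASS_NAMES)
        else tuple(f"class{i}" for i in range(config.n_classes)),
        trial_onset=-(FIXATION_S) if config.include_pre_trial else CUE_S,
    )
    truth = SimulationTruth(
        mixing_matrix=A,
        unmixing_matrix=np.linalg.pinv(A),
        source_bands=tuple(config.source_bands[:n_sources]),
        class_of_source=np.arange(n_sources),
        mi_sample_range=(mi_start, mi_stop),
    )
    return recording, truth


def generate_session(config: SimulationConfig = SimulationConfig()) -> EpochedRecording:
    """Generate one epoched session (see :func:`generate_session_with_truth`)."""
    recording, _ = generate_session_with_truth(config)
    return recording


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
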