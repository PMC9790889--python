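"""Band-pass filter bank and multi-scale time-step segmentation.

The preprocessing front end expands each epoch over two axes: nine contiguous
4 Hz band-pass filters spanning 4-40 Hz, and seven partially overlapping
time-step windows (1-3.5 s long) that accommodate subject-specific response
latencies.  The result is the block tensor on which spatial filters are fitted
per (band, window) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import EpochedRecording

__all__ = [
    "FilterBankSpec",
    "TimeStepSpec",
    "MultiScaleBandTensor",
    "design_filter_bank",
    "apply_filter_bank",
    "segment_time_steps",
]

DEFAULT_BANDS = tuple((4.0 * i, 4.0 * (i + 1)) for i in range(1, 10))  # 4-8 .. 36-40
DEFAULT_INTERVALS = (
    (2.5, 3.5), (3.0, 4.0), (4.0, 5.0), (5.0, 6.0),
    (2.5, 4.5), (4.0, 6.0), (2.5, 6.0),
)


class FilterDesignError(ValueError):
    """Band edges incompatible with the sampling rate."""


@dataclass(frozen=True)
class FilterBankSpec:
    """Band-pass bank specification (Butterworth, zero-phase by default)."""

    bands: tuple = DEFAULT_BANDS
    filter_order: int = 4
    design: str = "butterworth"
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.design != "butterworth":
            raise FilterDesignError(f"unsupported design {self.design!r}")
        if self.filter_order < 1:
            raise FilterDesignError("filter order must be >= 1")
        nyq = fs / 2.0
        for lo, hi in self.bands:
            if not (0.0 < lo < hi < nyq):
                raise FilterDesignError(
                    f"band ({lo}, {hi}) Hz invalid for fs={fs} (Nyquist {nyq})"
                )


@dataclass(frozen=True)
class TimeStepSpec:
    """Multi-scale analysis windows in seconds relative to trial start."""

    intervals: tuple = DEFAULT_INTERVALS
    reference: str = "trial_start"

    def validate(self) -> None:
        for start, end in self.intervals:
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) has end <= start")

    def n_samples(self, fs: float):
        return tuple(int(round((e - s) * fs)) for s, e in self.intervals)


@dataclass
class RealizedFilterBank:
    """Designed second-order-section coefficients per band."""

    spec: FilterBankSpec
    fs: float
    sos: tuple  # tuple of [n_sections x 6] arrays

    @property
    def n_bands(self) -> int:
        return len(self.sos)


@dataclass
class MultiScaleBandTensor:
    """Blocks ``(band, step) -> [n_trials x n_channels x n_samples(step)]``."""

    blocks: dict
    bands: tuple
    intervals: tuple
    fs: float
    labels: np.ndarray = None

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_steps(self) -> int:
        return len(self.intervals)

    def block(self, band: int, step: int) -> np.ndarray:
        return self.blocks[(band, step)]


def design_filter_bank(spec: FilterBankSpec, fs: float) -> RealizedFilterBank:
    """Design one band-pass filter per band; raises on invalid edges."""
    spec.validate(fs)
    sos = tuple(
        signal.butter(spec.filter_order, [lo, hi], btype="bandpass", fs=fs,
                      output="sos")
        for lo, hi in spec.bands
    )
    return RealizedFilterBank(spec=spec, fs=fs, sos=sos)


def band_response(bank: RealizedFilterBank, band: int, freqs_hz) -> np.ndarray:
    """Magnitude response of one band filter at the given frequencies.

    Zero-phase (forward-backward) application squares the magnitude response;
    the returned values reflect the mode the bank is applied in.
    """
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / bank.fs
    _, h = signal.sosfreqz(bank.sos[band], worN=w)
    mag = np.abs(h)
    return mag ** 2 if bank.spec.zero_phase else mag


def apply_filter_bank(recording: EpochedRecording,
                      bank: RealizedFilterBank) -> np.ndarray:
    """Filter every trial/channel with every band.

    Returns ``[n_trials x n_bands x n_channels x n_samples]``.  Zero-phase mode
    uses forward-backward filtering (no group delay); otherwise a causal pass.
    """
    if recording.fs != bank.fs:
        raise ValueError(
            f"recording fs {recording.fs} != filter design fs {bank.fs}"
        )
    x = recording.signals
    out = np.empty((x.shape[0], bank.n_bands) + x.shape[1:], dtype=float)
    for b, sos in enumerate(bank.sos):
        if bank.spec.zero_phase:
            out[:, b] = signal.sosfiltfilt(sos, x, axis=-1)
        else:
            out[:, b] = signal.sosfilt(sos, x, axis=-1)
    return out


def segment_time_steps(band_tensor: np.ndarray, steps: TimeStepSpec, fs: float,
                       bands: tuple = DEFAULT_BANDS,
                       labels: np.ndarray = None) -> MultiScaleBandTensor:
    """Slice each band signal into the multi-scale windows.

    Sample indexing: start index ``round(start*fs)``, block length
    ``round((end-start)*fs)``, half-open — interval lengths (not endpoints)
    drive downstream shapes.
    """
    steps.validate()
    if band_tensor.ndim != 4:
        raise ValueError("expected [n_trials x n_bands x n_channels x n_samples]")
    n_samples = band_tensor.shape[-1]
    blocks = {}
    for t, (start, end) in enumerate(steps.intervals):
        i0 = int(round(start * fs))
        length = int(round((end - start) * fs))
        i1 = i0 + length
        if i0 < 0 or i1 > n_samples:
            raise IndexError(
                f"interval ({start}, {end}) s -> samples [{i0}, {i1}) outside "
                f"epoch of {n_samples} samples"
            )
        for b in range(band_tensor.shape[1]):
            blocks[(b, t)] = band_tensor[:, b, :, i0:i1]
    return MultiScaleBandTensor(
        blocks=blocks, bands=tuple(bands), intervals=tuple(steps.intervals),
        fs=fs, labels=labels,
    )
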