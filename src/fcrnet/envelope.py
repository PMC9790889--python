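"""Hilbert-envelope extraction and unified-length resampling.

The envelope (magnitude of the analytic signal) of a narrow-band spatially
filtered component varies slowly — its spectral content is kept below 4 Hz
here — so each time-step window can be down-sampled aggressively.  Every
window, whatever its duration, is resampled to the same number of points
(default 40: the 4 s window at an effective 10 Hz), giving the network a
rectangular input regardless of the multi-scale segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "EnvelopeTensor",
    "analytic_envelope",
    "lowpass_resample",
    "envelope_pipeline",
]

#: Envelope band limit (Hz); the minimum alias-free output rate is twice this.
ENVELOPE_CUTOFF_HZ = 4.0


class NyquistViolationError(ValueError):
    """Requested output rate cannot represent the 4 Hz-limited envelope."""


@dataclass
class EnvelopeTensor:
    """Envelope features ``[n_trials x N_F x N_T x n_components x n_points]``.

    ``n_components`` is ``n_contrasts * 2M`` after CSP projection (or the
    channel count when envelopes are taken on raw channels).
    """

    values: np.ndarray
    n_points: int
    effective_rates_hz: tuple  # per time-step window
    bands: tuple = ()
    intervals: tuple = ()

    def as_epochs(self) -> np.ndarray:
        """Flatten to ``[n_trials x (N_F*N_T*components) x n_points]``.

        This is the "envelope" network input mode: every (band, window,
        component) envelope becomes one row of a rectangular epoch image.
        """
        v = self.values
        return v.reshape(v.shape[0], -1, v.shape[-1])


def analytic_envelope(x: np.ndarray, pad_fraction: float = 0.1) -> np.ndarray:
    """Magnitude of the analytic signal along the last axis.

    Uses the frequency-domain Hilbert transform with reflective padding
    (``pad_fraction`` of the window on each side, trimmed afterwards) to tame
    the transform's edge artifacts.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 4:
        raise ValueError("signal too short for envelope extraction")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN/Inf")
    pad = int(np.ceil(pad_fraction * x.shape[-1])) if pad_fraction > 0 else 0
    if pad > 0:
        xp = np.concatenate(
            [x[..., 1:pad + 1][..., ::-1], x, x[..., -pad - 1:-1][..., ::-1]],
            axis=-1,
        )
    else:
        xp = x
    env = np.abs(signal.hilbert(xp, axis=-1))
    return env[..., pad:pad + x.shape[-1]] if pad else env


def lowpass_resample(envelope: np.ndarray, fs_in: float, n_points_target: int,
                     cutoff_hz: float = ENVELOPE_CUTOFF_HZ) -> np.ndarray:
    """Anti-alias low-pass then resample the last axis to exactly ``n_points``.

    The implied output rate ``n_points_target / duration`` must be at least
    ``2 * cutoff_hz`` (8 Hz for the 4 Hz envelope band).  Non-integer ratios
    are handled by polyphase resampling, so a 1 s window and a 4 s window both
    land on the same number of points.
    """
    envelope = np.asarray(envelope, dtype=float)
    n_in = envelope.shape[-1]
    if n_points_target < 2:
        raise ValueError("need at least 2 output points")
    duration = n_in / fs_in
    fs_out = n_points_target / duration
    if fs_out < 2.0 * cutoff_hz:
        raise NyquistViolationError(
            f"target {n_points_target} points over {duration:.3g} s implies "
            f"{fs_out:.3g} Hz < Nyquist rate {2 * cutoff_hz:.3g} Hz for a "
            f"{cutoff_hz:g} Hz-limited envelope"
        )
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs_in, output="sos")
    smooth = signal.sosfiltfilt(sos, envelope, axis=-1)
    from math import gcd
    g = gcd(n_points_target, n_in)
    up, down = n_points_target // g, n_in // g
    out = signal.resample_poly(smooth, up, down, axis=-1, padtype="mean")
    assert out.shape[-1] == n_points_target
    # the low-pass can undershoot slightly below zero; amplitudes are
    # physically nonnegative
    return np.maximum(out, 0.0)


def envelope_pipeline(projected: dict, fs: float, n_points: int = 40,
                      bands: tuple = (), intervals: tuple = ()) -> EnvelopeTensor:
    """Envelope + unified resampling over all projected (band, step) blocks.

    ``projected`` maps ``(band, step, contrast) -> [n_trials x comps x n_s]``
    (the output of :func:`fcrnet.csp.projected_blocks`).  Components of all
    contrasts are stacked on one axis.
    """
    keys = sorted(projected.keys(), key=lambda k: (k[0], k[1], str(k[2])))
    band_ids = sorted({k[0] for k in keys})
    step_ids = sorted({k[1] for k in keys})
    contrast_ids = sorted({str(k[2]) for k in keys})
    first = projected[keys[0]]
    n_trials, n_comp = first.shape[0], first.shape[1]
    n_components = n_comp * len(contrast_ids)
    values = np.empty((n_trials, len(band_ids), len(step_ids), n_components,
                       n_points))
    rates = {}
    for (b, t, contrast) in keys:
        x = projected[(b, t, contrast)]
        env = analytic_envelope(x)
        res = lowpass_resample(env, fs, n_points)
        ci = contrast_ids.index(str(contrast))
        values[:, band_ids.index(b), step_ids.index(t),
               ci * n_comp:(ci + 1) * n_comp, :] = res
        rates[t] = n_points / (x.shape[-1] / fs)
    return EnvelopeTensor(
        values=values, n_points=n_points,
        effective_rates_hz=tuple(rates[t] for t in step_ids),
        bands=bands, intervals=intervals,
    )
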