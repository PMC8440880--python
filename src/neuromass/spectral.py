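"""STFT spectrograms of simulated mean membrane potentials.

Power is normalised to its global maximum, displayed on a log10 scale and
clipped below 1e-2 (i.e. the grid lives in [-2, 0]); the time axis is
shifted right by half a window (0.1 s for the default 0.2 s window) so
features line up causally with the stimulus onset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

__all__ = ["Spectrogram", "spectrogram"]


@dataclass
class Spectrogram:
    """Normalised log-power grid: times in s, freqs in Hz, power in [-2, 0]."""

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # shape (n_freqs, n_times)

    def to_frame(self):
        import pandas as pd

        t, f = np.meshgrid(self.times, self.freqs)
        return pd.DataFrame({
            "time_s": t.ravel(), "freq_hz": f.ravel(),
            "log10_power": self.power.ravel(),
        })


def spectrogram(
    signals: np.ndarray,
    dt_ms: float,
    window_s: float = 0.2,
    overlap: float = 0.95,
    mode: str = "single",
    time_shift_s: float = 0.1,
    clip_log: float = -2.0,
) -> Spectrogram:
    """Short-time Fourier spectrogram of one or several voltage traces.

    ``signals`` is (n_samples,) or (n_pop, n_samples) on a uniform grid of
    step ``dt_ms``.  Hann window, no detrending, one-sided spectrum; hop =
    (1 - overlap) * window, with slice k covering samples
    [k*hop, k*hop + window) — hence floor((L - window)/hop) + 1 slices.
    In ``population_average`` mode the per-signal power grids are averaged
    before normalisation.  The result is divided by its global maximum,
    log10-transformed and clipped at ``clip_log`` (overall scaling of the
    input therefore cancels).
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    fs = 1000.0 / dt_ms
    nperseg = int(round(window_s * fs))
    hop = max(1, int(round((1.0 - overlap) * nperseg)))
    if x.shape[1] < nperseg:
        raise ValueError(
            f"signal length {x.shape[1]} shorter than the window "
            f"({nperseg} samples)"
        )
    if mode not in ("single", "population_average"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "single" and x.shape[0] != 1:
        raise ValueError("mode='single' expects exactly one signal")

    win = hann(nperseg, sym=False)
    frames = sliding_window_view(x, nperseg, axis=1)[:, ::hop, :]
    spec = np.fft.rfft(frames * win, axis=-1)
    power = (np.abs(spec) ** 2).mean(axis=0).T  # (n_freqs, n_slices)

    power = power / power.max()
    with np.errstate(divide="ignore"):
        logp = np.log10(power)
    logp = np.maximum(logp, clip_log)
    times = np.arange(power.shape[1]) * hop / fs + time_shift_s
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return Spectrogram(times=times, freqs=freqs, power=logp)
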