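"""Vertical-signal smoothing ahead of extrema detection.

The default is convolution with a 40-sample Hanning window at 100 Hz —
short enough to stay under half a typical gait cycle (0.5 s) so that one
peak and one valley survive per cycle.  The kernel is normalized to unit
sum, so a constant signal passes through unchanged (unit DC gain); an
unnormalized window would rescale the signal.  Edges are handled by
reflection, which avoids manufacturing boundary extrema.  A Savitzky–Golay
low-pass is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigurationError

MAX_WINDOW_S = 0.5


@dataclass(frozen=True)
class SmoothingConfig:
    """Smoothing method and window size.

    ``window_samples`` wins when both it and ``window_s`` are given;
    ``window_s`` (default 0.4 s) keeps the under-half-a-cycle rule on
    data that is not sampled at 100 Hz.
    """

    method: str = "hanning_convolution"
    window_samples: int | None = None
    window_s: float = 0.4
    sg_polyorder: int = 3

    def resolve_window(self, fs: float) -> int:
        n = (
            self.window_samples
            if self.window_samples is not None
            else int(round(self.window_s * fs))
        )
        if n < 3:
            raise ConfigurationError("window_samples must be >= 3")
        if n / fs >= MAX_WINDOW_S:
            raise ConfigurationError(
                f"window_samples={n} spans {n / fs:.2f} s at {fs:g} Hz; "
                f"the window must stay under {MAX_WINDOW_S} s "
                "(half a typical gait cycle)"
            )
        return n


def hanning_kernel(window_samples: int) -> np.ndarray:
    """Unit-sum Hanning window of the given length."""
    w = np.hanning(window_samples)
    return w / w.sum()


def smooth(
    signal: np.ndarray, fs: float, config: SmoothingConfig | None = None
) -> np.ndarray:
    """Smooth one signal; output has the same length as the input."""
    if config is None:
        config = SmoothingConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("smooth expects a 1-D signal")
    n = config.resolve_window(fs)
    if len(x) <= n:
        raise ConfigurationError(
            f"signal length {len(x)} must exceed the {n}-sample window"
        )
    if config.method == "hanning_convolution":
        kernel = hanning_kernel(n)
        left = (n - 1) // 2
        right = n - 1 - left
        padded = np.pad(x, (left, right), mode="reflect")
        return np.convolve(padded, kernel, mode="valid")
    if config.method == "savitzky_golay":
        win = n if n % 2 == 1 else n + 1
        return savgol_filter(
            x, window_length=win, polyorder=config.sg_polyorder, mode="mirror"
        )
    raise ConfigurationError(f"unknown smoothing method {config.method!r}")
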