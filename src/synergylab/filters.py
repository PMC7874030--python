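"""Zero-phase Butterworth filtering and finite-difference derivatives."""

from __future__ import annotations

import numpy as np
from scipy import signal


def butter_zero_phase(x: np.ndarray, cutoff: float, rate: float,
                      btype: str = "lowpass", order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth filter (no phase lag).

    ``order`` is the per-pass order; the forward-backward application doubles
    the effective attenuation order, matching common surface-EMG practice.
    """
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2})")
    sos = signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def derivative(x: np.ndarray, rate: float, n: int = 1) -> np.ndarray:
    """n-th time derivative by repeated central differences (np.gradient)."""
    out = np.asarray(x, dtype=float)
    for _ in range(n):
        out = np.gradient(out, 1.0 / rate, axis=-1)
    return out
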