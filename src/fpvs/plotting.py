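"""Static topography and spectrum figures (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .simulate import SensorLayout
from .spectral import SNRSpectrum

__all__ = ["plot_topography", "plot_snr_spectrum"]


def plot_topography(layout: SensorLayout, values: np.ndarray, ax=None, **scatter_kw):
    """Scatter per-sensor values on the 2D projected layout."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(
        layout.projection[:, 0],
        layout.projection[:, 1],
        c=np.asarray(values, dtype=float),
        **scatter_kw,
    )
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(sc, ax=ax)
    return ax


def plot_snr_spectrum(snr: SNRSpectrum, sensor: int = 0, fmax: float | None = None, ax=None):
    """SNR as a function of frequency for one sensor; noise level 1 dashed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = snr.valid_mask.copy()
    if fmax is not None:
        mask &= snr.freq_grid <= fmax
    ax.plot(snr.freq_grid[mask], snr.values[sensor, mask], lw=0.8)
    ax.axhline(1.0, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("SNR")
    return ax
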