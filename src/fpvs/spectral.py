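"""Frequency-domain reduction of trial recordings to oddball-response scalars.

The steady-state logic of frequency tagging: trials are trimmed and averaged
in the time domain (phase-locked responses survive averaging, noise does not),
Fourier-transformed without windowing, and expressed as an amplitude spectrum
sqrt(Re^2 + Im^2) / N per sensor and bin. Each bin is then normalized by the
mean of 20 surrounding bins (10 per side, skipping the immediately adjacent
bin) to give a signal-to-noise ratio (SNR) spectrum that equals ~1 for noise.
The oddball response is the mean SNR at the oddball frequency bin and its
first three harmonics.

The trimmed-epoch duration fixes the frequency grid: a 58.333-s epoch gives a
bin spacing of 1/58.333 = 0.0171 Hz. Harmonic targets are defined as exact
multiples of the *realized* fundamental bin frequency, so a realized
fundamental of 1.1962 Hz yields targets at 2.3924, 3.5886, and 4.7848 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .cluster import AdjacencyGraph
from .simulate import TrialRecording

__all__ = [
    "Epoch",
    "save_epoch",
    "load_epoch",
    "save_spectrum",
    "load_spectrum",
    "AmplitudeSpectrum",
    "SNRSpectrum",
    "OddballTargets",
    "OddballResponse",
    "ResponseDataset",
    "trim_and_average",
    "amplitude_spectrum",
    "snr_spectrum",
    "oddball_bins",
    "oddball_response",
    "interpolate_channels",
]


@dataclass
class Epoch:
    """A trimmed, trial-averaged sensor x time window."""

    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("epoch must be a 2D sensor x time matrix")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]


@dataclass
class AmplitudeSpectrum:
    """Per-sensor one-sided amplitude spectrum |X_k| / N on grid k / duration."""

    values: np.ndarray  # (n_sensors, n_bins)
    freq_grid: np.ndarray  # (n_bins,)
    n_points: int

    @property
    def bin_spacing(self) -> float:
        return float(self.freq_grid[1] - self.freq_grid[0])


@dataclass
class SNRSpectrum:
    """Amplitude spectrum normalized by the local baseline of surrounding bins.

    ``values`` is NaN wherever the full baseline window would run off the
    grid; ``valid_mask`` marks bins with a complete baseline.
    """

    values: np.ndarray
    freq_grid: np.ndarray
    valid_mask: np.ndarray
    n_side: int
    gap: int


@dataclass
class OddballTargets:
    """Target bins: the realized fundamental bin and its exact multiples."""

    bins: np.ndarray
    freqs: np.ndarray

    @property
    def n_harmonics(self) -> int:
        return len(self.bins)


@dataclass
class OddballResponse:
    """Per-sensor mean SNR over the oddball fundamental + harmonic bins."""

    values: np.ndarray  # (n_sensors,)
    target_bins: np.ndarray
    target_freqs: np.ndarray


@dataclass
class ResponseDataset:
    """Subjects x conditions x sensors tensor of oddball-response scalars."""

    tensor: np.ndarray
    subjects: list
    conditions: list
    sensor_ids: list

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        want = (len(self.subjects), len(self.conditions), len(self.sensor_ids))
        if self.tensor.shape != want:
            raise ValueError(f"tensor shape {self.tensor.shape} != labels {want}")

    @property
    def size(self) -> int:
        return int(self.tensor.size)

    def condition_matrix(self, condition) -> np.ndarray:
        """Subjects x sensors matrix for one condition."""
        return self.tensor[:, self.conditions.index(condition), :]

    def to_long_frame(self) -> pd.DataFrame:
        subj, cond, sens = np.meshgrid(
            np.arange(len(self.subjects)),
            np.arange(len(self.conditions)),
            np.arange(len(self.sensor_ids)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "subject": np.asarray(self.subjects)[subj.ravel()],
                "condition": np.asarray(self.conditions)[cond.ravel()],
                "sensor": np.asarray(self.sensor_ids)[sens.ravel()],
                "response": self.tensor.ravel(),
            }
        )

    def write(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ResponseDataset":
        df = pd.read_csv(path, sep="\t")
        subjects = sorted(df["subject"].unique().tolist())
        conditions = sorted(df["condition"].unique().tolist())
        sensors = df["sensor"].unique().tolist()
        tensor = (
            df.set_index(["subject", "condition", "sensor"])["response"]
            .unstack(["condition", "sensor"])  # noqa: PD010 - keeps sensor order
            .to_numpy()
            .reshape(len(subjects), len(conditions), len(sensors))
        )
        return cls(tensor, subjects, conditions, sensors)


def save_epoch(epoch: Epoch, path) -> None:
    """Write an epoch to HDF5 with a JSON header attribute."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("data", data=epoch.data)
        ds.attrs["header"] = json.dumps(
            {"sampling_rate": epoch.sampling_rate, "duration": epoch.duration}
        )


def load_epoch(path) -> Epoch:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        header = json.loads(fh["data"].attrs["header"])
        return Epoch(fh["data"][()], header["sampling_rate"])


def save_spectrum(amp: AmplitudeSpectrum, path) -> None:
    """Write an amplitude spectrum (values + frequency grid) to HDF5."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=amp.values)
        fh.create_dataset("freq_grid", data=amp.freq_grid)
        ds.attrs["header"] = json.dumps({"n_points": amp.n_points})


def load_spectrum(path) -> AmplitudeSpectrum:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        header = json.loads(fh["values"].attrs["header"])
        return AmplitudeSpectrum(
            fh["values"][()], fh["freq_grid"][()], header["n_points"]
        )


def trim_and_average(
    trials: list[TrialRecording], head_trim: float, tail_trim: float = 0.0
) -> Epoch:
    """Crop each trial to [head_trim, duration - tail_trim) and average.

    The head trim drops the onset transient (the reference configuration cuts
    the first two oddball cycles, 1.667 s, of each 60-s trial, leaving the
    58.333-s epoch that fixes the 0.0171-Hz frequency grid).
    """
    if not trials:
        raise ValueError("need at least one trial")
    shapes = {t.data.shape for t in trials}
    rates = {t.sampling_rate for t in trials}
    if len(shapes) != 1 or len(rates) != 1:
        raise ValueError("all trials must share shape and sampling rate")
    fs = trials[0].sampling_rate
    n = trials[0].data.shape[1]
    if head_trim < 0 or tail_trim < 0 or head_trim + tail_trim >= n / fs:
        raise ValueError("trims must be non-negative and leave a non-empty epoch")
    start = int(round(head_trim * fs))
    stop = n - int(round(tail_trim * fs))
    data = np.mean([t.data[:, start:stop] for t in trials], axis=0)
    return Epoch(data=data, sampling_rate=fs)


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """One-sided DFT amplitude spectrum, sqrt(Re^2 + Im^2) / N per bin.

    No windowing or detrending; the DC bin is retained. A sinusoid of
    amplitude A at an exact bin frequency contributes A/2 at that bin.
    """
    n = epoch.data.shape[1]
    spec = np.abs(np.fft.rfft(epoch.data, axis=1)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.sampling_rate)
    return AmplitudeSpectrum(values=spec, freq_grid=freqs, n_points=n)


def snr_spectrum(
    amp: AmplitudeSpectrum, n_side: int = 10, gap: int = 1
) -> SNRSpectrum:
    """Normalize each bin by the mean of surrounding bins.

    The baseline of bin k is the mean of bins k +/- (gap+1) ... k +/-
    (gap+n_side): 20 bins with the defaults, excluding the immediately
    adjacent bin on each side. Bins whose baseline window runs off the grid
    are flagged invalid (NaN) rather than normalized by a truncated window.
    """
    n_bins = amp.values.shape[1]
    half = gap + n_side
    if n_bins < 2 * half + 1:
        raise ValueError(
            f"spectrum has {n_bins} bins; need at least {2 * half + 1} "
            f"for an n_side={n_side}, gap={gap} baseline"
        )
    kernel = np.zeros(2 * half + 1)
    kernel[:n_side] = 1.0
    kernel[-n_side:] = 1.0
    kernel /= 2 * n_side
    baseline = convolve1d(amp.values, kernel[::-1], axis=1, mode="constant")
    valid = np.zeros(n_bins, dtype=bool)
    valid[half : n_bins - half] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        values = amp.values / baseline
    values[:, ~valid] = np.nan
    return SNRSpectrum(
        values=values,
        freq_grid=amp.freq_grid,
        valid_mask=valid,
        n_side=n_side,
        gap=gap,
    )


def oddball_bins(
    freq_grid: np.ndarray, oddball_freq: float, n_harmonics: int = 4
) -> OddballTargets:
    """Locate the oddball fundamental bin and its harmonic bins.

    The fundamental is the grid bin nearest ``oddball_freq`` (ties break to
    the lower bin); harmonics h = 2..n_harmonics are the exact bin multiples
    h * k1, so the realized harmonic frequencies are exact multiples of the
    realized fundamental.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    df = freq_grid[1] - freq_grid[0]
    x = oddball_freq / df
    k = int(np.floor(x))
    k1 = k if (x - k) <= 0.5 else k + 1
    if k1 < 1:
        raise ValueError(f"oddball frequency {oddball_freq} Hz maps to the DC bin")
    bins = k1 * np.arange(1, n_harmonics + 1)
    if bins[-1] >= len(freq_grid):
        raise ValueError(
            f"harmonic {n_harmonics} (bin {bins[-1]}) exceeds the grid "
            f"({len(freq_grid)} bins)"
        )
    return OddballTargets(bins=bins, freqs=bins * df)


def oddball_response(snr: SNRSpectrum, targets: OddballTargets) -> OddballResponse:
    """Per-sensor mean SNR over the target bins."""
    for b in targets.bins:
        if b >= len(snr.valid_mask) or not snr.valid_mask[b]:
            raise ValueError(f"target bin {b} lacks a complete baseline window")
    values = snr.values[:, targets.bins].mean(axis=1)
    return OddballResponse(
        values=values, target_bins=targets.bins, target_freqs=targets.freqs
    )


def interpolate_channels(
    trial: TrialRecording, bad: set, adjacency: AdjacencyGraph
) -> TrialRecording:
    """Replace bad sensors by the inverse-distance-weighted mean of good neighbors.

    Neighborhoods come from the triangulation-based adjacency graph; weights
    are inverse 3D distances. Good sensors are untouched; a bad sensor with
    no good neighbor raises.
    """
    bad = {int(b) for b in bad}
    if not bad:
        return trial
    if adjacency.positions is None:
        raise ValueError("adjacency graph carries no sensor positions")
    if max(bad) >= trial.n_sensors:
        raise ValueError("bad sensor index outside the recording")
    data = trial.data.copy()
    for b in bad:
        good = [j for j in adjacency.neighbors[b] if j not in bad]
        if not good:
            raise ValueError(f"bad sensor {b} has no good neighbor to interpolate from")
        d = np.linalg.norm(
            adjacency.positions[good] - adjacency.positions[b], axis=1
        )
        w = 1.0 / d
        data[b] = (w[:, None] * trial.data[good]).sum(axis=0) / w.sum()
    return TrialRecording(data=data, sampling_rate=trial.sampling_rate, t0=trial.t0)
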