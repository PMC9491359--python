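"""Synthetic FPVS-MEG cohorts with known ground truth.

The generator emulates the measurement situation of a frequency-tagging
oddball experiment: a 160-sensor whole-head layout sampled at 250 Hz, 60-s
trials containing a steady-state response at the 6-Hz base rate, an oddball
response at 1.2 Hz and its harmonics confined to a spatial subset of sensors,
1/f background activity plus white sensor noise, and multiplicative
between-subject amplitude variability. Responses are modeled directly as
sinusoids at the tagged frequencies — the analysis only observes the frequency
domain, so this gives exact ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .utils import derive_seed

__all__ = [
    "SensorLayout",
    "SimulationConfig",
    "TrialRecording",
    "CohortDataset",
    "make_layout",
    "patch_topography",
    "powerlaw_noise",
    "subject_params",
    "trial_seed",
    "simulate_trial",
    "simulate_cohort",
    "downsample",
    "save_cohort",
    "load_cohort",
]


@dataclass
class SensorLayout:
    """Sensor ids, 3D positions on the upper unit hemisphere, 2D projection."""

    sensor_ids: list[str]
    positions: np.ndarray  # (n, 3)
    projection: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.projection = np.asarray(self.projection, dtype=float)
        n = len(self.sensor_ids)
        if self.positions.shape != (n, 3) or self.projection.shape != (n, 2):
            raise ValueError("layout arrays inconsistent with sensor count")
        if len({tuple(p) for p in np.round(self.positions, 12)}) != n:
            raise ValueError("sensor positions must be unique")

    def __len__(self) -> int:
        return len(self.sensor_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sensor_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "px": self.projection[:, 0],
                "py": self.projection[:, 1],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SensorLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sensor_ids=[str(s) for s in df["id"]],
            positions=df[["x", "y", "z"]].to_numpy(),
            projection=df[["px", "py"]].to_numpy(),
        )


def make_layout(n_sensors: int, seed: int | None = None) -> SensorLayout:
    """Quasi-uniform sensor placement on the upper unit hemisphere.

    Uses a Fibonacci lattice restricted to z >= 0 plus an azimuthal-equidistant
    2D projection (polar angle as radius), which keeps the triangulation of
    the projection faithful to on-sphere neighborhoods. Deterministic; ``seed``
    is accepted for interface symmetry but unused.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors to triangulate a layout")
    i = np.arange(n_sensors)
    z = (i + 0.5) / n_sensors  # upper hemisphere only
    r = np.sqrt(1.0 - z**2)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = i * golden
    pos = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    theta = np.arccos(np.clip(z, -1, 1))  # polar angle from the vertex
    proj = np.column_stack([theta * np.cos(az), theta * np.sin(az)])
    ids = [f"MEG{k:03d}" for k in range(n_sensors)]
    return SensorLayout(ids, pos, proj)


def patch_topography(
    layout: SensorLayout, center: np.ndarray | int, radius: float
) -> np.ndarray:
    """Binary per-sensor weights: 1 within an angular radius of a center.

    ``center`` is a 3-vector direction or a sensor index; ``radius`` is the
    great-circle angular radius in radians.
    """
    if np.isscalar(center):
        c = layout.positions[int(center)]
    else:
        c = np.asarray(center, dtype=float)
    c = c / np.linalg.norm(c)
    cosang = layout.positions @ c / np.linalg.norm(layout.positions, axis=1)
    return (np.arccos(np.clip(cosang, -1, 1)) <= radius).astype(float)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic cohort.

    Amplitudes are in arbitrary field units (only the SNR matters downstream);
    ``base_amplitudes[h]`` / ``oddball_amplitudes[h]`` drive the (h+1)-th
    harmonic of the 6-Hz base / 1.2-Hz oddball response. ``topography`` and
    ``base_topography`` are per-sensor weights in [0, 1] (None = uniform).
    ``subject_sd`` is the log-scale spread of multiplicative subject gains.
    """

    n_sensors: int = 160
    sampling_rate: float = 250.0
    trial_duration: float = 60.0
    n_trials: int = 5
    base_freq: float = 6.0
    oddball_freq: float = 1.2
    base_amplitudes: tuple = (1.0, 0.4)
    oddball_amplitudes: tuple = (0.08, 0.06, 0.04, 0.025)
    topography: np.ndarray | None = None
    base_topography: np.ndarray | None = None
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    white_scale: float = 0.3
    subject_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        period = self.base_freq / self.oddball_freq
        if abs(period - round(period)) > 1e-9:
            raise ValueError(
                "base_freq must be an integer multiple of oddball_freq, got "
                f"{self.base_freq}/{self.oddball_freq}"
            )
        if any(a < 0 for a in self.base_amplitudes) or any(
            a < 0 for a in self.oddball_amplitudes
        ):
            raise ValueError("amplitudes must be non-negative")
        nyq = self.sampling_rate / 2.0
        fmax = max(
            len(self.base_amplitudes) * self.base_freq,
            len(self.oddball_amplitudes) * self.oddball_freq,
        )
        if fmax >= nyq:
            raise ValueError(
                f"highest generated frequency {fmax} Hz >= Nyquist {nyq} Hz"
            )
        for name in ("topography", "base_topography"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float)
                if w.shape != (self.n_sensors,):
                    raise ValueError(f"{name} must have shape ({self.n_sensors},)")
                if np.any(w < 0) or np.any(w > 1):
                    raise ValueError(f"{name} weights must lie in [0, 1]")
                setattr(self, name, w)

    @property
    def oddball_period(self) -> int:
        return int(round(self.base_freq / self.oddball_freq))

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
            elif isinstance(v, tuple):
                d[k] = list(v)
            else:
                d[k] = v
        return d


@dataclass
class TrialRecording:
    """One trial: a dense sensor x time matrix in arbitrary field units."""

    data: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a 2D sensor x time matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data must be finite")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


def powerlaw_noise(
    n_channels: int,
    n_samples: int,
    exponent: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Colored noise with power spectral density proportional to f**(-exponent).

    Generated by spectral shaping: white Gaussian noise is transformed to the
    frequency domain, each bin scaled by f**(-exponent/2), and transformed
    back; each channel is normalized to unit standard deviation.
    """
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    colored = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = colored.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return colored / sd


def _signal_matrix(
    config: SimulationConfig,
    subject_gain: float,
    phases_base: np.ndarray,
    phases_odd: np.ndarray,
) -> np.ndarray:
    t = np.arange(config.n_samples) / config.sampling_rate
    base_w = (
        np.ones(config.n_sensors)
        if config.base_topography is None
        else config.base_topography
    )
    odd_w = (
        np.ones(config.n_sensors) if config.topography is None else config.topography
    )
    sig = np.zeros((config.n_sensors, config.n_samples))
    for h, amp in enumerate(config.base_amplitudes, start=1):
        sig += amp * np.outer(
            base_w, np.sin(2 * np.pi * h * config.base_freq * t + phases_base[h - 1])
        )
    for h, amp in enumerate(config.oddball_amplitudes, start=1):
        sig += (
            subject_gain
            * amp
            * np.outer(
                odd_w,
                np.sin(2 * np.pi * h * config.oddball_freq * t + phases_odd[h - 1]),
            )
        )
    return sig


def simulate_trial(
    config: SimulationConfig,
    subject_gain: float = 1.0,
    trial_seed: int | None = None,
    phases: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrialRecording:
    """Simulate a single trial: tagged sinusoids + 1/f noise + white noise.

    ``phases`` holds per-harmonic phase offsets (base, oddball); if omitted
    they are drawn from the trial seed. Noise is freshly drawn per trial.
    """
    rng = np.random.default_rng(trial_seed)
    if phases is None:
        phases = (
            rng.uniform(0, 2 * np.pi, len(config.base_amplitudes)),
            rng.uniform(0, 2 * np.pi, len(config.oddball_amplitudes)),
        )
    data = _signal_matrix(config, subject_gain, *phases)
    if config.noise_scale > 0:
        data = data + config.noise_scale * powerlaw_noise(
            config.n_sensors,
            config.n_samples,
            config.noise_exponent,
            config.sampling_rate,
            rng,
        )
    if config.white_scale > 0:
        data = data + config.white_scale * rng.standard_normal(
            (config.n_sensors, config.n_samples)
        )
    return TrialRecording(data=data, sampling_rate=config.sampling_rate)


def downsample(trial: TrialRecording, factor: int) -> TrialRecording:
    """Decimate a trial by an integer factor (anti-aliased via FFT resampling).

    The reference configuration simulates natively at the post-downsampling
    rate, so this is a pass-through hook for realism testing (factor 1).
    """
    if factor == 1:
        return trial
    from scipy.signal import resample

    n = trial.data.shape[1] // factor
    return TrialRecording(
        data=resample(trial.data, n, axis=1),
        sampling_rate=trial.sampling_rate / factor,
        t0=trial.t0,
    )


@dataclass
class CohortDataset:
    """Trials per (subject, condition) plus the generative ground truth."""

    layout: SensorLayout
    config: SimulationConfig
    trials: dict = field(default_factory=dict)  # (subject, condition) -> [TrialRecording]
    ground_truth: dict = field(default_factory=dict)  # subject -> dict

    @property
    def subjects(self) -> list:
        return sorted({s for s, _ in self.trials})

    @property
    def conditions(self) -> list:
        return sorted({c for _, c in self.trials})


def subject_params(
    config: SimulationConfig, base_seed: int, subject: int
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Deterministic per-subject gain and response phases.

    The gain is log-normal with log-sd ``config.subject_sd``; phases are
    uniform per harmonic and shared across that subject's trials. Keyed by a
    hash-derived sub-seed so cohorts can be generated eagerly or streamed
    trial-by-trial with identical results.
    """
    srng = np.random.default_rng(derive_seed(base_seed, "subject", subject))
    gain = float(np.exp(srng.normal(0.0, config.subject_sd)))
    phases = (
        srng.uniform(0, 2 * np.pi, len(config.base_amplitudes)),
        srng.uniform(0, 2 * np.pi, len(config.oddball_amplitudes)),
    )
    return gain, phases


def trial_seed(base_seed: int, subject: int, condition, trial: int) -> int:
    """Sub-seed for one trial's noise stream."""
    return derive_seed(base_seed, "trial", subject, condition, trial)


def simulate_cohort(
    n_subjects: int,
    config: SimulationConfig,
    condition_effects: Mapping[int, float],
    seed: int | None = None,
    layout: SensorLayout | None = None,
) -> CohortDataset:
    """Simulate a cohort: per-subject gains and phases, per-condition effects.

    ``condition_effects`` maps condition id -> multiplier applied to the
    oddball amplitudes (0 = that condition carries no oddball response).
    Subject gains are log-normal with log-sd ``config.subject_sd``. Every
    (subject, condition, trial) stream is keyed by a hash-derived sub-seed,
    so identical (seed, config) give bit-identical cohorts.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if layout is None:
        layout = make_layout(config.n_sensors)
    if len(layout) != config.n_sensors:
        raise ValueError("layout size does not match config.n_sensors")
    base = config.seed if seed is None else seed
    dataset = CohortDataset(layout=layout, config=config)
    for subj in range(n_subjects):
        gain, phases = subject_params(config, base or 0, subj)
        dataset.ground_truth[subj] = {
            "gain": gain,
            "phases_base": phases[0].tolist(),
            "phases_oddball": phases[1].tolist(),
            "config": config.to_dict(),
        }
        for cond, mult in condition_effects.items():
            cond_config = replace(
                config,
                oddball_amplitudes=tuple(
                    mult * a for a in config.oddball_amplitudes
                ),
            )
            recs = []
            for trial in range(config.n_trials):
                tseed = trial_seed(base or 0, subj, cond, trial)
                recs.append(
                    simulate_trial(cond_config, gain, tseed, phases=phases)
                )
            dataset.trials[(subj, cond)] = recs
    return dataset


def save_cohort(dataset: CohortDataset, outdir) -> Path:
    """Write a cohort as one HDF5 file per (subject, condition) + manifest."""
    import h5py

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.layout.write(outdir / "layout.tsv")
    files = {}
    for (subj, cond), recs in dataset.trials.items():
        name = f"subject{subj:03d}_condition{cond}.h5"
        with h5py.File(outdir / name, "w") as fh:
            for i, rec in enumerate(recs):
                ds = fh.create_dataset(f"trial{i:02d}", data=rec.data)
                ds.attrs["sampling_rate"] = rec.sampling_rate
                ds.attrs["t0"] = rec.t0
        files[f"{subj}/{cond}"] = name
    manifest = {
        "files": files,
        "config": dataset.config.to_dict(),
        "ground_truth": dataset.ground_truth,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def load_cohort(indir) -> CohortDataset:
    """Load a cohort written by :func:`save_cohort`."""
    import h5py

    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = dict(manifest["config"])
    for key in ("base_amplitudes", "oddball_amplitudes"):
        cfg[key] = tuple(cfg[key])
    for key in ("topography", "base_topography"):
        if cfg.get(key) is not None:
            cfg[key] = np.asarray(cfg[key], dtype=float)
    config = SimulationConfig(**cfg)
    dataset = CohortDataset(
        layout=SensorLayout.read(indir / "layout.tsv"),
        config=config,
        ground_truth={int(k): v for k, v in manifest["ground_truth"].items()},
    )
    for key, name in manifest["files"].items():
        subj, cond = (int(x) for x in key.split("/"))
        recs = []
        with h5py.File(indir / name, "r") as fh:
            for dsname in sorted(fh):
                ds = fh[dsname]
                recs.append(
                    TrialRecording(
                        data=ds[()],
                        sampling_rate=float(ds.attrs["sampling_rate"]),
                        t0=float(ds.attrs["t0"]),
                    )
                )
        dataset.trials[(subj, cond)] = recs
    return dataset
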