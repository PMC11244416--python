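"""Epoched ERP data: containers, synthetic CTP-paradigm generation, and I/O.

The central container is :class:`EpochSet`, holding stimulus-locked multichannel
EEG epochs (trials x channels x time, in microvolts) with binary labels
(1 = self-face / probe stimulus, 0 = stranger-face / irrelevant stimulus) and a
subject identifier per trial.

Because the study dataset this package targets is not publicly deposited, the
module also provides a synthetic generator that emulates the concealed-information
(CTP) face paradigm: probe epochs carry a P300-like positivity in the 300-500 ms
window, irrelevant epochs carry an N200-like negativity in the 180-250 ms window,
with a 1:4 probe:irrelevant imbalance, between-subject latency/amplitude
variability, a parietal-maximal scalp topography, and additive background noise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EpochSet",
    "SyntheticSpec",
    "generate_dataset",
    "average_blocks",
    "split_by_subject",
    "save_epochs",
    "load_epochs",
    "read_eeglab_epochs",
]


@dataclass
class EpochSet:
    """Labeled, subject-tagged multichannel EEG epochs.

    Parameters
    ----------
    data : ndarray of shape (n_trials, n_channels, n_samples)
        Epoch amplitudes in microvolts.
    labels : ndarray of shape (n_trials,)
        Binary trial labels; 1 = self-face (probe), 0 = stranger-face (irrelevant).
    subject_ids : ndarray of shape (n_trials,)
        Integer subject identifier per trial.
    sampling_rate : float
        Sampling rate in Hz.
    onset_offset : float
        Time of the first sample relative to stimulus onset, in ms.
    channel_names : list of str
        One name per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    sampling_rate: float
    onset_offset: float = 0.0
    channel_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        n, c, t = self.data.shape
        if c < 1 or t < 1:
            raise ValueError("need at least one channel and one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if self.labels.shape != (n,):
            raise ValueError(f"labels must have length {n}; got {self.labels.shape}")
        if self.subject_ids.shape != (n,):
            raise ValueError(f"subject_ids must have length {n}; got {self.subject_ids.shape}")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary (0 or 1)")
        self.labels = self.labels.astype(np.int64)
        self.subject_ids = self.subject_ids.astype(np.int64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(c)]
        self.channel_names = [str(nm) for nm in self.channel_names]
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must equal the channel count")

    # -- convenience ---------------------------------------------------------

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.onset_offset + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def subset(self, index: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial index."""
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            labels=self.labels[index],
            subject_ids=self.subject_ids[index],
            sampling_rate=self.sampling_rate,
            onset_offset=self.onset_offset,
            channel_names=list(self.channel_names),
        )


def _default_topography(n_channels: int, pz_index: int, width: float = 5.0) -> np.ndarray:
    """Gaussian gain profile over channel index, peaking (gain 1) at ``pz_index``."""
    idx = np.arange(n_channels, dtype=np.float64)
    g = np.exp(-0.5 * ((idx - pz_index) / width) ** 2)
    return g / g.max()


@dataclass
class SyntheticSpec:
    """Parameterization of the simulated CTP face-recognition ERP dataset.

    Amplitudes are in microvolts, latencies and windows in ms relative to
    stimulus onset.  Between-subject variability is modelled by drawing one
    latency and one amplitude per (subject, component); the component waveform
    is a half-period raised-cosine bump compactly supported inside its window.

    The default noise level (3 uV white noise) represents epochs *after*
    across-block averaging: raw single-trial EEG background of roughly 10 uV
    averaged over ~10 repetitions.
    """

    n_subjects: int = 10
    trials_per_subject: int = 60
    imbalance_ratio: int = 4          # irrelevant (negative) trials per probe (positive)
    n_channels: int = 30
    n_samples: int = 1000
    sampling_rate: float = 1000.0
    p300_window: Tuple[float, float] = (300.0, 500.0)
    p300_latency_mean: float = 400.0
    p300_latency_sd: float = 20.0
    p300_amplitude_mean: float = 5.0
    p300_amplitude_sd: float = 1.0
    n200_window: Tuple[float, float] = (180.0, 250.0)
    n200_latency_mean: float = 211.0
    n200_latency_sd: float = 8.0
    n200_amplitude_mean: float = -3.0
    n200_amplitude_sd: float = 0.6
    noise_sd: float = 3.0
    noise_spectral_exponent: float = 0.0  # 0 = white; >0 gives 1/f^a shaping
    pz_index: Optional[int] = None        # channel where components are maximal
    topography: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pz_index is None:
            self.pz_index = self.n_channels // 2
        if self.topography is None:
            self.topography = _default_topography(self.n_channels, self.pz_index)
        self.topography = np.asarray(self.topography, dtype=np.float64)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def validate(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial per subject")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.trials_per_subject < self.imbalance_ratio + 1:
            raise ValueError(
                "trials_per_subject must be at least imbalance_ratio + 1 "
                "to realize the class ratio"
            )
        for name, win in (("p300_window", self.p300_window), ("n200_window", self.n200_window)):
            lo, hi = win
            if not (0 <= lo < hi <= self.duration_ms):
                raise ValueError(f"{name}={win} must lie within [0, {self.duration_ms}] ms")
        if self.topography.shape != (self.n_channels,):
            raise ValueError("topography must have one gain per channel")
        if self.topography.min() < 0 or not np.isclose(self.topography.max(), 1.0):
            raise ValueError("topography gains must lie in [0, 1] with max = 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def channel_names(self) -> List[str]:
        names = [f"ch{i:02d}" for i in range(self.n_channels)]
        names[self.pz_index] = "Pz"
        return names


def _raised_cosine_bump(times_ms: np.ndarray, latency: float, amplitude: float,
                        window: Tuple[float, float]) -> np.ndarray:
    """Half-period raised-cosine deflection peaking at ``latency``.

    The half-width is the distance from the peak to the nearer window edge, so
    the bump is zero outside ``window`` by construction and attains exactly
    ``amplitude`` at the peak.
    """
    lo, hi = window
    half_width = min(latency - lo, hi - latency)
    if half_width <= 0:
        return np.zeros_like(times_ms)
    u = (times_ms - latency) / half_width
    bump = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
    return amplitude * bump


def _shaped_noise(rng: np.random.Generator, shape: Tuple[int, ...], sd: float,
                  exponent: float, sampling_rate: float) -> np.ndarray:
    """Gaussian noise with 1/f^exponent spectral shaping; white when exponent=0."""
    if sd == 0:
        return np.zeros(shape)
    if exponent == 0:
        return rng.normal(0.0, sd, size=shape)
    n = shape[-1]
    white = rng.normal(0.0, 1.0, size=shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return sd * shaped


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_dataset(spec: SyntheticSpec) -> EpochSet:
    """Simulate a CTP-paradigm ERP dataset according to ``spec``.

    Per subject, ``trials_per_subject`` epochs are produced at a
    1:``imbalance_ratio`` probe:irrelevant ratio (at least one probe).  Probe
    epochs carry the subject's P300 bump, irrelevant epochs the subject's N200
    bump; both are scaled by the scalp topography and summed with additive
    noise.  Subject latencies are snapped to the sample grid so the peak is
    attained exactly at a sample.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.sampling_rate
    times = np.arange(spec.n_samples) * dt

    n_pos = max(1, round(spec.trials_per_subject / (1 + spec.imbalance_ratio)))
    n_neg = spec.trials_per_subject - n_pos

    eps = 2 * dt  # keep peaks strictly inside their window so bumps have support
    data = np.empty((spec.n_subjects * spec.trials_per_subject,
                     spec.n_channels, spec.n_samples))
    labels = np.empty(data.shape[0], dtype=np.int64)
    subject_ids = np.empty(data.shape[0], dtype=np.int64)

    row = 0
    for s in range(spec.n_subjects):
        p3_lat = _clipped_normal(rng, spec.p300_latency_mean, spec.p300_latency_sd,
                                 spec.p300_window[0] + eps, spec.p300_window[1] - eps)
        p3_lat = round(p3_lat / dt) * dt
        p3_amp = max(0.1, rng.normal(spec.p300_amplitude_mean, spec.p300_amplitude_sd))
        n2_lat = _clipped_normal(rng, spec.n200_latency_mean, spec.n200_latency_sd,
                                 spec.n200_window[0] + eps, spec.n200_window[1] - eps)
        n2_lat = round(n2_lat / dt) * dt
        n2_amp = min(-0.1, rng.normal(spec.n200_amplitude_mean, spec.n200_amplitude_sd))

        p300 = _raised_cosine_bump(times, p3_lat, p3_amp, spec.p300_window)
        n200 = _raised_cosine_bump(times, n2_lat, n2_amp, spec.n200_window)

        subj_labels = np.concatenate([np.ones(n_pos, np.int64), np.zeros(n_neg, np.int64)])
        subj_labels = subj_labels[rng.permutation(spec.trials_per_subject)]

        for lab in subj_labels:
            component = p300 if lab == 1 else n200
            epoch = spec.topography[:, None] * component[None, :]
            epoch = epoch + _shaped_noise(
                rng, (spec.n_channels, spec.n_samples), spec.noise_sd,
                spec.noise_spectral_exponent, spec.sampling_rate)
            data[row] = epoch
            labels[row] = lab
            subject_ids[row] = s
            row += 1

    return EpochSet(data=data, labels=labels, subject_ids=subject_ids,
                    sampling_rate=spec.sampling_rate, onset_offset=0.0,
                    channel_names=spec.channel_names())


def average_blocks(es: EpochSet, group_size: int) -> EpochSet:
    """Average consecutive groups of ``group_size`` trials within (subject, label) strata.

    Mirrors the across-block averaging used to raise ERP signal-to-noise: each
    output trial is the pointwise mean of ``group_size`` input trials sharing
    subject and label; leftover trials that cannot fill a group are dropped.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size == 1:
        return es.subset(np.arange(len(es)))

    out_data, out_labels, out_subjects = [], [], []
    formed_any = False
    for subj in np.unique(es.subject_ids):
        for lab in (0, 1):
            idx = np.flatnonzero((es.subject_ids == subj) & (es.labels == lab))
            n_groups = len(idx) // group_size
            if n_groups == 0:
                continue
            formed_any = True
            for g in range(n_groups):
                members = idx[g * group_size:(g + 1) * group_size]
                out_data.append(es.data[members].mean(axis=0))
                out_labels.append(lab)
                out_subjects.append(subj)
    if not formed_any:
        raise ValueError(
            f"group_size={group_size} exceeds the size of every (subject, label) stratum"
        )
    return EpochSet(data=np.stack(out_data), labels=np.array(out_labels),
                    subject_ids=np.array(out_subjects),
                    sampling_rate=es.sampling_rate, onset_offset=es.onset_offset,
                    channel_names=list(es.channel_names))


def split_by_subject(es: EpochSet, train_fraction: float = 0.9, n_folds: int = 3,
                     seed: int = 0) -> List[Tuple[EpochSet, EpochSet]]:
    """Subject-disjoint train/test folds for cross-subject evaluation.

    Each fold holds out ``max(1, round(n_subjects * (1 - train_fraction)))``
    whole subjects for testing; test sets are disjoint across folds, drawn from
    a seed-shuffled subject order, and all remaining subjects train.  Trial
    order within the input never affects the assignment.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    subjects = np.unique(es.subject_ids)
    n_subjects = len(subjects)
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if n_folds > n_subjects:
        raise ValueError(f"n_folds={n_folds} exceeds the number of subjects ({n_subjects})")
    test_size = max(1, round(n_subjects * (1.0 - train_fraction)))
    if n_folds * test_size > n_subjects:
        raise ValueError(
            f"cannot draw {n_folds} disjoint test sets of {test_size} subjects "
            f"from {n_subjects} subjects"
        )
    order = subjects[np.random.default_rng(seed).permutation(n_subjects)]
    folds = []
    for f in range(n_folds):
        test_subjects = set(order[f * test_size:(f + 1) * test_size].tolist())
        test_mask = np.isin(es.subject_ids, list(test_subjects))
        folds.append((es.subset(np.flatnonzero(~test_mask)),
                      es.subset(np.flatnonzero(test_mask))))
    return folds


# -- container I/O -----------------------------------------------------------

_REQUIRED_DATASETS = ("data", "labels", "subject_ids")
_REQUIRED_ATTRS = ("sampling_rate", "onset_offset", "channel_names")


def save_epochs(es: EpochSet, path: str) -> None:
    """Write an EpochSet to an HDF5 container.

    Layout: datasets ``/data`` (n, C, T), ``/labels`` (n), ``/subject_ids`` (n)
    and root attributes ``sampling_rate``, ``onset_offset``, ``channel_names``.
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=es.data)
        f.create_dataset("labels", data=es.labels)
        f.create_dataset("subject_ids", data=es.subject_ids)
        f.attrs["sampling_rate"] = float(es.sampling_rate)
        f.attrs["onset_offset"] = float(es.onset_offset)
        f.attrs["channel_names"] = [str(n) for n in es.channel_names]


def load_epochs(path: str) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    import h5py

    if not os.path.exists(path):
        raise FileNotFoundError(f"no epoch container at {path!r}")
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise KeyError(f"epoch container is missing required dataset {name!r}")
        for name in _REQUIRED_ATTRS:
            if name not in f.attrs:
                raise KeyError(f"epoch container is missing required attribute {name!r}")
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["channel_names"]]
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            subject_ids=f["subject_ids"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            onset_offset=float(f.attrs["onset_offset"]),
            channel_names=names,
        )


def read_eeglab_epochs(path: str, positive_events: Sequence[str],
                       subject_id: int = 0) -> EpochSet:
    """Best-effort importer for EEGLAB ``.set`` epoch files (requires ``mne``).

    Events whose name is in ``positive_events`` are labeled 1, all others 0.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EEGLAB .set files requires the 'mne' package") from exc

    ep = mne.io.read_epochs_eeglab(path, verbose="error")
    inv = {v: k for k, v in ep.event_id.items()}
    labels = np.array([1 if inv[code] in positive_events else 0
                       for code in ep.events[:, 2]])
    return EpochSet(
        data=ep.get_data() * 1e6,  # volts -> microvolts
        labels=labels,
        subject_ids=np.full(len(labels), subject_id),
        sampling_rate=float(ep.info["sfreq"]),
        onset_offset=float(ep.times[0] * 1000.0),
        channel_names=list(ep.ch_names),
    )
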