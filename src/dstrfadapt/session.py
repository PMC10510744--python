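"""Core data containers for switching-noise stimulus sessions.

A session couples a mel-like stimulus spectrogram (100 Hz, 23 bands by
default), a schedule of background-noise segments, and an electrodes x time
response matrix normalized to a silent baseline interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: canonical background-condition labels
CONDITIONS = ("clean", "bar", "city", "jet")
NOISE_CONDITIONS = ("bar", "city", "jet")

DEFAULT_RATE = 100.0
DEFAULT_N_FREQ = 23


@dataclass
class Spectrogram:
    """Nonnegative time x frequency magnitude spectrogram.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_freq)
        Linear-magnitude bin values, finite and >= 0.
    rate : float
        Sampling rate in Hz (default 100).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float = DEFAULT_RATE
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (time x freq)")
        if not np.isfinite(self.values).all():
            raise ValueError("spectrogram values must be finite")
        if (self.values < 0).any():
            raise ValueError("spectrogram values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def slice_time(self, start_s: float, end_s: float) -> "Spectrogram":
        """Half-open time slice [start_s, end_s) in absolute seconds."""
        i0 = int(round((start_s - self.t0) * self.rate))
        i1 = int(round((end_s - self.t0) * self.rate))
        i0 = max(i0, 0)
        return Spectrogram(self.values[i0:i1], rate=self.rate,
                           t0=self.t0 + i0 / self.rate)


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    condition: str

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class NoiseSchedule:
    """Ordered background-condition segments tiling a session timeline.

    Segments are half-open ``[start, end)``; consecutive segments must
    differ in condition. ``block_bounds`` are the boundaries of the natural
    stimulus blocks used for jackknifing (length ``n_blocks + 1``).
    """

    segments: list[Segment]
    block_bounds: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = [Segment(*s) if not isinstance(s, Segment) else s
                for s in self.segments]
        self.segments = segs
        for a, b in zip(segs, segs[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("segments must tile with no gaps/overlaps")
            if a.condition == b.condition:
                raise ValueError("consecutive segments must differ")

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds) - 1

    def condition_at(self, t: float) -> str:
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg.condition
        raise ValueError(f"time {t} outside schedule")

    def transitions(self) -> list[tuple[float, str, str]]:
        """(time, from_condition, to_condition) at each segment boundary."""
        return [(b.start, a.condition, b.condition)
                for a, b in zip(self.segments, self.segments[1:])]

    def condition_labels(self, times: np.ndarray) -> np.ndarray:
        """Condition label for every time point (post-transition ownership)."""
        labels = np.empty(len(times), dtype=object)
        labels[:] = ""
        starts = np.array([s.start for s in self.segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        conds = np.array([s.condition for s in self.segments], dtype=object)
        inside = (times >= self.start) & (times < self.end)
        labels[inside] = conds[idx[inside]]
        return labels

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(s.start, s.end, s.condition) for s in self.segments],
            columns=["start_s", "end_s", "condition"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NoiseClassSpec:
    """Spectral description of one background-noise class.

    ``mean_spectrum`` is normalized to unit total power;
    ``stationarity`` in [0, 1] sets the temporal modulation depth
    (1 = fully stationary).
    """

    label: str
    mean_spectrum: np.ndarray
    stationarity: float

    def __post_init__(self) -> None:
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=float)
        if (self.mean_spectrum < 0).any():
            raise ValueError("mean_spectrum must be nonnegative")
        tot = self.mean_spectrum.sum()
        if tot <= 0:
            raise ValueError("mean_spectrum must have positive power")
        self.mean_spectrum = self.mean_spectrum / tot
        if not 0.0 <= self.stationarity <= 1.0:
            raise ValueError("stationarity must lie in [0, 1]")


@dataclass
class ResponseMatrix:
    """Electrodes x time response matrix with subject labels.

    Responses are z-scored to the silent ``baseline_window`` (absolute
    seconds): after normalization the baseline interval has per-electrode
    mean 0 and variance 1.
    """

    values: np.ndarray
    subject_ids: np.ndarray
    rate: float = DEFAULT_RATE
    baseline_window: tuple[float, float] = (0.0, 120.0)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("responses must be 2-D (electrodes x time)")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject label per electrode required")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def baseline_slice(self) -> slice:
        i0 = int(round((self.baseline_window[0] - self.t0) * self.rate))
        i1 = int(round((self.baseline_window[1] - self.t0) * self.rate))
        return slice(i0, i1)


def normalize_to_baseline(values: np.ndarray, baseline: slice) -> np.ndarray:
    """Z-score each row by the mean/sd of its baseline samples.

    Rows whose baseline is (numerically) constant are centered only, so a
    noiseless simulation remains finite.
    """
    base = values[:, baseline]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (values - mu) / sd


@dataclass
class Session:
    """One complete synthetic experiment: stimulus, schedule, responses."""

    stimulus: Spectrogram
    schedule: NoiseSchedule
    responses: ResponseMatrix
    noise_classes: list[NoiseClassSpec] = field(default_factory=list)
    clean_spectrum: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        seg = np.array([(s.start, s.end, s.condition)
                        for s in self.schedule.segments], dtype=object)
        payload = dict(
            stim_values=self.stimulus.values,
            stim_rate=self.stimulus.rate,
            stim_t0=self.stimulus.t0,
            seg_start=np.array([s.start for s in self.schedule.segments]),
            seg_end=np.array([s.end for s in self.schedule.segments]),
            seg_cond=np.array([s.condition for s in self.schedule.segments]),
            block_bounds=np.array(self.schedule.block_bounds),
            resp_values=self.responses.values,
            subject_ids=np.array(self.responses.subject_ids, dtype=str),
            resp_rate=self.responses.rate,
            resp_t0=self.responses.t0,
            baseline_window=np.array(self.responses.baseline_window),
            meta_json=json.dumps(self.meta, default=str),
        )
        if self.clean_spectrum is not None:
            payload["clean_spectrum"] = self.clean_spectrum
        for spec in self.noise_classes:
            payload[f"noise_{spec.label}"] = np.concatenate(
                [spec.mean_spectrum, [spec.stationarity]])
        del seg
        if path.suffix in {".h5", ".hdf5"}:
            import h5py

            with h5py.File(path, "w") as f:
                for k, v in payload.items():
                    if isinstance(v, str):
                        f.attrs[k] = v
                        continue
                    v = np.asarray(v)
                    if v.dtype.kind == "U":
                        v = v.astype("S")
                    f.create_dataset(k, data=v)
        else:
            np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "Session":
        path = Path(path)
        if path.suffix in {".h5", ".hdf5"}:
            import h5py

            with h5py.File(path, "r") as f:
                data = {}
                for k in f.keys():
                    v = f[k][()]
                    if isinstance(v, np.ndarray) and v.dtype.kind == "S":
                        v = v.astype(str)
                    data[k] = v
                data["meta_json"] = f.attrs.get("meta_json", "{}")
        else:
            with np.load(path, allow_pickle=False) as npz:
                data = {k: npz[k] for k in npz.files}
        segs = [Segment(float(a), float(b), str(c if isinstance(c, str)
                                                else c.item() if np.ndim(c) == 0
                                                else c))
                for a, b, c in zip(data["seg_start"], data["seg_end"],
                                   np.asarray(data["seg_cond"], dtype=str))]
        schedule = NoiseSchedule(segs, list(map(float, data["block_bounds"])))
        stim = Spectrogram(data["stim_values"], rate=float(data["stim_rate"]),
                           t0=float(data["stim_t0"]))
        resp = ResponseMatrix(
            data["resp_values"],
            np.asarray(data["subject_ids"], dtype=str),
            rate=float(data["resp_rate"]),
            baseline_window=tuple(map(float, data["baseline_window"])),
            t0=float(data["resp_t0"]),
        )
        noise_classes = []
        for label in NOISE_CONDITIONS:
            key = f"noise_{label}"
            if key in data:
                v = np.asarray(data[key], dtype=float)
                noise_classes.append(
                    NoiseClassSpec(label, v[:-1], float(v[-1])))
        meta_raw = data.get("meta_json", "{}")
        if not isinstance(meta_raw, str):
            meta_raw = bytes(meta_raw).decode() if isinstance(
                meta_raw, (bytes, np.bytes_)) else str(meta_raw)
        clean = data.get("clean_spectrum")
        return cls(stim, schedule, resp, noise_classes,
                   None if clean is None else np.asarray(clean, dtype=float),
                   json.loads(meta_raw))


def asdict_config(obj) -> dict:
    """Serialize a (nested) dataclass config to plain JSON-able dict."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: asdict_config(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [asdict_config(v) for v in obj]
    return obj
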