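"""Synthetic switching-noise sessions with known adaptive ground truth.

The study design this module emulates: continuous speech-like foregrounds
mixed with background noise at 6 dB SNR, where the background switches every
3 or 6 s between three spectrally distinct noise classes (low-frequency
"bar", broadband nonstationary "city", high-frequency stationary "jet") and
a clean condition, across 18 one-minute blocks preceded by a 2-minute silent
lead-in used for response normalization. Responses are produced by known
adaptive encoders (static linear, contrast-gain-adaptive, noise-band
suppressing, or LN + short-term-plasticity) so every downstream analysis has
a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, fftconvolve, lfilter

from .session import (CONDITIONS, NOISE_CONDITIONS, DEFAULT_N_FREQ,
                      DEFAULT_RATE, NoiseClassSpec, NoiseSchedule,
                      ResponseMatrix, Segment, Session, Spectrogram,
                      normalize_to_baseline)

__all__ = [
    "make_noise_classes", "speech_spectrum", "generate_foreground",
    "generate_noise", "mix_at_snr", "build_session", "BuiltStimulus",
    "GroundTruthEncoder", "make_base_filter", "simulate_responses",
    "effective_filter_timecourse", "make_session",
]


# ---------------------------------------------------------------------------
# noise classes

def speech_spectrum(n_freq: int = DEFAULT_N_FREQ) -> np.ndarray:
    """Canonical long-term speech-like band spectrum (unit total power).

    Low/mid-band emphasis peaking around the first-formant region with a
    smooth roll-off toward high bands.
    """
    f = np.arange(n_freq)
    spec = np.exp(-0.5 * ((f - 4.0) / 4.0) ** 2) + 0.35 * np.exp(-f / 8.0)
    return spec / spec.sum()


def make_noise_classes(seed: int,
                       n_freq: int = DEFAULT_N_FREQ) -> list[NoiseClassSpec]:
    """Three background-noise classes spanning spectrum and stationarity.

    - ``bar``: low-frequency, strongly speech-overlapping, moderately
      nonstationary (babble-like).
    - ``city``: broadband, highly nonstationary.
    - ``jet``: high-frequency (>70% of power in the top third of bands),
      nearly stationary.

    Deterministic given ``seed`` (a small per-seed spectral jitter keeps
    classes from being bit-identical across studies).
    """
    rng = np.random.default_rng(seed)
    f = np.arange(n_freq)
    top = int(np.ceil(2 * n_freq / 3))

    bar = np.exp(-0.5 * ((f - 3.0) / 3.0) ** 2) + 0.1
    city = 1.0 + 0.4 * np.exp(-f / 10.0) + 0.25 * np.sin(f / 3.0) ** 2
    jet = 1.0 / (1.0 + np.exp(-(f - (top - 0.5)) / 1.2)) + 0.02

    specs = []
    for label, spec, stat in (("bar", bar, 0.45), ("city", city, 0.15),
                              ("jet", jet, 0.9)):
        jitter = np.exp(0.04 * rng.standard_normal(n_freq))
        specs.append(NoiseClassSpec(label, spec * jitter, stat))

    # construction guarantee: jet concentrates power in the top third
    jet_spec = specs[2].mean_spectrum
    assert jet_spec[top:].sum() > 0.7
    return specs


# ---------------------------------------------------------------------------
# spectrogram generation

def _lowpass_noise(rng, n, rate, cutoff_hz):
    """Zero-mean unit-sd noise lowpassed below cutoff_hz."""
    x = rng.standard_normal(n)
    b, a = butter(2, cutoff_hz / (rate / 2), btype="low")
    y = filtfilt(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _bandpass_noise(rng, n, rate, lo_hz, hi_hz):
    x = rng.standard_normal(n)
    b, a = butter(2, [lo_hz / (rate / 2), hi_hz / (rate / 2)], btype="band")
    y = filtfilt(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_foreground(duration: float, seed: int,
                        rate: float = DEFAULT_RATE,
                        n_freq: int = DEFAULT_N_FREQ) -> Spectrogram:
    """Speech-like foreground spectrogram.

    2-3 formant-like spectral peaks drifting slowly in frequency, an
    amplitude envelope with modulation energy concentrated in the syllabic
    2-8 Hz range, and interleaved short silent gaps (< 300 ms). Values are
    linear magnitudes with per-bin rms of order 1.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    f = np.arange(n_freq)

    # syllabic amplitude modulation, 2-8 Hz
    env = 1.0 + 0.7 * _bandpass_noise(rng, n, rate, 2.0, 8.0)
    env = np.clip(env, 0.0, None)

    # short silent gaps (stop closures / pauses), each < 300 ms
    n_gaps = rng.poisson(0.8 * duration)
    for _ in range(n_gaps):
        start = rng.integers(0, max(n - 1, 1))
        length = rng.integers(int(0.05 * rate), int(0.28 * rate))
        env[start:start + length] = 0.0

    # drifting formant-like peaks
    n_peaks = int(rng.integers(2, 4))
    centers0 = np.sort(rng.uniform(2.0, n_freq - 3.0, size=n_peaks))
    profile = np.zeros((n, n_freq))
    for i in range(n_peaks):
        drift = 2.5 * _lowpass_noise(rng, n, rate, 1.0)
        c = np.clip(centers0[i] + drift, 0.0, n_freq - 1.0)
        width = rng.uniform(1.2, 2.2)
        amp = rng.uniform(0.6, 1.0)
        profile += amp * np.exp(-0.5 * ((f[None, :] - c[:, None]) / width) ** 2)

    tilt = speech_spectrum(n_freq)
    tilt = tilt / tilt.max()
    values = env[:, None] * profile * (0.4 + 0.6 * tilt[None, :])

    rms = np.sqrt(np.mean(values ** 2))
    if rms > 0:
        values = values / rms
    return Spectrogram(values, rate=rate)


def generate_noise(spec: NoiseClassSpec, duration: float, seed: int,
                   rate: float = DEFAULT_RATE) -> Spectrogram:
    """Background-noise spectrogram for one class.

    The class mean spectrum is modulated in time with depth set by
    ``1 - stationarity`` (global envelope plus weaker per-band fluctuation).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    n_freq = len(spec.mean_spectrum)
    depth = 1.0 - spec.stationarity

    env = 1.0 + depth * _lowpass_noise(rng, n, rate, 6.0)
    env = np.clip(env, 0.05, None)
    band_mod = 1.0 + 0.5 * depth * np.stack(
        [_lowpass_noise(rng, n, rate, 3.0) for _ in range(n_freq)], axis=1)
    band_mod = np.clip(band_mod, 0.05, None)

    shape = spec.mean_spectrum / spec.mean_spectrum.max()
    values = env[:, None] * band_mod * shape[None, :]
    rms = np.sqrt(np.mean(values ** 2))
    if rms > 0:
        values = values / rms
    return Spectrogram(values, rate=rate)


def mix_at_snr(foreground: Spectrogram, background: Spectrogram,
               snr_db: float) -> Spectrogram:
    """Sum foreground and background after rescaling the background so the
    realized SNR (10*log10 of mean-squared-bin power ratio) equals snr_db.
    """
    if foreground.values.shape != background.values.shape:
        raise ValueError("foreground/background shapes must match")
    if foreground.rate != background.rate:
        raise ValueError("foreground/background rates must match")
    p_fore = np.mean(foreground.values ** 2)
    p_back = np.mean(background.values ** 2)
    if p_back <= 0:
        raise ValueError("background has zero power; cannot set SNR")
    scale = np.sqrt(p_fore / (p_back * 10.0 ** (snr_db / 10.0)))
    return Spectrogram(foreground.values + scale * background.values,
                       rate=foreground.rate, t0=foreground.t0)


# ---------------------------------------------------------------------------
# session assembly

def _draw_segment_lengths(rng, block_duration, lengths=(3.0, 6.0)):
    """Tile one block exactly with segments drawn from ``lengths``."""
    short, long = sorted(lengths)
    out, remaining = [], block_duration
    while remaining > 0:
        if remaining < long or (remaining - long) % short != 0:
            out.append(short)
            remaining -= short
        else:
            pick = long if rng.random() < 0.5 else short
            out.append(pick)
            remaining -= pick
    return out


def _draw_conditions(rng, durations):
    """Condition per segment: no immediate repeats, exposure balanced."""
    exposure = {c: 0.0 for c in CONDITIONS}
    prev = None
    out = []
    for d in durations:
        cands = [c for c in CONDITIONS if c != prev]
        exps = np.array([exposure[c] for c in cands])
        w = np.exp(-(exps - exps.min()) / 3.0)
        c = rng.choice(cands, p=w / w.sum())
        out.append(c)
        exposure[c] += d
        prev = c
    return out


@dataclass
class BuiltStimulus:
    """Output of :func:`build_session`: mixed stimulus plus provenance."""

    stimulus: Spectrogram
    schedule: NoiseSchedule
    foreground: Spectrogram          # clean foreground, same timeline
    noise_classes: list[NoiseClassSpec]
    clean_spectrum: np.ndarray       # time-averaged clean-foreground spectrum
    lead_in: float

    def __iter__(self):
        return iter((self.stimulus, self.schedule))


def build_session(n_blocks: int = 18, block_duration: float = 60.0,
                  segment_lengths: tuple[float, float] = (3.0, 6.0),
                  snr_db: float = 6.0, seed: int = 0,
                  lead_in: float = 120.0, rate: float = DEFAULT_RATE,
                  n_freq: int = DEFAULT_N_FREQ) -> BuiltStimulus:
    """Assemble a full switching-noise stimulus session.

    A silent ``lead_in`` (default 2 min, for baseline normalization) is
    followed by ``n_blocks`` blocks tiled by 3/6-s background segments over
    the four conditions; each noisy segment's background is rescaled so its
    realized within-segment SNR equals ``snr_db``.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2 (jackknifing needs blocks)")
    rng = np.random.default_rng(seed)
    task_dur = n_blocks * block_duration
    fore = generate_foreground(task_dur, seed=int(rng.integers(2 ** 31)),
                               rate=rate, n_freq=n_freq)
    noise_classes = make_noise_classes(int(rng.integers(2 ** 31)), n_freq)
    by_label = {s.label: s for s in noise_classes}

    durations: list[float] = []
    for _ in range(n_blocks):
        durations.extend(_draw_segment_lengths(rng, block_duration,
                                               segment_lengths))
    conditions = _draw_conditions(rng, durations)

    mixed = fore.values.copy()
    segments = []
    t = lead_in
    for d, cond in zip(durations, conditions):
        i0 = int(round((t - lead_in) * rate))
        i1 = int(round((t + d - lead_in) * rate))
        if cond != "clean":
            sub = int(rng.integers(2 ** 31))
            noise = generate_noise(by_label[cond], d, seed=sub, rate=rate)
            seg_fore = Spectrogram(fore.values[i0:i1], rate=rate)
            mixed[i0:i1] = mix_at_snr(seg_fore, noise, snr_db).values
        segments.append(Segment(t, t + d, cond))
        t += d

    n_lead = int(round(lead_in * rate))
    full = np.vstack([np.zeros((n_lead, n_freq)), mixed])
    fore_full = np.vstack([np.zeros((n_lead, n_freq)), fore.values])
    block_bounds = [lead_in + i * block_duration for i in range(n_blocks + 1)]
    schedule = NoiseSchedule(segments, block_bounds)
    clean_spectrum = fore.values.mean(axis=0)
    return BuiltStimulus(Spectrogram(full, rate=rate),
                         schedule,
                         Spectrogram(fore_full, rate=rate),
                         noise_classes, clean_spectrum, lead_in)


# ---------------------------------------------------------------------------
# ground-truth encoders

def make_base_filter(seed: int, n_freq: int = DEFAULT_N_FREQ,
                     n_lag: int = 65, rate: float = DEFAULT_RATE,
                     scale: float = 3.0) -> np.ndarray:
    """Gabor-like spectro-temporal filter (freq x lag), Frobenius norm
    ``scale``.

    An excitatory blob at a random best frequency and ~60-120 ms latency
    plus a weaker delayed inhibitory sidelobe — the shape typical of
    auditory-cortical STRFs. Lag 0 is the most recent sample.
    """
    rng = np.random.default_rng(seed)
    f = np.arange(n_freq)[:, None]
    lag = np.arange(n_lag)[None, :]
    bf = rng.uniform(4.0, n_freq - 5.0)
    lat = rng.uniform(0.06, 0.12) * rate
    fw = rng.uniform(1.5, 3.0)
    lw = rng.uniform(3.0, 6.0)
    exc = np.exp(-0.5 * ((f - bf) / fw) ** 2
                 - 0.5 * ((lag - lat) / lw) ** 2)
    inh_lat = lat + rng.uniform(6.0, 12.0)
    inh_bf = bf + rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 3.0)
    inh = -rng.uniform(0.4, 0.7) * np.exp(
        -0.5 * ((f - inh_bf) / (fw * 1.3)) ** 2
        - 0.5 * ((lag - inh_lat) / (lw * 1.3)) ** 2)
    w = exc + inh
    return scale * w / np.linalg.norm(w)


@dataclass
class GroundTruthEncoder:
    """Generative encoder mapping a spectrogram to one electrode response.

    kinds
    -----
    ``static_linear``
        r(t) = rectify(base_filter * x_window(t)).
    ``gain_adaptive``
        the same drive premultiplied by contrast gain
        g = k * (c + c0)^(-alpha) on the trailing 1-s window contrast c,
        relaxing with time constant ``tau_adapt``.
    ``noise_filtering``
        base filter augmented after each transition (exponential approach,
        ``tau_adapt``) by an inhibitory component matched to the incoming
        noise-class spectrum (depth ``suppression_depth``), optionally also
        attenuating the filter's excitatory bins at the noise bands
        (``exc_suppression_depth``).
    ``ln_stp``
        rectified linear drive through Tsodyks-Markram resource dynamics
        (release fraction ``stp_u``, recovery ``stp_tau_rec``) and a
        double-exponential (Gompertz) output nonlinearity.

    ``transient_amp`` adds a decaying onset transient after every background
    transition (time constant ``transient_tau``), emulating the transient
    deviation-and-return that the adaptation index quantifies.

    ``drive_offset_sd`` sets the operating point: a constant equal to this
    many standard deviations of the task-period drive is added before
    rectification, emulating ongoing baseline activity and keeping the
    rectifier mostly in its linear region.
    """

    kind: str
    base_filter: np.ndarray
    gain_k: float = 1.0
    gain_alpha: float = 0.5
    gain_c0: float = 0.1
    contrast_window: float = 1.0
    suppression_depth: float = 1.5
    exc_suppression_depth: float = 0.0
    tau_adapt: float = 0.3
    stp_u: float = 0.4
    stp_tau_rec: float = 0.15
    nonlin_base: float = 0.0
    nonlin_amplitude: float = 3.0
    nonlin_shift: float = 0.5
    nonlin_slope: float = 1.5
    output_noise_sd: float = 0.1
    drive_offset_sd: float = 1.5
    rectifier: str = "softplus"
    transient_amp: float = 0.0
    transient_tau: float = 0.25
    subject: str = "S1"

    def __post_init__(self) -> None:
        if self.kind not in {"static_linear", "gain_adaptive",
                             "noise_filtering", "ln_stp"}:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        self.base_filter = np.asarray(self.base_filter, dtype=float)
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be positive")

    @property
    def n_lag(self) -> int:
        return self.base_filter.shape[1]


def _rectify(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "softplus":
        return np.logaddexp(0.0, x)
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "linear":
        return x
    raise ValueError(f"unknown rectifier {kind!r}")


def _linear_drive(stim_values: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """drive[t] = sum_{f,l} filt[f,l] * S[t-l, f], zero-padded history."""
    n = stim_values.shape[0]
    out = np.zeros(n)
    for fband in range(filt.shape[0]):
        out += fftconvolve(stim_values[:, fband], filt[fband])[:n]
    return out


def _relax(target: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order relaxation toward a target time course."""
    a = dt / tau
    a = min(a, 1.0)
    return lfilter([a], [1.0, -(1.0 - a)], target, zi=None)


def local_contrast(stim: Spectrogram, window_s: float = 1.0) -> np.ndarray:
    """Trailing-window standard deviation over all time-frequency bins."""
    v = stim.values
    n, nf = v.shape
    w = int(round(window_s * stim.rate))
    c1 = np.cumsum(np.concatenate([[0.0], v.sum(axis=1)]))
    c2 = np.cumsum(np.concatenate([[0.0], (v ** 2).sum(axis=1)]))
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - w, 0)
    cnt = (idx - lo) * nf
    m1 = (c1[idx] - c1[lo]) / cnt
    m2 = (c2[idx] - c2[lo]) / cnt
    var = np.maximum(m2 - m1 ** 2, 0.0)
    return np.sqrt(var)


def _lag_profile(n_lag: int, tau_samples: float = 10.0) -> np.ndarray:
    prof = np.exp(-np.arange(n_lag) / tau_samples)
    return prof / prof.sum()


def _class_activations(schedule: NoiseSchedule, times: np.ndarray,
                       tau: float, dt: float) -> dict[str, np.ndarray]:
    """a_c(t): exponential approach to 1 while condition c is active."""
    labels = schedule.condition_labels(times)
    acts = {}
    for c in NOISE_CONDITIONS:
        acts[c] = _relax((labels == c).astype(float), tau, dt)
    return acts


def _transients(schedule: NoiseSchedule, times: np.ndarray,
                amp: float, tau: float) -> np.ndarray:
    out = np.zeros(len(times))
    if amp == 0.0:
        return out
    for t0, _, _ in schedule.transitions():
        rel = times - t0
        m = rel >= 0
        out[m] += amp * np.exp(-rel[m] / tau)
    return out


def _stp_resource(drive: np.ndarray, u: float, tau_rec: float,
                  dt: float) -> np.ndarray:
    """Tsodyks-Markram resource trace for a nonnegative drive."""
    if tau_rec <= 0:
        raise ValueError("tau_rec must be positive")
    x = np.empty(len(drive))
    cur = 1.0
    k = dt / tau_rec
    for i, d in enumerate(drive):
        cur = cur + k * (1.0 - cur) - u * cur * d * dt
        cur = min(max(cur, 0.0), 1.0)
        x[i] = cur
    return x


def _simulate_one(enc: GroundTruthEncoder, stim: Spectrogram,
                  schedule: NoiseSchedule, rng,
                  noise_specs: dict[str, np.ndarray]) -> np.ndarray:
    dt = 1.0 / stim.rate
    times = stim.times
    drive = _linear_drive(stim.values, enc.base_filter)
    task = times >= schedule.start
    drive = drive + enc.drive_offset_sd * drive[task].std()

    if enc.kind == "static_linear":
        r = _rectify(drive, enc.rectifier)
    elif enc.kind == "gain_adaptive":
        c = local_contrast(stim, enc.contrast_window)
        g_target = enc.gain_k * (c + enc.gain_c0) ** (-enc.gain_alpha)
        g = _relax(g_target, enc.tau_adapt, dt)
        r = g * _rectify(drive, enc.rectifier)
    elif enc.kind == "noise_filtering":
        acts = _class_activations(schedule, times, enc.tau_adapt, dt)
        comps = _suppression_components(enc, noise_specs)
        total = drive.copy()
        for c in NOISE_CONDITIONS:
            total -= acts[c] * _linear_drive(stim.values, comps[c])
        r = _rectify(total, enc.rectifier)
    elif enc.kind == "ln_stp":
        d = np.maximum(drive, 0.0)
        x = _stp_resource(d, enc.stp_u, enc.stp_tau_rec, dt)
        v = enc.stp_u * x * d
        r = enc.nonlin_base + enc.nonlin_amplitude * np.exp(
            -np.exp(-enc.nonlin_slope * (v - enc.nonlin_shift)))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(enc.kind)

    r = r + _transients(schedule, times, enc.transient_amp, enc.transient_tau)
    if enc.output_noise_sd > 0:
        r = r + enc.output_noise_sd * rng.standard_normal(len(r))
    return r


def _suppression_components(enc: GroundTruthEncoder,
                            noise_specs: dict[str, np.ndarray]
                            ) -> dict[str, np.ndarray]:
    """Per-class filter components a noise_filtering encoder develops.

    The spectrum weighting is centered across bands, so subtracting a
    component steers filter weight away from the noise bands and slightly
    toward the others instead of shifting the filter's net drive.

    - ``suppression_depth`` scales the inhibitory part: the
      above-average portion of the noise spectrum crossed with a decaying
      lag profile, restricted to cells where the base filter is not
      excitatory. Subtracting it creates new inhibition at the noise
      bands while leaving the excitatory region untouched.
    - ``exc_suppression_depth`` scales the mirrored excitatory part: new
      excitatory weight at the bands where the noise is weakest (the
      below-average portion of the noise spectrum), restricted to cells
      where the base filter is not inhibitory — the excitatory region
      steers away from the new noise by growing away from it.

    Both components are normalized to unit Frobenius norm before scaling,
    so the depths share the base filter's units (default base norm 3.0;
    depth 1.5 alters the filter by half its magnitude at steady state).
    """
    prof = _lag_profile(enc.n_lag)
    inh_cells = enc.base_filter < 0
    exc_cells = enc.base_filter > 0
    comps = {}
    for c, spec in noise_specs.items():
        sc = spec - spec.mean()
        inh = np.outer(np.maximum(sc, 0.0), prof)
        inh[exc_cells] = 0.0
        comp = enc.suppression_depth * inh / np.linalg.norm(inh)
        if enc.exc_suppression_depth:
            exc = np.outer(np.maximum(-sc, 0.0), prof)
            exc[inh_cells] = 0.0
            # subtracting a negative component adds excitatory weight
            comp = comp - (enc.exc_suppression_depth
                           * exc / np.linalg.norm(exc))
        comps[c] = comp
    return comps


def _unit_noise_specs(noise_classes: list[NoiseClassSpec] | None,
                      n_freq: int) -> dict[str, np.ndarray]:
    """Unit-L2 spectrum per noise-class label."""
    if noise_classes is None:
        noise_classes = make_noise_classes(0, n_freq)
    return {s.label: s.mean_spectrum / np.linalg.norm(s.mean_spectrum)
            for s in noise_classes}


def simulate_responses(stim: Spectrogram, schedule: NoiseSchedule,
                       encoders: list[GroundTruthEncoder], seed: int,
                       lead_in: float | None = None,
                       noise_classes: list[NoiseClassSpec] | None = None
                       ) -> ResponseMatrix:
    """Run every ground-truth encoder on the stimulus and z-score each
    electrode to the silent lead-in (baseline) interval.
    """
    if lead_in is None:
        lead_in = schedule.start - stim.t0
    specs = _unit_noise_specs(noise_classes, stim.n_freq)
    rng = np.random.default_rng(seed)
    rows = []
    for enc in encoders:
        sub = np.random.default_rng(rng.integers(2 ** 31))
        rows.append(_simulate_one(enc, stim, schedule, sub, specs))
    values = np.asarray(rows)
    resp = ResponseMatrix(values,
                          np.array([e.subject for e in encoders]),
                          rate=stim.rate,
                          baseline_window=(stim.t0, stim.t0 + lead_in),
                          t0=stim.t0)
    resp.values = normalize_to_baseline(resp.values, resp.baseline_slice())
    return resp


def effective_filter_timecourse(enc: GroundTruthEncoder, stim: Spectrogram,
                                schedule: NoiseSchedule,
                                sample_idx: np.ndarray,
                                noise_classes: list[NoiseClassSpec] | None
                                = None) -> np.ndarray:
    """Ground-truth time-varying filter of an adaptive encoder.

    Returns the generator's defining spectro-temporal filter at the
    requested sample indices (shape ``(len(sample_idx), n_freq, n_lag)``):
    the gain-scaled base filter for ``gain_adaptive``, the augmented filter
    for ``noise_filtering``, the constant base filter for ``static_linear``.
    This is the oracle against which dSTRF-based analyses are validated.
    """
    dt = 1.0 / stim.rate
    sample_idx = np.asarray(sample_idx)
    base = enc.base_filter
    if enc.kind == "static_linear":
        return np.broadcast_to(base, (len(sample_idx),) + base.shape).copy()
    if enc.kind == "gain_adaptive":
        c = local_contrast(stim, enc.contrast_window)
        g_target = enc.gain_k * (c + enc.gain_c0) ** (-enc.gain_alpha)
        g = _relax(g_target, enc.tau_adapt, dt)[sample_idx]
        return g[:, None, None] * base[None]
    if enc.kind == "noise_filtering":
        specs = _unit_noise_specs(noise_classes, stim.n_freq)
        acts = _class_activations(schedule, stim.times, enc.tau_adapt, dt)
        comps = _suppression_components(enc, specs)
        out = np.broadcast_to(base, (len(sample_idx),) + base.shape).copy()
        for c in NOISE_CONDITIONS:
            out -= acts[c][sample_idx, None, None] * comps[c][None]
        return out
    raise ValueError(f"no effective filter defined for kind {enc.kind!r}")


def oracle_adaptation_timecourses(enc: GroundTruthEncoder, stim: Spectrogram,
                                  schedule: NoiseSchedule,
                                  sample_idx: np.ndarray,
                                  noise_classes: list[NoiseClassSpec] | None
                                  = None) -> tuple[dict, dict]:
    """Gain and lag-averaged-profile time courses of the generator's own
    effective filter (region-resolved), shaped like the dSTRF-derived
    time courses so the same index machinery applies.

    Returns ``(gain_tc, profile_tc)`` mapping region -> session-long
    arrays (NaN off ``sample_idx``).
    """
    sample_idx = np.asarray(sample_idx)
    filters = effective_filter_timecourse(enc, stim, schedule, sample_idx,
                                          noise_classes=noise_classes)
    gain_tc, profile_tc = {}, {}
    for region in ("full", "excitatory", "inhibitory"):
        if region == "full":
            arr = filters
        elif region == "excitatory":
            arr = np.where(filters > 0, filters, 0.0)
        else:
            arr = np.where(filters < 0, filters, 0.0)
        g = np.full(stim.n_samples, np.nan)
        g[sample_idx] = arr.std(axis=(1, 2))
        p = np.full((stim.n_samples, stim.n_freq), np.nan)
        p[sample_idx] = arr.mean(axis=2)
        gain_tc[region] = g
        profile_tc[region] = p
    return gain_tc, profile_tc


# ---------------------------------------------------------------------------
# convenience: one call from config to full Session

def make_session(n_blocks: int = 18, block_duration: float = 60.0,
                 snr_db: float = 6.0, seed: int = 0,
                 encoders: list[GroundTruthEncoder] | None = None,
                 lead_in: float = 120.0,
                 n_electrodes: int = 10,
                 encoder_kind: str = "gain_adaptive",
                 output_noise_sd: float = 0.1,
                 n_subjects: int = 2, **encoder_kwargs) -> Session:
    """Build stimulus + schedule and simulate a population of encoders.

    If ``encoders`` is None, ``n_electrodes`` encoders of ``encoder_kind``
    are created with independent base filters and subjects assigned round
    robin over ``n_subjects``.
    """
    built = build_session(n_blocks=n_blocks, block_duration=block_duration,
                          snr_db=snr_db, seed=seed, lead_in=lead_in)
    rng = np.random.default_rng(seed + 1)
    if encoders is None:
        encoders = []
        for i in range(n_electrodes):
            filt = make_base_filter(int(rng.integers(2 ** 31)))
            encoders.append(GroundTruthEncoder(
                kind=encoder_kind, base_filter=filt,
                output_noise_sd=output_noise_sd,
                subject=f"S{i % n_subjects + 1}", **encoder_kwargs))
    resp = simulate_responses(built.stimulus, built.schedule, encoders,
                              seed=seed + 2, lead_in=lead_in,
                              noise_classes=built.noise_classes)
    meta = dict(seed=seed, n_blocks=n_blocks, block_duration=block_duration,
                snr_db=snr_db, encoder_kinds=[e.kind for e in encoders])
    return Session(built.stimulus, built.schedule, resp,
                   built.noise_classes, built.clean_spectrum, meta)
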