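"""Dynamic STRF (dSTRF) extraction from piecewise-linear CNN encoders.

For a ReLU network without hidden biases, the instantaneous equivalent
linear filter at input window x_t is the exact gradient of the output with
respect to the window: masking each weight matrix by its layer's activation
pattern and multiplying the masked matrices yields a single linear map, and
sum(dSTRF * x_t) + head_bias reproduces the network output exactly. The
gradient is computed here by reverse-mode accumulation through the
convolution stack, which is mathematically identical to materializing the
masked-weight products.

Robust per-timepoint dSTRFs are obtained by averaging the dSTRFs of the
jackknife member models and zeroing any lag-frequency bin whose sign is not
shared by at least ``min_agree`` members (15 of 17 at full scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _nn
from .cnn import CnnResults
from .session import Spectrogram

__all__ = ["DstrfFrame", "DstrfTensor", "compute_dstrf",
           "compute_dstrf_batch", "average_and_mask", "default_min_agree",
           "dstrf_timecourse", "dstrf_reduce", "adaptation_timecourses"]


@dataclass
class DstrfFrame:
    """One instantaneous filter: (n_freq, n_lag), lag 0 = most recent."""

    weights: np.ndarray
    t: float
    electrode: int


@dataclass
class DstrfTensor:
    """Masked jackknife-averaged dSTRF time course for one electrode."""

    frames: np.ndarray          # (n_times, n_freq, n_lag)
    sample_idx: np.ndarray      # stimulus sample index of each frame
    electrode: int
    mask_threshold: int
    n_members: int
    rate: float = 100.0

    @property
    def times(self) -> np.ndarray:
        return self.sample_idx / self.rate


def default_min_agree(n_members: int) -> int:
    """Sign-consistency threshold scaled from the 15-of-17 full-scale rule."""
    return math.ceil(n_members * 15 / 17)


def _windows(stim: Spectrogram, results: CnnResults,
             sample_idx: np.ndarray) -> np.ndarray:
    """Normalized input windows (B, n_freq, RF) ending at each sample."""
    rf = results.rf
    if (np.asarray(sample_idx) < rf - 1).any():
        raise ValueError("dSTRF undefined before one full receptive field")
    x = results.normalize_input(stim.values)
    win = sliding_window_view(x, rf, axis=0)       # (T-RF+1, F, RF)
    return np.ascontiguousarray(win[np.asarray(sample_idx) - (rf - 1)])


def compute_dstrf_batch(results: CnnResults, stim: Spectrogram,
                        sample_idx: np.ndarray, electrode: int,
                        chunk: int = 1024) -> np.ndarray:
    """Exact dSTRFs in raw stimulus units for a batch of time points.

    Returns (B, n_freq, n_lag) with lag 0 = most recent sample. The
    per-band input normalization is chain-ruled away, so
    sum(dSTRF * raw_window) + head_bias == prediction holds in raw units.
    """
    sample_idx = np.asarray(sample_idx)
    out = np.empty((len(sample_idx), stim.n_freq, results.rf))
    resp_scale = (1.0 if results.resp_sd is None
                  else float(results.resp_sd[electrode]))
    for c0 in range(0, len(sample_idx), chunk):
        sl = slice(c0, min(c0 + chunk, len(sample_idx)))
        xw = _windows(stim, results, sample_idx[sl])
        _, cache = _nn.forward_windows(results.params, xw)
        g = _nn.input_gradient_windows(results.params, cache, electrode)
        out[sl] = g * (resp_scale / results.band_scale[None, :, None])
    # model layout is (freq, window position); flip to lag convention
    return out[:, :, ::-1]


def compute_dstrf(results: CnnResults, stim: Spectrogram, t: int,
                  electrode: int) -> DstrfFrame:
    """dSTRF of one model at one output sample (index ``t``)."""
    w = compute_dstrf_batch(results, stim, np.array([t]), electrode)[0]
    return DstrfFrame(w, t / stim.rate, electrode)


def average_and_mask(member_frames: np.ndarray,
                     min_agree: int | None = None) -> np.ndarray:
    """Sign-consistency masked average over jackknife members.

    member_frames : (n_members, ...) stacked dSTRFs. Bins where fewer than
    ``min_agree`` members share a strict sign are set to exactly 0; zeros
    count toward neither sign. Elsewhere the plain member mean is returned.
    """
    member_frames = np.asarray(member_frames)
    if member_frames.shape[0] == 0:
        raise ValueError("empty member list")
    m = member_frames.shape[0]
    if min_agree is None:
        min_agree = default_min_agree(m)
    if min_agree > m:
        raise ValueError("min_agree cannot exceed the member count")
    pos = (member_frames > 0).sum(axis=0)
    neg = (member_frames < 0).sum(axis=0)
    keep = (pos >= min_agree) | (neg >= min_agree)
    return np.where(keep, member_frames.mean(axis=0), 0.0)


def dstrf_timecourse(members: list[CnnResults], stim: Spectrogram,
                     electrode: int, sample_idx: np.ndarray | None = None,
                     min_agree: int | None = None,
                     chunk: int = 512) -> DstrfTensor:
    """Masked member-averaged dSTRF at each requested time point.

    ``sample_idx`` defaults to every sample with a full receptive field.
    For long sessions prefer :func:`dstrf_reduce`, which avoids storing the
    full (time x freq x lag) tensor.
    """
    rf = members[0].rf
    if sample_idx is None:
        sample_idx = np.arange(rf - 1, stim.n_samples)
    sample_idx = np.asarray(sample_idx)
    if min_agree is None:
        min_agree = default_min_agree(len(members))
    frames = np.empty((len(sample_idx), stim.n_freq, rf))
    for c0 in range(0, len(sample_idx), chunk):
        sl = slice(c0, min(c0 + chunk, len(sample_idx)))
        stack = np.stack([compute_dstrf_batch(m, stim, sample_idx[sl],
                                              electrode, chunk=chunk)
                          for m in members])
        frames[sl] = average_and_mask(stack, min_agree)
    return DstrfTensor(frames, sample_idx, electrode, min_agree,
                       len(members), rate=stim.rate)


def dstrf_reduce(members: list[CnnResults], stim: Spectrogram,
                 electrode: int, reducers: dict,
                 sample_idx: np.ndarray | None = None,
                 min_agree: int | None = None,
                 chunk: int = 512) -> dict[str, np.ndarray]:
    """Stream masked dSTRF frames through per-frame reducer functions.

    Each reducer maps a masked frame (n_freq, n_lag) to a scalar or small
    vector; results are returned as full-session-length arrays (NaN where
    no frame was computed), keyed like ``reducers``. This keeps memory flat
    regardless of session length.
    """
    rf = members[0].rf
    if sample_idx is None:
        sample_idx = np.arange(rf - 1, stim.n_samples)
    sample_idx = np.asarray(sample_idx)
    if min_agree is None:
        min_agree = default_min_agree(len(members))

    probe = average_and_mask(
        np.stack([compute_dstrf_batch(m, stim, sample_idx[:1], electrode)
                  for m in members]), min_agree)[0]
    out = {}
    for name, fn in reducers.items():
        val = np.asarray(fn(probe), dtype=float)
        out[name] = np.full((stim.n_samples,) + val.shape, np.nan)

    for c0 in range(0, len(sample_idx), chunk):
        sl = slice(c0, min(c0 + chunk, len(sample_idx)))
        idx = sample_idx[sl]
        stack = np.stack([compute_dstrf_batch(m, stim, idx, electrode,
                                              chunk=chunk)
                          for m in members])
        masked = average_and_mask(stack, min_agree)
        for name, fn in reducers.items():
            for i, frame in enumerate(masked):
                out[name][idx[i]] = fn(frame)
    return out


def _member_gradients(members, stim, sample_idx, electrodes, chunk=1024):
    """Yield (chunk_indices, {electrode: member-stacked dSTRFs}).

    One forward pass per member per chunk is shared across all electrodes
    (the trunk is common; only the head backward differs).
    """
    sample_idx = np.asarray(sample_idx)
    for c0 in range(0, len(sample_idx), chunk):
        idx = sample_idx[c0: c0 + chunk]
        per_elec = {e: [] for e in electrodes}
        for m in members:
            xw = _windows(stim, m, idx)
            _, cache = _nn.forward_windows(m.params, xw)
            for e in electrodes:
                g = _nn.input_gradient_windows(m.params, cache, e)
                scale = (1.0 if m.resp_sd is None
                         else float(m.resp_sd[e]))
                per_elec[e].append(
                    (g * (scale / m.band_scale[None, :, None]))[:, :, ::-1])
        yield idx, {e: np.stack(v) for e, v in per_elec.items()}


def adaptation_timecourses(members: list[CnnResults], stim: Spectrogram,
                           electrodes, sample_idx: np.ndarray | None = None,
                           min_agree: int | None = None,
                           chunk: int = 1024) -> tuple[dict, dict]:
    """Session-long dSTRF gain and lag-averaged-profile time courses.

    Returns ``(gain_tc, profile_tc)`` nested as {electrode: {region:
    array}} for regions full/excitatory/inhibitory — the inputs the
    adaptation-index table builder consumes. Arrays are NaN at samples
    where no frame was computed.
    """
    rf = members[0].rf
    if sample_idx is None:
        sample_idx = np.arange(rf - 1, stim.n_samples)
    sample_idx = np.asarray(sample_idx)
    if min_agree is None:
        min_agree = default_min_agree(len(members))
    regions = ("full", "excitatory", "inhibitory")
    gain_tc = {e: {r: np.full(stim.n_samples, np.nan) for r in regions}
               for e in electrodes}
    profile_tc = {e: {r: np.full((stim.n_samples, stim.n_freq), np.nan)
                      for r in regions} for e in electrodes}
    for idx, grads in _member_gradients(members, stim, sample_idx,
                                        electrodes, chunk):
        for e in electrodes:
            masked = average_and_mask(grads[e], min_agree)
            exc = np.where(masked > 0, masked, 0.0)
            inh = np.where(masked < 0, masked, 0.0)
            for r, arr in (("full", masked), ("excitatory", exc),
                           ("inhibitory", inh)):
                gain_tc[e][r][idx] = arr.std(axis=(1, 2))
                profile_tc[e][r][idx] = arr.mean(axis=2)
    return gain_tc, profile_tc
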