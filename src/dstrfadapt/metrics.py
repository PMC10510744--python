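"""Adaptation metrics: contrast, dSTRF gain, noise-spectrum correlation,
transition alignment, and the gain-change / noise-filtering / adaptation
indices.

Index conventions
-----------------
- gain-change index: paired t between dSTRF gain 0.5-0 s before a
  transition and 0.65-1.15 s after it (the first half second following the
  adaptation period); positive = gain increased.
- noise-filtering index: the same paired t on the correlation between the
  lag-averaged dSTRF and the incoming noise spectrum, sign-flipped so
  positive = correlation decreased (the filter steered away from the new
  noise).
- adaptation index: paired t between the neural response 0-0.7 s and
  2-2.7 s after a transition; positive = a larger transient that returns
  to baseline.

All tests pair by within-window position on the transition-averaged time
course, giving a fixed number of pairs (50 for the gain/noise windows, 70
for the adaptation windows at 100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (NOISE_CONDITIONS, NoiseSchedule, ResponseMatrix,
                      Spectrogram)

__all__ = [
    "stimulus_contrast", "dstrf_gain", "lag_average",
    "noise_spectrum_correlation", "TransitionAlignedSeries",
    "align_to_transitions", "index_ttest", "gain_change_index",
    "noise_filtering_index", "adaptation_index", "build_index_table",
    "contrast_gain_coupling", "CLEAN_TO_NOISE", "NOISE_TO_CLEAN",
    "DEGENERATE_T_CAP",
]

DEGENERATE_T_CAP = 1e6

PRE_WINDOW = (-0.5, 0.0)
POST_WINDOW = (0.65, 1.15)
ADAPT_EARLY = (0.0, 0.7)
ADAPT_LATE = (2.0, 2.7)


# ---------------------------------------------------------------------------
# frame-level quantities

def stimulus_contrast(values: np.ndarray) -> float:
    """Spectro-temporal contrast in dB: 20*log10 of the standard deviation
    of all time-frequency bins, floored at -120 dB."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty segment")
    sd = float(values.std())
    if sd <= 10 ** (-120 / 20):
        return -120.0
    return 20.0 * np.log10(sd)


def _region_view(frame: np.ndarray, region: str) -> np.ndarray:
    if region == "full":
        return frame
    if region == "excitatory":
        return np.where(frame > 0, frame, 0.0)
    if region == "inhibitory":
        return np.where(frame < 0, frame, 0.0)
    raise ValueError(f"unknown region {region!r}")


def dstrf_gain(frame: np.ndarray, region: str = "full") -> float:
    """Gain of a lag-frequency filter: population sd over all bins after
    zeroing the opposite-sign bins for the excitatory/inhibitory regions
    (the zeros stay in the population)."""
    return float(_region_view(np.asarray(frame), region).std())


def lag_average(frame: np.ndarray, region: str = "full") -> np.ndarray:
    """Frequency profile: mean over lags of the (region-zeroed) filter."""
    return _region_view(np.asarray(frame), region).mean(axis=1)


def noise_spectrum_correlation(frame: np.ndarray, target_spectrum: np.ndarray,
                               region: str = "full") -> float:
    """Pearson r between the lag-averaged dSTRF frequency profile and a
    target spectrum. NaN (undefined) when the profile is constant, e.g. for
    a fully masked frame; such values are excluded downstream rather than
    treated as zero."""
    frame = np.asarray(frame)
    profile = lag_average(frame, region) if frame.ndim == 2 else frame
    target = np.asarray(target_spectrum)
    if len(profile) != len(target):
        raise ValueError("target spectrum length must equal n_freq")
    if profile.std() == 0 or target.std() == 0:
        return np.nan
    return float(np.corrcoef(profile, target)[0, 1])


# ---------------------------------------------------------------------------
# transition alignment

def CLEAN_TO_NOISE(from_cond: str, to_cond: str) -> bool:
    """Transitions from clean into any specific noise class."""
    return from_cond == "clean" and to_cond != "clean"


def NOISE_TO_CLEAN(from_cond: str, to_cond: str) -> bool:
    return to_cond == "clean"


@dataclass
class TransitionAlignedSeries:
    """Time courses aligned to background transitions (t = 0).

    values : (n_transitions, n_window[, ...]) — NaN where undefined.
    """

    values: np.ndarray
    rel_times: np.ndarray
    transitions: list[tuple[float, str, str]]
    window: tuple[float, float]
    empty: bool = False

    @property
    def n_transitions(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        """Transition-averaged time course (NaN-aware)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=0)


def align_to_transitions(timecourse: np.ndarray, times: np.ndarray,
                         schedule: NoiseSchedule, transition_filter=None,
                         pre_s: float = 0.5, post_s: float = 1.15,
                         rate: float = 100.0,
                         require_containment: bool = True
                         ) -> TransitionAlignedSeries:
    """Cut ``timecourse`` into windows [-pre_s, +post_s) around qualifying
    transitions.

    The transition sample (t = 0) belongs to the post segment. Windows are
    only kept when the pre part lies inside the preceding segment and the
    post part inside the new segment (no truncation by further
    transitions); set ``require_containment=False`` to keep them all.
    """
    timecourse = np.asarray(timecourse)
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    rel = np.arange(-n_pre, n_post)
    segs = schedule.segments
    keep, rows = [], []
    for i in range(1, len(segs)):
        prev, cur = segs[i - 1], segs[i]
        tf = transition_filter or (lambda a, b: True)
        if not tf(prev.condition, cur.condition):
            continue
        if require_containment:
            if cur.start - pre_s < prev.start - 1e-9:
                continue
            if cur.start + post_s > cur.end + 1e-9:
                continue
        i0 = int(round((cur.start - times[0]) * rate))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > len(timecourse):
            continue
        rows.append(timecourse[lo:hi])
        keep.append((cur.start, prev.condition, cur.condition))
    if not rows:
        shape = (0, len(rel)) + timecourse.shape[1:]
        return TransitionAlignedSeries(np.empty(shape), rel / rate, [],
                                       (pre_s, post_s), empty=True)
    return TransitionAlignedSeries(np.stack(rows), rel / rate, keep,
                                   (pre_s, post_s))


# ---------------------------------------------------------------------------
# indices

def _paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, str]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post windows must have equal length")
    ok = np.isfinite(pre) & np.isfinite(post)
    d = post[ok] - pre[ok]
    if len(d) < 3:
        return np.nan, "insufficient-coverage"
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, "ok"
        return float(np.sign(d.mean()) * DEGENERATE_T_CAP), "degenerate"
    return float(d.mean() / (sd / np.sqrt(len(d)))), "ok"


def index_ttest(pre_values: np.ndarray, post_values: np.ndarray) -> float:
    """Paired t over within-window positions; positive means post > pre.

    Zero-variance differences are capped at +-1e6 (degenerate flag is
    available via the richer index functions)."""
    return _paired_t(pre_values, post_values)[0]


def _window_slices(rel_times: np.ndarray, window: tuple[float, float]):
    return (rel_times >= window[0] - 1e-9) & (rel_times < window[1] - 1e-9)


def _windowed_index(avg: np.ndarray, rel_times: np.ndarray,
                    pre_win, post_win, min_coverage: float = 0.5
                    ) -> tuple[float, str]:
    pre = avg[_window_slices(rel_times, pre_win)]
    post = avg[_window_slices(rel_times, post_win)]
    if (np.isfinite(pre).mean() < min_coverage
            or np.isfinite(post).mean() < min_coverage):
        return np.nan, "insufficient-coverage"
    return _paired_t(pre, post)


def gain_change_index(aligned: TransitionAlignedSeries) -> float:
    """Paired t of transition-averaged gain, [post] - [pre]; positive =
    gain increased after the transition."""
    if aligned.empty:
        return np.nan
    t, _ = _windowed_index(aligned.mean(), aligned.rel_times,
                           PRE_WINDOW, POST_WINDOW)
    return t


def noise_filtering_index(aligned: TransitionAlignedSeries) -> float:
    """Sign-flipped paired t of the noise-spectrum correlation time course;
    positive = the dSTRF steered away from the new noise spectrum."""
    if aligned.empty:
        return np.nan
    t, _ = _windowed_index(aligned.mean(), aligned.rel_times,
                           PRE_WINDOW, POST_WINDOW)
    return -t if np.isfinite(t) else t


def adaptation_index(aligned: TransitionAlignedSeries) -> float:
    """Paired t between the transition-averaged response 0-0.7 s and
    2-2.7 s after the transition; positive = larger drop back to
    baseline."""
    if aligned.empty:
        return np.nan
    avg = aligned.mean()
    early = avg[_window_slices(aligned.rel_times, ADAPT_EARLY)]
    late = avg[_window_slices(aligned.rel_times, ADAPT_LATE)]
    t, _ = _paired_t(late, early)   # positive when early > late
    return t


# ---------------------------------------------------------------------------
# table assembly

def _to_condition_filter(condition: str):
    """Qualifying transitions for a condition's aligned analyses:
    clean -> noise-class for noise conditions, any-noise -> clean for the
    clean condition (noise-to-noise never qualifies)."""
    if condition == "clean":
        return NOISE_TO_CLEAN
    return lambda a, b: a == "clean" and b == condition


def build_index_table(schedule: NoiseSchedule, times: np.ndarray,
                      gain_tc: dict[str, dict[str, np.ndarray]],
                      profile_tc: dict[str, dict[str, np.ndarray]],
                      noise_spectra: dict[str, np.ndarray],
                      clean_spectrum: np.ndarray,
                      resp: ResponseMatrix | None = None,
                      subjects: dict | None = None,
                      rate: float = 100.0) -> pd.DataFrame:
    """Tidy per-electrode index table.

    gain_tc / profile_tc : nested {electrode: {region: array}} session-long
    time courses of dSTRF gain (scalars) and lag-averaged frequency
    profiles ((T, n_freq)), NaN where not computed.
    """
    regions = ("full", "excitatory", "inhibitory")
    conditions = list(NOISE_CONDITIONS) + ["clean"]
    rows = []
    for elec, per_region in gain_tc.items():
        subject = (subjects or {}).get(elec, "S1")
        for cond in conditions:
            tf = _to_condition_filter(cond)
            target = (clean_spectrum if cond == "clean"
                      else noise_spectra[cond])
            for region in regions:
                aligned_g = align_to_transitions(
                    per_region[region], times, schedule, tf, rate=rate)
                rows.append(dict(
                    electrode=elec, subject=subject, condition=cond,
                    region=region, index_kind="gain_change",
                    value=gain_change_index(aligned_g),
                    n_transitions=aligned_g.n_transitions))
                prof = profile_tc[elec][region]
                aligned_p = align_to_transitions(prof, times, schedule, tf,
                                                 rate=rate)
                corr = _profile_correlations(aligned_p, target)
                rows.append(dict(
                    electrode=elec, subject=subject, condition=cond,
                    region=region, index_kind="noise_filtering",
                    value=noise_filtering_index(corr),
                    n_transitions=corr.n_transitions))
            if resp is not None:
                e_idx = elec if isinstance(elec, int) else int(elec)
                aligned_r = align_to_transitions(
                    resp.values[e_idx], times, schedule,
                    lambda a, b, c=cond: b == c,
                    pre_s=0.0, post_s=ADAPT_LATE[1], rate=rate)
                rows.append(dict(
                    electrode=elec, subject=subject, condition=cond,
                    region="full", index_kind="adaptation",
                    value=adaptation_index(aligned_r),
                    n_transitions=aligned_r.n_transitions))
    return pd.DataFrame(rows)


def _profile_correlations(aligned: TransitionAlignedSeries,
                          target: np.ndarray) -> TransitionAlignedSeries:
    """Convert aligned (n_trans, n_win, n_freq) profiles into aligned
    correlation-with-target time courses."""
    if aligned.empty:
        return TransitionAlignedSeries(
            np.empty(aligned.values.shape[:2]), aligned.rel_times,
            aligned.transitions, aligned.window, empty=True)
    v = aligned.values
    out = np.full(v.shape[:2], np.nan)
    t = np.asarray(target, dtype=float)
    tc = t - t.mean()
    tn = np.sqrt((tc ** 2).sum())
    for i in range(v.shape[0]):
        p = v[i]
        ok = np.isfinite(p).all(axis=1)
        pc = p[ok] - p[ok].mean(axis=1, keepdims=True)
        pn = np.sqrt((pc ** 2).sum(axis=1))
        good = pn > 0
        r = np.full(ok.sum(), np.nan)
        r[good] = (pc[good] @ tc) / (pn[good] * tn)
        out[i, ok] = r
    return TransitionAlignedSeries(out, aligned.rel_times,
                                   aligned.transitions, aligned.window)


def pooled_clean_to_noise_indices(schedule: NoiseSchedule,
                                  times: np.ndarray,
                                  gain_tc: dict[str, np.ndarray],
                                  profile_tc: dict[str, np.ndarray],
                                  noise_spectra: dict[str, np.ndarray],
                                  region: str = "inhibitory",
                                  rate: float = 100.0
                                  ) -> tuple[float, float]:
    """Gain-change and noise-filtering indices pooled over *all*
    clean-to-noise transitions of one electrode.

    Each transition's correlation time course is computed against its own
    incoming noise-class spectrum; transitions are then averaged together
    regardless of class. Returns ``(gain_change, noise_filtering)``;
    ``gain_tc``/``profile_tc`` map region -> session-long arrays.
    """
    aligned_g = align_to_transitions(gain_tc[region], times, schedule,
                                     CLEAN_TO_NOISE, rate=rate)
    g_idx = gain_change_index(aligned_g)

    aligned_p = align_to_transitions(profile_tc[region], times, schedule,
                                     CLEAN_TO_NOISE, rate=rate)
    if aligned_p.empty:
        return g_idx, np.nan
    rows = np.full(aligned_p.values.shape[:2], np.nan)
    for i, (_, _, to) in enumerate(aligned_p.transitions):
        one = TransitionAlignedSeries(aligned_p.values[i: i + 1],
                                      aligned_p.rel_times,
                                      [aligned_p.transitions[i]],
                                      aligned_p.window)
        rows[i] = _profile_correlations(one, noise_spectra[to]).values[0]
    corr = TransitionAlignedSeries(rows, aligned_p.rel_times,
                                   aligned_p.transitions, aligned_p.window)
    return g_idx, noise_filtering_index(corr)


def mean_adaptation_index(resp: ResponseMatrix, schedule: NoiseSchedule,
                          rate: float = 100.0) -> np.ndarray:
    """Per-electrode adaptation index averaged over the 4 to-conditions."""
    conditions = list(NOISE_CONDITIONS) + ["clean"]
    times = resp.times
    out = np.empty(resp.n_electrodes)
    for e in range(resp.n_electrodes):
        vals = []
        for cond in conditions:
            aligned = align_to_transitions(
                resp.values[e], times, schedule,
                lambda a, b, c=cond: b == c,
                pre_s=0.0, post_s=ADAPT_LATE[1], rate=rate)
            vals.append(adaptation_index(aligned))
        out[e] = np.nanmean(vals)
    return out


# ---------------------------------------------------------------------------
# contrast / gain coupling across transitions

def contrast_gain_coupling(stim: Spectrogram, schedule: NoiseSchedule,
                           gain_tcs: dict[str, np.ndarray],
                           rate: float = 100.0) -> tuple[float, pd.DataFrame]:
    """Across-transition correlation between the change in stimulus
    contrast and the change in dSTRF gain.

    For every clean<->noise transition and electrode, the contrast change is
    contrast(new segment) - contrast(previous segment) and the gain change
    is mean gain in [0.65, 1.15) s minus mean gain in [-0.5, 0) s. Returns
    the Pearson r over all (transition, electrode) pairs and the pair table.
    """
    times = stim.times
    tf = lambda a, b: (a == "clean") != (b == "clean")
    segs = schedule.segments
    seg_contrast = {}
    for s in segs:
        sl = stim.slice_time(s.start, s.end)
        seg_contrast[(s.start, s.condition)] = stimulus_contrast(sl.values)

    rows = []
    for elec, tc in gain_tcs.items():
        aligned = align_to_transitions(tc, times, schedule, tf, rate=rate)
        for i, (t0, frm, to) in enumerate(aligned.transitions):
            prev = next(s for s in segs if abs(s.end - t0) < 1e-9)
            cur = next(s for s in segs if abs(s.start - t0) < 1e-9)
            dc = (seg_contrast[(cur.start, cur.condition)]
                  - seg_contrast[(prev.start, prev.condition)])
            pre = aligned.values[i][_window_slices(aligned.rel_times,
                                                   PRE_WINDOW)]
            post = aligned.values[i][_window_slices(aligned.rel_times,
                                                    POST_WINDOW)]
            if np.isfinite(pre).mean() < 0.5 or np.isfinite(post).mean() < 0.5:
                continue
            rows.append(dict(electrode=elec, t=t0, from_cond=frm,
                             to_cond=to, d_contrast=dc,
                             d_gain=np.nanmean(post) - np.nanmean(pre)))
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        return np.nan, pairs
    r = float(np.corrcoef(pairs.d_contrast, pairs.d_gain)[0, 1])
    return r, pairs
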