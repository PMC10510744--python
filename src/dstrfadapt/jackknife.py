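"""Cross-validated jackknife fitting and split-correlation evaluation.

For each held-out test block, ``n_blocks - 1`` member models are trained,
each additionally excluding one of the remaining blocks; the test-block
prediction is the arithmetic mean of the member predictions (17 members per
block when the session has 18 blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import CnnConfig, CnnEncoder, CnnHyper
from .session import NoiseSchedule, ResponseMatrix, Spectrogram
from .stp import StpEncoder
from .strf import StrfEncoder

__all__ = ["block_masks", "JackknifeEnsemble", "jackknife_fit",
           "predict_session", "evaluate_split_correlation"]


def block_masks(schedule: NoiseSchedule, times: np.ndarray) -> list[np.ndarray]:
    """Boolean sample mask per jackknife block."""
    return [(times >= a) & (times < b)
            for a, b in zip(schedule.block_bounds, schedule.block_bounds[1:])]


@dataclass
class JackknifeEnsemble:
    """Member models sharing one held-out test block."""

    test_block: int
    members: list
    member_excluded: list[int]
    test_mask: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.members)

    def predict(self, stim: Spectrogram) -> np.ndarray:
        """Mean of member predictions over the full session."""
        preds = [m.predict(stim) for m in self.members]
        return np.mean(preds, axis=0)


def _make_fitter(fitter, stim, resp, schedule, config, hyper, n_lag):
    if callable(fitter):
        return fitter
    if fitter == "strf":
        def fit_strf(train_mask, val_mask, seed):
            enc = StrfEncoder(stim, resp, n_lag=n_lag, schedule=schedule,
                              sample_mask=train_mask)
            return enc.fit()
        return fit_strf
    if fitter == "cnn":
        def fit_cnn(train_mask, val_mask, seed):
            enc = CnnEncoder(stim, resp,
                             config=config or CnnConfig(n_freq=stim.n_freq),
                             hyper=hyper or CnnHyper(),
                             train_mask=train_mask, val_mask=val_mask)
            return enc.fit(seed=seed)
        return fit_cnn
    if fitter == "stp":
        def fit_stp(train_mask, val_mask, seed):
            enc = StpEncoder(stim, resp, n_lag=n_lag, schedule=schedule,
                             sample_mask=train_mask)
            return enc.fit(seed=seed)
        return fit_stp
    raise ValueError(f"unknown fitter {fitter!r}")


def jackknife_fit(stim: Spectrogram, resp: ResponseMatrix,
                  schedule: NoiseSchedule, fitter="strf",
                  test_blocks=None, config: CnnConfig | None = None,
                  hyper: CnnHyper | None = None, n_lag: int = 65,
                  seed: int = 0, task_only: bool = True
                  ) -> list[JackknifeEnsemble]:
    """Leave-one-block-out jackknife over the schedule's blocks.

    For every test block ``b``, one member is trained per remaining block
    ``m`` on all blocks except ``{b, m}``; ``m`` serves as the member's
    validation block (used for CNN early stopping). Member seeds are
    distinct, derived from ``seed``.
    """
    masks = block_masks(schedule, stim.times)
    n_blocks = len(masks)
    if n_blocks < 3:
        raise ValueError("jackknife needs at least 3 blocks")
    if test_blocks is None:
        test_blocks = range(n_blocks)
    fit = _make_fitter(fitter, stim, resp, schedule, config, hyper, n_lag)

    ensembles = []
    for b in test_blocks:
        members, excluded = [], []
        for m in range(n_blocks):
            if m == b:
                continue
            train = np.zeros_like(masks[0])
            for j in range(n_blocks):
                if j not in (b, m):
                    train |= masks[j]
            member_seed = (seed * 1000003 + b * 1009 + m * 13) % (2 ** 31)
            members.append(fit(train, masks[m], member_seed))
            excluded.append(m)
        ensembles.append(JackknifeEnsemble(b, members, excluded, masks[b]))
    return ensembles


def predict_session(ensembles: list[JackknifeEnsemble],
                    stim: Spectrogram) -> np.ndarray:
    """Stitch test-block predictions so every sample is predicted exactly
    once by the ensemble holding it out."""
    out = None
    for ens in ensembles:
        pred = ens.predict(stim)
        if out is None:
            out = np.full_like(pred, np.nan)
        out[:, ens.test_mask] = pred[:, ens.test_mask]
    return out


# ---------------------------------------------------------------------------
# adaptation-window vs remainder correlation split

def transition_window_mask(schedule: NoiseSchedule, times: np.ndarray,
                           window_s: float = 0.65,
                           rate: float | None = None) -> np.ndarray:
    """Samples within ``window_s`` after any background transition
    (half-open [t_transition, t_transition + window_s))."""
    mask = np.zeros(len(times), dtype=bool)
    for t0, _, _ in schedule.transitions():
        mask |= (times >= t0 - 1e-9) & (times < t0 + window_s - 1e-9)
    return mask


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_split_correlation(pred: np.ndarray, actual: np.ndarray,
                               schedule: NoiseSchedule, times: np.ndarray,
                               adaptation_window: float = 0.65,
                               valid_mask: np.ndarray | None = None
                               ) -> pd.DataFrame:
    """Prediction accuracy over all samples, the post-transition adaptation
    window, and the remainder, overall and per background condition.

    Samples are assigned to the condition active at that sample (the
    transition sample belongs to the post-transition condition). The
    adaptation mask holds samples within ``adaptation_window`` seconds after
    any transition; the remainder is its complement within the task region.
    Returns a tidy frame (electrode, condition, full_r, adaptation_r,
    remainder_r).
    """
    pred = np.atleast_2d(pred)
    actual = np.atleast_2d(actual)
    task = (times >= schedule.start) & (times < schedule.end)
    ok = task & ~np.isnan(pred).any(axis=0) & ~np.isnan(actual).any(axis=0)
    if valid_mask is not None:
        ok &= np.asarray(valid_mask, dtype=bool)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 valid samples: correlation undefined")
    adapt = transition_window_mask(schedule, times, adaptation_window) & ok
    remain = ok & ~adapt
    labels = schedule.condition_labels(times)

    rows = []
    conditions = ["all"] + sorted({s.condition for s in schedule.segments})
    for e in range(pred.shape[0]):
        for cond in conditions:
            sel = ok if cond == "all" else (ok & (labels == cond))
            rows.append(dict(
                electrode=e, condition=cond,
                full_r=_pearson(pred[e, sel], actual[e, sel]),
                adaptation_r=_pearson(pred[e, sel & adapt],
                                      actual[e, sel & adapt]),
                remainder_r=_pearson(pred[e, sel & remain],
                                     actual[e, sel & remain]),
                n_full=int(sel.sum()),
                n_adaptation=int((sel & adapt).sum()),
                n_remainder=int((sel & remain).sum()),
            ))
    return pd.DataFrame(rows)
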