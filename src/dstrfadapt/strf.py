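"""Linear spectro-temporal receptive field (STRF) estimation.

Ridge regression on the lagged stimulus design matrix, with the
regularization strength chosen by leave-one-block-out cross-validated
prediction correlation. This is the regularized linear-Gaussian estimator
family that normalized reverse correlation with tolerance/sparseness sweeps
belongs to; the lambda grid plays the role of that sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .session import NoiseSchedule, ResponseMatrix, Spectrogram

__all__ = ["StrfEncoder", "StrfResults", "DEFAULT_LAMBDAS"]

DEFAULT_LAMBDAS = tuple(10.0 ** np.arange(0, 6))


def lagged_design(values: np.ndarray, n_lag: int) -> np.ndarray:
    """Design row at t: stimulus window [t-n_lag+1 .. t] flattened (F*L).

    Column ordering is (freq, lag) with lag 0 = most recent sample, matching
    the (n_freq, n_lag) filter layout. Valid rows start at t = n_lag - 1.
    """
    n, nf = values.shape
    if n < n_lag:
        raise ValueError("fewer samples than lags")
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(values, n_lag, axis=0)  # (n-L+1, F, L)
    return win[:, :, ::-1].reshape(n - n_lag + 1, nf * n_lag)


def condition_window_mask(schedule: NoiseSchedule, times: np.ndarray,
                          condition: str, n_lag: int) -> np.ndarray:
    """Samples whose full n_lag-sample history lies inside ``condition``."""
    labels = schedule.condition_labels(times)
    same = labels == condition
    csum = np.cumsum(np.concatenate([[0], same.astype(int)]))
    full = np.zeros(len(times), dtype=bool)
    t = np.arange(n_lag - 1, len(times))
    full[t] = (csum[t + 1] - csum[t + 1 - n_lag]) == n_lag
    return full


@dataclass
class _BlockStats:
    """Sufficient statistics of one sample group for ridge fitting."""

    g: np.ndarray      # X'X (uncentered)
    cxy: np.ndarray    # X'Y
    sx: np.ndarray     # sum of X rows
    sy: np.ndarray     # sum of Y rows
    n: int


def _combine(blocks: list[_BlockStats]):
    g = sum(b.g for b in blocks)
    cxy = sum(b.cxy for b in blocks)
    sx = sum(b.sx for b in blocks)
    sy = sum(b.sy for b in blocks)
    n = sum(b.n for b in blocks)
    # center both X and Y (intercept is unpenalized)
    gc = g - np.outer(sx, sx) / n
    cc = cxy - np.outer(sx, sy) / n
    return gc, cc, sx / n, sy / n, n


def _ridge_solve(gc, cc, lam):
    a = gc + lam * np.eye(gc.shape[0])
    return cho_solve(cho_factor(a, lower=True), cc)


class StrfEncoder:
    """Model object: per-electrode ridge STRFs on lagged spectrogram input.

    Parameters
    ----------
    stim, resp : aligned Spectrogram / ResponseMatrix at the same rate.
    n_lag : history length in samples (65 = 650 ms at 100 Hz).
    lambdas : ridge penalty grid for cross-validation.
    schedule : NoiseSchedule providing block bounds for CV folds. When
        absent, the sample range is split into ``n_folds`` equal folds.
    sample_mask : restrict fitting to these samples (e.g. training blocks).
    condition : fit only on samples whose entire lag window lies in this
        background condition (per-condition STRF).
    """

    def __init__(self, stim: Spectrogram, resp: ResponseMatrix,
                 n_lag: int = 65, lambdas=DEFAULT_LAMBDAS,
                 schedule: NoiseSchedule | None = None,
                 sample_mask: np.ndarray | None = None,
                 condition: str | None = None, n_folds: int = 5):
        if stim.n_samples != resp.n_samples:
            raise ValueError("stimulus and response lengths differ")
        if stim.n_samples < n_lag:
            raise ValueError("fewer samples than lags")
        self.stim = stim
        self.resp = resp
        self.n_lag = n_lag
        self.lambdas = np.asarray(list(lambdas), dtype=float)
        mask = np.ones(stim.n_samples, dtype=bool)
        if sample_mask is not None:
            mask &= np.asarray(sample_mask, dtype=bool)
        if condition is not None:
            if schedule is None:
                raise ValueError("condition mask requires a schedule")
            mask &= condition_window_mask(schedule, stim.times, condition,
                                          n_lag)
        mask[: n_lag - 1] = False
        self.sample_mask = mask
        self.folds = self._make_folds(schedule, n_folds)

    def _make_folds(self, schedule, n_folds):
        t = self.stim.times
        idx = np.flatnonzero(self.sample_mask)
        if len(idx) < self.n_lag:
            raise ValueError("too few usable samples")
        if schedule is not None and schedule.block_bounds:
            bounds = schedule.block_bounds
            folds = []
            for a, b in zip(bounds, bounds[1:]):
                f = idx[(t[idx] >= a) & (t[idx] < b)]
                if len(f):
                    folds.append(f)
            if len(folds) >= 2:
                return folds
        return [f for f in np.array_split(idx, n_folds) if len(f)]

    def _stats(self, idx: np.ndarray) -> _BlockStats:
        x = lagged_design(self.stim.values, self.n_lag)[idx - (self.n_lag - 1)]
        y = self.resp.values[:, idx].T
        return _BlockStats(x.T @ x, x.T @ y, x.sum(axis=0), y.sum(axis=0),
                           len(idx))

    def fit(self) -> "StrfResults":
        stats = [self._stats(f) for f in self.folds]
        n_elec = self.resp.n_electrodes
        n_lam = len(self.lambdas)

        cv_r = np.zeros((n_lam, n_elec))
        if len(stats) >= 2:
            for k in range(len(stats)):
                train = [s for j, s in enumerate(stats) if j != k]
                gc, cc, mx, my, _ = _combine(train)
                xk = lagged_design(self.stim.values, self.n_lag)[
                    self.folds[k] - (self.n_lag - 1)]
                yk = self.resp.values[:, self.folds[k]].T
                for li, lam in enumerate(self.lambdas):
                    w = _ridge_solve(gc, cc, lam)
                    pred = (xk - mx) @ w + my
                    cv_r[li] += _columnwise_r(pred, yk)
            cv_r /= len(stats)
            best = np.argmax(cv_r, axis=0)
        else:
            best = np.full(n_elec, n_lam // 2)

        gc, cc, mx, my, _ = _combine(stats)
        weights = np.empty((n_elec, self.stim.n_freq, self.n_lag))
        bias = np.empty(n_elec)
        for li in np.unique(best):
            w = _ridge_solve(gc, cc, self.lambdas[li])
            cols = np.flatnonzero(best == li)
            for e in cols:
                weights[e] = w[:, e].reshape(self.stim.n_freq, self.n_lag)
                bias[e] = my[e] - mx @ w[:, e]
        return StrfResults(weights, bias, self.lambdas[best], self.n_lag,
                           cv_table=cv_r, lambdas=self.lambdas)


def _columnwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac ** 2).sum(axis=0) * (bc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        return np.where(denom == 0, 0.0, (ac * bc).sum(axis=0) / denom)


@dataclass
class StrfResults:
    """Fitted STRFs: (n_electrodes, n_freq, n_lag) weights plus intercepts."""

    weights: np.ndarray
    bias: np.ndarray
    ridge_lambda: np.ndarray
    n_lag: int
    cv_table: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return self.weights.shape[0]

    def predict(self, stim: Spectrogram) -> np.ndarray:
        """Predictions over the full session (first n_lag-1 samples NaN)."""
        x = lagged_design(stim.values, self.n_lag)
        w = self.weights.reshape(self.n_electrodes, -1)
        out = np.full((self.n_electrodes, stim.n_samples), np.nan)
        out[:, self.n_lag - 1:] = w @ x.T + self.bias[:, None]
        return out

    def score(self, stim: Spectrogram, resp: ResponseMatrix,
              mask: np.ndarray | None = None) -> np.ndarray:
        pred = self.predict(stim)
        ok = ~np.isnan(pred[0])
        if mask is not None:
            ok &= np.asarray(mask, dtype=bool)
        return _columnwise_r(pred[:, ok].T, resp.values[:, ok].T)

    def summary(self) -> str:
        lines = [
            "Ridge STRF model",
            "=" * 32,
            f"electrodes: {self.n_electrodes}, lags: {self.n_lag}",
            "lambda per electrode: "
            + ", ".join(f"{v:g}" for v in np.atleast_1d(self.ridge_lambda)),
        ]
        if self.cv_table is not None and self.lambdas is not None:
            best = self.cv_table.max(axis=0)
            lines.append(
                f"mean CV correlation at chosen lambda: {best.mean():.3f}")
        return "\n".join(lines)
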