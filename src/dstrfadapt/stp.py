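"""Linear-nonlinear encoding model with short-term plasticity (LN + STP).

A 650-ms FIR filter drives Tsodyks-Markram synaptic resource dynamics
(two parameters: release fraction ``u`` and recovery time ``tau_rec``),
whose output passes through a double-exponential (Gompertz) static
nonlinearity  y = base + amplitude * exp(-exp(-slope * (v - shift))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .session import ResponseMatrix, Spectrogram
from .strf import StrfEncoder

__all__ = ["StpParams", "stp_forward", "stp_resource", "StpEncoder",
           "StpResults", "FittingFailedError"]


class FittingFailedError(RuntimeError):
    pass


@dataclass
class StpParams:
    """Parameters of one electrode's LN+STP cascade."""

    fir: np.ndarray            # (n_freq, n_lag)
    u: float = 0.4             # release fraction in (0, 1]
    tau_rec: float = 0.15      # recovery time constant, s
    base: float = 0.0
    amplitude: float = 1.0
    shift: float = 0.0
    slope: float = 1.0

    def __post_init__(self):
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must lie in [0, 1]")


def stp_resource(drive: np.ndarray, u: float, tau_rec: float,
                 dt: float) -> np.ndarray:
    """Discrete-time Tsodyks-Markram resource trace, x(0-) = 1.

    x <- x + dt*(1 - x)/tau_rec - u*x*drive*dt, clipped to [0, 1].
    For constant drive d the dt->0 steady state is
    (1/tau_rec) / (1/tau_rec + u*d).
    """
    if tau_rec <= 0:
        raise ValueError("tau_rec must be positive")
    out = np.empty(len(drive))
    x = 1.0
    k = dt / tau_rec
    for i in range(len(drive)):
        x = x + k * (1.0 - x) - u * x * drive[i] * dt
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        out[i] = x
    return out


def _gompertz(v, base, amplitude, shift, slope):
    return base + amplitude * np.exp(-np.exp(-slope * (v - shift)))


def _fir_drive(stim_values: np.ndarray, fir: np.ndarray) -> np.ndarray:
    from scipy.signal import fftconvolve

    n = stim_values.shape[0]
    out = np.zeros(n)
    for f in range(fir.shape[0]):
        out += fftconvolve(stim_values[:, f], fir[f])[:n]
    return out


def stp_forward(params: StpParams, stim: Spectrogram) -> np.ndarray:
    """Response trace of the LN+STP cascade on a stimulus."""
    dt = 1.0 / stim.rate
    drive = np.maximum(_fir_drive(stim.values, params.fir), 0.0)
    x = stp_resource(drive, params.u, params.tau_rec, dt)
    v = params.u * x * drive
    return _gompertz(v, params.base, params.amplitude, params.shift,
                     params.slope)


class StpEncoder:
    """Model object: per-electrode LN+STP fits.

    The FIR stage is initialized from a ridge STRF and held fixed (this
    anchors the drive scale, without which the release fraction ``u`` is not
    identifiable: scaling the drive by s and u by 1/s leaves both the
    depletion and the output invariant). The STP and nonlinearity
    parameters are then fitted by multi-start Nelder-Mead on MSE.
    """

    def __init__(self, stim: Spectrogram, resp: ResponseMatrix,
                 n_lag: int = 65, sample_mask: np.ndarray | None = None,
                 fir: np.ndarray | None = None, schedule=None):
        self.stim = stim
        self.resp = resp
        self.n_lag = n_lag
        n = stim.n_samples
        mask = np.ones(n, dtype=bool)
        if sample_mask is not None:
            mask &= np.asarray(sample_mask, dtype=bool)
        mask[: n_lag - 1] = False
        self.sample_mask = mask
        self.schedule = schedule
        self.fir = fir

    def _initial_firs(self) -> np.ndarray:
        if self.fir is not None:
            fir = np.asarray(self.fir, dtype=float)
            if fir.ndim == 2:
                fir = np.broadcast_to(
                    fir, (self.resp.n_electrodes,) + fir.shape)
            return fir
        res = StrfEncoder(self.stim, self.resp, n_lag=self.n_lag,
                          schedule=self.schedule,
                          sample_mask=self.sample_mask).fit()
        return res.weights

    def fit(self, seed: int = 0, n_restarts: int = 5,
            maxiter: int = 400, fix_u: float | None = None,
            no_depression: bool = False) -> "StpResults":
        """Fit per-electrode STP + nonlinearity parameters.

        ``fix_u`` freezes the release fraction; ``no_depression`` clamps
        the resource at 1 (u then acts as a pure input gain), giving the
        nested LN-only null model."""
        rng = np.random.default_rng(seed)
        firs = self._initial_firs()
        dt = 1.0 / self.stim.rate
        mask = self.sample_mask
        fits, losses = [], []
        for e in range(self.resp.n_electrodes):
            fir = firs[e]
            drive = np.maximum(_fir_drive(self.stim.values, fir), 0.0)
            y = self.resp.values[e]
            ym = y[mask]
            d_scale = max(drive[mask].std(), 1e-9)

            def objective(theta):
                u = (fix_u if fix_u is not None
                     else 1.0 / (1.0 + np.exp(-theta[0])))   # (0, 1)
                tau = np.exp(theta[1])
                base, amplitude = theta[2], np.exp(theta[3])
                shift, slope = theta[4], np.exp(theta[5])
                if no_depression:
                    v = u * drive
                else:
                    x = stp_resource(drive, u, tau, dt)
                    v = u * x * drive
                pred = _gompertz(v, base, amplitude, shift, slope)
                err = pred[mask] - ym
                val = float(np.mean(err ** 2))
                return val if np.isfinite(val) else 1e12

            # restart grid over (u, tau_rec); nonlinearity starts near the
            # response statistics with mild jitter
            u_grid = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
            best = None
            for ri in range(max(n_restarts, 5)):
                u0 = u_grid[ri % len(u_grid)]
                tau0 = [0.1, 0.3][ri // len(u_grid) % 2]
                theta0 = np.array([
                    np.log(u0 / (1 - u0)),
                    np.log(tau0),
                    float(ym.min()),
                    np.log(max(ym.max() - ym.min(), 1e-3)),
                    u0 * d_scale,
                    np.log(1.0 / d_scale),
                ])
                theta0[2:] += 0.05 * rng.standard_normal(4)
                res = minimize(objective, theta0, method="Nelder-Mead",
                               options=dict(maxiter=maxiter, xatol=1e-4,
                                            fatol=1e-7))
                if np.isfinite(res.fun) and (best is None
                                             or res.fun < best.fun):
                    best = res
            if best is None:
                raise FittingFailedError(
                    f"all STP restarts diverged for electrode {e}")
            th = best.x
            fits.append(StpParams(
                fir=fir,
                u=float(fix_u if fix_u is not None
                        else 1.0 / (1.0 + np.exp(-th[0]))),
                tau_rec=float(np.exp(th[1])),
                base=float(th[2]), amplitude=float(np.exp(th[3])),
                shift=float(th[4]), slope=float(np.exp(th[5]))))
            losses.append(float(best.fun))
        return StpResults(fits, self.stim.rate, self.n_lag,
                          np.array(losses))


@dataclass
class StpResults:
    """Fitted LN+STP models, one per electrode."""

    params: list[StpParams]
    rate: float
    n_lag: int
    final_loss: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_electrodes(self) -> int:
        return len(self.params)

    def predict(self, stim: Spectrogram) -> np.ndarray:
        return np.vstack([stp_forward(p, stim) for p in self.params])

    def score(self, stim: Spectrogram, resp: ResponseMatrix,
              mask: np.ndarray | None = None) -> np.ndarray:
        pred = self.predict(stim)
        ok = np.ones(stim.n_samples, dtype=bool)
        if mask is not None:
            ok &= np.asarray(mask, dtype=bool)
        out = np.empty(self.n_electrodes)
        for e in range(self.n_electrodes):
            a, b = pred[e, ok], resp.values[e, ok]
            out[e] = np.corrcoef(a, b)[0, 1]
        return out

    def summary(self) -> str:
        lines = ["LN + short-term-plasticity model", "=" * 32]
        for e, p in enumerate(self.params):
            lines.append(f"electrode {e}: u={p.u:.3f} "
                         f"tau_rec={p.tau_rec * 1e3:.0f} ms "
                         f"slope={p.slope:.2f}")
        return "\n".join(lines)
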