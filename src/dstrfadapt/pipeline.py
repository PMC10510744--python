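"""End-to-end orchestration of a synthetic adaptation experiment.

Stages: synth -> encode (STRF + CNN jackknife) -> dstrf -> metrics ->
popstats. Each stage writes its artifacts under the run directory and a
manifest records config hashes so completed stages are skipped on resume.
All randomness derives from the single config seed through named per-stage
substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dstrf as dstrf_mod
from . import metrics as metrics_mod
from . import popstats as popstats_mod
from .cnn import CnnConfig, CnnHyper
from .jackknife import (block_masks, evaluate_split_correlation,
                        jackknife_fit, predict_session)
from .session import Session, asdict_config
from .synthgen import make_session

__all__ = ["RunConfig", "full_scale", "demo_scale", "run_experiment",
           "validate_suite"]


@dataclass
class RunConfig:
    """Fully serializable description of one experiment run."""

    # synthgen
    n_blocks: int = 4
    block_duration: float = 30.0
    snr_db: float = 6.0
    n_electrodes: int = 10
    encoder_kind: str = "gain_adaptive"
    output_noise_sd: float = 0.3
    n_subjects: int = 2
    lead_in: float = 120.0
    # encoders
    n_kernels: int = 32
    n_layers: int = 5
    kernel_size: int = 5
    dilations: tuple[int, ...] = (1, 1, 2, 4, 8)
    lr: float = 1e-3
    weight_decay: float = 0.03
    lr_decay: float = 0.996
    epochs: int = 80
    patience: int = 15
    n_lag: int = 65
    # dstrf
    min_agree: int | None = None        # None -> ceil(members * 15/17)
    dstrf_stride: int = 1               # compute every k-th frame
    # misc
    seed: int = 0
    out_dir: str = "run"

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict_config(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def full_scale(**overrides) -> RunConfig:
    """Full study conditions: 18 one-minute blocks, 128 kernels,
    17-member jackknife ensembles."""
    cfg = RunConfig(n_blocks=18, block_duration=60.0, n_kernels=128,
                    epochs=200, patience=20)
    return _override(cfg, overrides)


def demo_scale(**overrides) -> RunConfig:
    """Reduced conditions for one-CPU runs: 4 x 30 s blocks, 32 kernels,
    3-member ensembles (sign mask threshold ceil(3*15/17) = 3)."""
    cfg = RunConfig()
    return _override(cfg, overrides)


def _override(cfg, overrides):
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg


def _manifest_path(out: Path) -> Path:
    return out / "manifest.json"


def _load_manifest(out: Path) -> dict:
    p = _manifest_path(out)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(out: Path, manifest: dict) -> None:
    _manifest_path(out).write_text(json.dumps(manifest, indent=2,
                                              default=str))


def _stage_done(manifest, out: Path, name: str, cfg_hash: str,
                outputs: list[str]) -> bool:
    st = manifest["stages"].get(name)
    return (st is not None and st.get("config_hash") == cfg_hash
            and all((out / o).exists() for o in outputs))


def run_experiment(config: RunConfig, verbose: bool = True) -> Path:
    """Run all stages, resuming past completed ones. Returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out)
    cfg_hash = config.hash()
    manifest["config"] = asdict_config(config)
    manifest["config_hash"] = cfg_hash

    def log(msg):
        if verbose:
            print(f"[pipeline] {msg}", flush=True)

    def finish(name, outputs, t0, extra=None):
        manifest["stages"][name] = dict(
            config_hash=cfg_hash, outputs=outputs,
            wall_s=round(time.time() - t0, 2), **(extra or {}))
        _save_manifest(out, manifest)

    # ---- synth -----------------------------------------------------------
    session_file = "session.npz"
    if not _stage_done(manifest, out, "synth", cfg_hash, [session_file]):
        t0 = time.time()
        log("synth: generating session")
        sess = make_session(
            n_blocks=config.n_blocks, block_duration=config.block_duration,
            snr_db=config.snr_db, seed=config.stage_seed("synth"),
            n_electrodes=config.n_electrodes,
            encoder_kind=config.encoder_kind,
            output_noise_sd=config.output_noise_sd,
            n_subjects=config.n_subjects, lead_in=config.lead_in)
        sess.save(out / session_file)
        sess.schedule.to_tsv(out / "schedule.tsv")
        finish("synth", [session_file, "schedule.tsv"], t0,
               dict(shape=list(sess.stimulus.values.shape)))
    sess = Session.load(out / session_file)
    stim, schedule, resp = sess.stimulus, sess.schedule, sess.responses
    task_mask = (stim.times >= schedule.start) & (stim.times < schedule.end)

    # ---- encode ----------------------------------------------------------
    models_dir = out / "models"
    pred_file = "predictions.npz"
    cnn_cfg = CnnConfig(n_layers=config.n_layers, n_kernels=config.n_kernels,
                        kernel_size=config.kernel_size,
                        dilations=tuple(config.dilations),
                        n_freq=stim.n_freq)
    hyper = CnnHyper(lr=config.lr, weight_decay=config.weight_decay,
                     lr_decay=config.lr_decay, epochs=config.epochs,
                     patience=config.patience)
    global _CNN_ENSEMBLES
    if not _stage_done(manifest, out, "encode", cfg_hash, [pred_file]):
        t0 = time.time()
        log("encode: jackknife STRF")
        strf_ens = jackknife_fit(stim, resp, schedule, fitter="strf",
                                 n_lag=config.n_lag,
                                 seed=config.stage_seed("strf"))
        strf_pred = predict_session(strf_ens, stim)
        log("encode: jackknife CNN")
        cnn_ens = jackknife_fit(stim, resp, schedule, fitter="cnn",
                                config=cnn_cfg, hyper=hyper,
                                seed=config.stage_seed("cnn"))
        cnn_pred = predict_session(cnn_ens, stim)
        models_dir.mkdir(exist_ok=True)
        np.savez_compressed(out / pred_file, strf=strf_pred, cnn=cnn_pred)
        table = []
        for name, pred in (("strf", strf_pred), ("cnn", cnn_pred)):
            df = evaluate_split_correlation(pred, resp.values, schedule,
                                            stim.times)
            df.insert(0, "model", name)
            table.append(df)
        pd.concat(table).to_csv(out / "correlations.csv", index=False)
        _CNN_ENSEMBLES[cfg_hash] = cnn_ens
        finish("encode", [pred_file, "correlations.csv"], t0)
    if cfg_hash not in _CNN_ENSEMBLES:
        log("encode: refitting CNN ensembles (model cache empty)")
        _CNN_ENSEMBLES[cfg_hash] = jackknife_fit(
            stim, resp, schedule, fitter="cnn", config=cnn_cfg, hyper=hyper,
            seed=config.stage_seed("cnn"))
    cnn_ens = _CNN_ENSEMBLES[cfg_hash]

    # ---- dstrf -----------------------------------------------------------
    tc_file = "dstrf_timecourses.npz"
    if not _stage_done(manifest, out, "dstrf", cfg_hash, [tc_file]):
        t0 = time.time()
        log("dstrf: extracting gain/profile time courses")
        rf = cnn_ens[0].members[0].rf
        sample_idx = np.flatnonzero(task_mask)
        sample_idx = sample_idx[sample_idx >= rf - 1]
        sample_idx = sample_idx[::config.dstrf_stride]
        payload = {}
        electrodes = list(range(resp.n_electrodes))
        for ens in cnn_ens:
            idx = sample_idx[ens.test_mask[sample_idx]]
            if not len(idx):
                continue
            g, p = dstrf_mod.adaptation_timecourses(
                ens.members, stim, electrodes, sample_idx=idx,
                min_agree=config.min_agree)
            for e in electrodes:
                for r in ("full", "excitatory", "inhibitory"):
                    payload.setdefault(f"gain_{r}_{e}", np.full(
                        stim.n_samples, np.nan))
                    payload.setdefault(f"profile_{r}_{e}", np.full(
                        (stim.n_samples, stim.n_freq), np.nan))
                    m = np.isfinite(g[e][r])
                    payload[f"gain_{r}_{e}"][m] = g[e][r][m]
                    m2 = np.isfinite(p[e][r]).all(axis=1)
                    payload[f"profile_{r}_{e}"][m2] = p[e][r][m2]
        np.savez_compressed(out / tc_file, **payload)
        finish("dstrf", [tc_file], t0)

    # ---- metrics ---------------------------------------------------------
    idx_file = "index_table.csv"
    if not _stage_done(manifest, out, "metrics", cfg_hash, [idx_file]):
        t0 = time.time()
        log("metrics: building index table")
        with np.load(out / tc_file) as npz:
            gain_tc = {e: {r: npz[f"gain_{r}_{e}"]
                           for r in ("full", "excitatory", "inhibitory")}
                       for e in range(resp.n_electrodes)}
            profile_tc = {e: {r: npz[f"profile_{r}_{e}"]
                              for r in ("full", "excitatory", "inhibitory")}
                          for e in range(resp.n_electrodes)}
        noise_spectra = {s.label: s.mean_spectrum for s in sess.noise_classes}
        table = metrics_mod.build_index_table(
            schedule, stim.times, gain_tc, profile_tc, noise_spectra,
            sess.clean_spectrum, resp=resp,
            subjects={e: str(resp.subject_ids[e])
                      for e in range(resp.n_electrodes)})
        table.to_csv(out / idx_file, index=False)
        r, pairs = metrics_mod.contrast_gain_coupling(
            stim, schedule, {e: gain_tc[e]["full"]
                             for e in range(resp.n_electrodes)})
        pairs.to_csv(out / "contrast_gain_pairs.csv", index=False)
        (out / "contrast_gain.json").write_text(
            json.dumps(dict(pearson_r=None if np.isnan(r) else r,
                            n_pairs=len(pairs))))
        finish("metrics", [idx_file], t0)

    # ---- popstats --------------------------------------------------------
    report_file = "report.json"
    if not _stage_done(manifest, out, "popstats", cfg_hash, [report_file]):
        t0 = time.time()
        log("popstats: population statistics")
        table = pd.read_csv(out / idx_file)
        corr = pd.read_csv(out / "correlations.csv")
        report = population_report(table, corr, resp.subject_ids)
        (out / report_file).write_text(json.dumps(report, indent=2,
                                                  default=float))
        finish("popstats", [report_file], t0)
    log("done")
    return out


# in-memory model cache (fitted ensembles are not serialized to disk in
# this reduced pipeline; reruns refit deterministically from the seed)
_CNN_ENSEMBLES: dict = {}


def population_report(index_table: pd.DataFrame, correlations: pd.DataFrame,
                      subject_ids) -> dict:
    """Population statistics from the tidy index and correlation tables."""
    report: dict = {}
    cnn = correlations[(correlations.model == "cnn")
                       & (correlations.condition == "all")]
    strf = correlations[(correlations.model == "strf")
                        & (correlations.condition == "all")]
    imp = (cnn.set_index("electrode").full_r
           - strf.set_index("electrode").full_r)
    report["median_improvement"] = float(np.median(imp.dropna()))
    try:
        t, p = popstats_mod.subject_controlled_ttest(
            imp.values, np.asarray(subject_ids)[imp.index])
        report["improvement_ttest"] = dict(t=t, p=p)
    except popstats_mod.InsufficientDataError as err:
        report["improvement_ttest"] = dict(error=str(err))

    # clustering on exc/inh noise-filtering indices over the 4 to-conditions
    nf = index_table[index_table.index_kind == "noise_filtering"]
    feats = nf.pivot_table(index="electrode", columns=["region", "condition"],
                           values="value")
    cols = [(r, c) for r in ("excitatory", "inhibitory")
            for c in ("bar", "city", "jet", "clean")]
    have = [c for c in cols if c in feats.columns]
    feats = feats[have].dropna()
    report["n_cluster_electrodes"] = int(len(feats))
    if len(feats) >= 4 and len(have) == 8:
        res = popstats_mod.cluster_noise_filtering(
            feats.values, electrode_index=feats.index.values,
            exc_to_noise_cols=(0, 1, 2))
        report["cluster_sizes"] = [int((res.groups == g).sum())
                                   for g in (1, 2)]
        adapt = index_table[index_table.index_kind == "adaptation"]
        mean_ai = adapt.groupby("electrode").value.mean()
        ai = mean_ai.reindex(feats.index).values
        try:
            cmp = popstats_mod.compare_groups(res.groups, ai)
            report["group_comparison"] = {
                k: v for k, v in cmp.items()
                if not isinstance(v, np.ndarray)}
        except popstats_mod.InsufficientDataError as err:
            report["group_comparison"] = dict(error=str(err))
    return report


# ---------------------------------------------------------------------------
# invariant validation

def validate_suite(seed: int = 0, verbose: bool = False) -> dict:
    """Reduced-scale execution of the package's core invariants.

    Returns a report mapping each invariant to its measured value and
    pass/fail flag; failures are entries, not exceptions.
    """
    from . import _nn
    from .cnn import CnnEncoder, receptive_field
    from .synthgen import (GroundTruthEncoder, build_session,
                           make_base_filter, simulate_responses)

    rng = np.random.default_rng(seed)
    report = {}

    def record(name, value, ok):
        report[name] = dict(value=value, passed=bool(ok))
        if verbose:
            print(f"  {name}: {value} ({'ok' if ok else 'FAIL'})")

    # receptive field arithmetic
    rf = receptive_field(CnnConfig())
    record("cnn_receptive_field", rf, rf == 65)

    # linearization identity on random nets
    cfg = CnnConfig(n_layers=3, n_kernels=8, dilations=(1, 2, 4), n_freq=6)
    worst = 0.0
    for _ in range(20):
        params = _nn.init_params(cfg.n_freq, cfg.n_kernels, cfg.kernel_size,
                                 cfg.n_layers, cfg.dilations, 2, rng)
        xw = np.abs(rng.standard_normal((10, cfg.n_freq,
                                         receptive_field(cfg))))
        y, cache = _nn.forward_windows(params, xw)
        for e in range(2):
            g = _nn.input_gradient_windows(params, cache, e)
            recon = (g * xw).sum(axis=(1, 2)) + params.head_bias[e]
            denom = np.maximum(np.abs(y[:, e]), 1e-3)
            worst = max(worst, float(np.max(np.abs(recon - y[:, e]) / denom)))
    record("linearization_identity_max_rel_err", worst, worst < 1e-4)

    # SNR conservation
    built = build_session(n_blocks=2, block_duration=12.0, seed=seed,
                          lead_in=6.0)
    worst_snr = 0.0
    for seg in built.schedule.segments:
        if seg.condition == "clean":
            continue
        f = built.foreground.slice_time(seg.start, seg.end).values
        m = built.stimulus.slice_time(seg.start, seg.end).values
        b = m - f
        snr = 10 * np.log10(np.mean(f ** 2) / np.mean(b ** 2))
        worst_snr = max(worst_snr, abs(snr - 6.0))
    record("snr_max_abs_err_db", worst_snr, worst_snr < 0.1)

    # static-linear generator vs single-loop convolution oracle
    filt = make_base_filter(seed)
    enc = GroundTruthEncoder("static_linear", filt, output_noise_sd=0.0)
    resp = simulate_responses(built.stimulus, built.schedule, [enc],
                              seed=seed, noise_classes=built.noise_classes)
    v = built.stimulus.values
    t_chk = np.array([700, 900, 1100])
    task = built.stimulus.times >= built.schedule.start
    full_drive = _raw_drive(v, filt)
    offset = enc.drive_offset_sd * full_drive[task].std()
    oracle = []
    for t in t_chk:
        acc = 0.0
        for lag in range(filt.shape[1]):
            if t - lag >= 0:
                acc += float(filt[:, lag] @ v[t - lag])
        oracle.append(np.logaddexp(0.0, acc + offset))
    oracle = np.array(oracle)
    base = resp.baseline_slice()
    raw = np.logaddexp(0.0, full_drive + offset)
    mu, sd = raw[base].mean(), raw[base].std()
    sd = sd if sd > 1e-12 else 1.0
    err = np.max(np.abs((oracle - mu) / sd - resp.values[0][t_chk]))
    record("static_linear_oracle_max_abs_err", float(err), err < 1e-9)
    return report


def _raw_drive(values, filt):
    from scipy.signal import fftconvolve

    out = np.zeros(values.shape[0])
    for f in range(filt.shape[0]):
        out += fftconvolve(values[:, f], filt[f])[:values.shape[0]]
    return out
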