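"""dSTRF linearization: exact gradient identity, masking, time courses."""

import numpy as np
import pytest

import dstrfadapt as da
from dstrfadapt import _nn
from dstrfadapt.cnn import CnnConfig, receptive_field
from dstrfadapt.dstrf import (average_and_mask, compute_dstrf_batch,
                              default_min_agree)


def _random_results(seed, n_freq=6, n_elec=3):
    from dstrfadapt.cnn import CnnHyper, CnnResults

    cfg = CnnConfig(n_layers=3, n_kernels=8, kernel_size=5,
                    dilations=(1, 2, 4), n_freq=n_freq)
    rng = np.random.default_rng(seed)
    params = _nn.init_params(cfg.n_freq, cfg.n_kernels, cfg.kernel_size,
                             cfg.n_layers, cfg.dilations, n_elec, rng)
    params.head_bias[:] = rng.standard_normal(n_elec)
    scale = 0.5 + rng.random(n_freq)
    return CnnResults(params, cfg, CnnHyper(), scale, np.zeros(1),
                      np.zeros(0), 0, n_elec)


class TestLinearityIdentity:
    def test_identity_on_many_random_models_and_inputs(self):
        """sum(dSTRF * x) + head bias reproduces the forward output to
        1e-4 relative, across random ReLU CNNs and inputs (raw units)."""
        worst = 0.0
        rng = np.random.default_rng(123)
        for seed in range(12):
            res = _random_results(seed)
            rf = res.rf
            n = rf + 30
            stim = da.Spectrogram(np.abs(rng.standard_normal((n, 6))))
            pred = res.predict(stim)
            idx = np.arange(rf - 1, n)
            for e in range(3):
                g = compute_dstrf_batch(res, stim, idx, e)
                # pair lag order (0 = most recent) with reversed windows
                from numpy.lib.stride_tricks import sliding_window_view

                win = sliding_window_view(stim.values, rf, axis=0)[
                    idx - (rf - 1)][:, :, ::-1]
                recon = (g * win).sum(axis=(1, 2)) + res.params.head_bias[e]
                denom = np.maximum(np.abs(pred[e, idx]), 1e-3)
                worst = max(worst, np.max(np.abs(recon - pred[e, idx])
                                          / denom))
        assert worst < 1e-4

    def test_linear_map_model_returns_its_weights(self):
        """A CNN whose ReLUs never switch off implements a pure linear map;
        the dSTRF equals that map for every input."""
        res = _random_results(99)
        # make all hidden activations positive: huge positive bias via
        # all-positive weights and positive input
        for w in res.params.conv_weights:
            np.abs(w, out=w)
        rng = np.random.default_rng(0)
        stim1 = da.Spectrogram(np.abs(rng.standard_normal((80, 6))) + 0.1)
        stim2 = da.Spectrogram(np.abs(rng.standard_normal((80, 6))) + 0.1)
        g1 = compute_dstrf_batch(res, stim1, np.array([70]), 0)[0]
        g2 = compute_dstrf_batch(res, stim2, np.array([75]), 0)[0]
        np.testing.assert_allclose(g1, g2, rtol=1e-10)

    def test_all_dead_input_gives_zero_dstrf(self):
        res = _random_results(7)
        # negate first-layer weights so a positive input kills layer 1
        res.params.conv_weights[0] *= 0.0
        res.params.conv_weights[0] -= 1.0
        stim = da.Spectrogram(np.ones((80, 6)))
        g = compute_dstrf_batch(res, stim, np.array([70]), 1)[0]
        assert np.all(g == 0)

    def test_frame_constant_under_pattern_preserving_perturbation(self):
        """Perturbations too small to flip any ReLU leave the dSTRF
        bit-identical (exact local linearity)."""
        res = _random_results(3)
        rng = np.random.default_rng(1)
        base = np.abs(rng.standard_normal((80, 6))) + 0.5
        stim = da.Spectrogram(base)
        g1 = compute_dstrf_batch(res, stim, np.array([70]), 0)[0]
        pert = base.copy()
        pert[40, 2] += 1e-9
        g2 = compute_dstrf_batch(res, da.Spectrogram(pert),
                                 np.array([70]), 0)[0]
        np.testing.assert_array_equal(g1, g2)


class TestMasking:
    def test_identical_members_pass_through(self):
        frames = np.tile(np.arange(6.0).reshape(2, 3) - 2, (17, 1, 1))
        out = average_and_mask(frames, min_agree=15)
        np.testing.assert_array_equal(out, frames[0])

    def test_fourteen_of_seventeen_masked(self):
        frames = np.ones((17, 1, 1))
        frames[14:] = -1.0   # 14 positive, 3 negative
        out = average_and_mask(frames, min_agree=15)
        assert out[0, 0] == 0.0

    def test_mean_includes_disagreeing_members(self):
        frames = np.ones((17, 1, 1))
        frames[16] = -1.0    # 16 positive, 1 negative
        out = average_and_mask(frames, min_agree=15)
        assert np.isclose(out[0, 0], 15.0 / 17.0)

    def test_zeros_count_toward_neither_sign(self):
        frames = np.ones((5, 1, 1))
        frames[2:] = 0.0     # 2 positive, 0 negative, 3 zero
        out = average_and_mask(frames, min_agree=3)
        assert out[0, 0] == 0.0

    def test_lower_threshold_never_masks_more(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((9, 4, 5))
        prev_zeros = None
        for min_agree in range(9, 0, -1):
            out = average_and_mask(frames, min_agree)
            zeros = int((out == 0).sum())
            if prev_zeros is not None:
                assert zeros <= prev_zeros
            prev_zeros = zeros

    def test_masking_is_idempotent(self):
        rng = np.random.default_rng(4)
        frames = rng.standard_normal((7, 3, 4))
        once = average_and_mask(frames, 6)
        again = average_and_mask(once[None], 1)
        np.testing.assert_array_equal(once, again)

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            average_and_mask(np.empty((0, 2, 2)))

    def test_threshold_scaling(self):
        assert default_min_agree(17) == 15
        assert default_min_agree(3) == 3
        assert default_min_agree(2) == 2


class TestTimecourse:
    def test_tensor_bookkeeping_and_near_constant_on_linear_truth(
            self, linear_session):
        """On static-linear ground truth the trained CNN's masked dSTRF is
        nearly the same filter at every time point."""
        from dstrfadapt.cnn import CnnEncoder, CnnHyper
        from dstrfadapt.jackknife import block_masks
        from dstrfadapt.dstrf import dstrf_timecourse

        sess = linear_session
        masks = block_masks(sess.schedule, sess.stimulus.times)
        full = masks[0] | masks[1] | masks[2] | masks[3] | masks[4]
        members = []
        for k, m in enumerate((2, 3, 4)):
            members.append(CnnEncoder(
                sess.stimulus, sess.responses,
                config=CnnConfig(n_kernels=16),
                hyper=CnnHyper(epochs=120, patience=25, lr=3e-3,
                               chunk_size=1500),
                train_mask=full & ~masks[m],
                val_mask=masks[m]).fit(seed=10 + k))
        idx = np.arange(8000, 9000, 2)
        tensor = dstrf_timecourse(members, sess.stimulus, electrode=0,
                                  sample_idx=idx)
        assert tensor.frames.shape == (500, 23, 65)
        assert tensor.n_members == 3
        assert tensor.mask_threshold == default_min_agree(3)
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(100):
            i, j = rng.integers(0, len(idx), size=2)
            a, b = tensor.frames[i].ravel(), tensor.frames[j].ravel()
            if a.std() > 0 and b.std() > 0 and i != j:
                rs.append(np.corrcoef(a, b)[0, 1])
        assert np.median(rs) > 0.9
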