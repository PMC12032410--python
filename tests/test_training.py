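"""Training objectives, schedule arithmetic, baselines, reproducibility."""

import math

import numpy as np
import pandas as pd
import pytest

from leadrecon.leads import LeadSet, MultiLeadSignal, INDEPENDENT_LEADS, one_lead_set
from leadrecon.models import Critic, DiscriminatorConfig, Generator, GeneratorConfig
from leadrecon.training import (TrainConfig, TrainingError, baseline_linear,
                                baseline_mean_predictor, cohort_tensors,
                                desk_train_config, train, train_unet,
                                validation_error, wgan_gp_losses)

TINY_GEN = GeneratorConfig(
    input_leads=1, output_leads=7, down_channels=(3, 4, 4, 5, 5, 6),
    up_channels=(6, 5, 5, 4, 4, 3), kernel_size=5, dropout_p=0.25)
TINY_DISC = DiscriminatorConfig(channels=(4, 4, 5, 5, 6, 6, 6), kernel_size=5,
                                patch_samples=160)


class LinearCritic:
    """Critic(x) = <w, x>; closed-form score and input gradient."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def score(self, x):
        return np.einsum("bcp,cp->b", np.asarray(x, dtype=float), self.w)

    def input_gradient(self, x):
        return np.broadcast_to(self.w, np.asarray(x).shape).copy()


class TestWganGpLosses:
    def test_unit_gradient_linear_critic_has_zero_penalty(self, rng):
        w = rng.standard_normal((8, 50))
        w /= np.linalg.norm(w)
        critic = LinearCritic(w)
        real = rng.standard_normal((4, 8, 50))
        fake = rng.standard_normal((4, 8, 50))
        loss_d, _ = wgan_gp_losses(critic, real, fake, 10.0, 0.0, real, fake,
                                   np.random.default_rng(0))
        expected = critic.score(fake).mean() - critic.score(real).mean()
        assert loss_d == pytest.approx(expected, abs=1e-10)

    def test_identical_signals_zero_l1_term(self, rng):
        critic = LinearCritic(rng.standard_normal((8, 50)))
        sig = rng.standard_normal((3, 7, 200))
        patch = rng.standard_normal((3, 8, 50))
        _, loss_g = wgan_gp_losses(critic, patch, patch, 0.0, 100.0, sig, sig,
                                   np.random.default_rng(1))
        assert loss_g == pytest.approx(-critic.score(patch).mean(), abs=1e-10)

    def test_matches_straight_line_formula_for_linear_critic(self, rng):
        """Dual-implementation oracle: every term recomputed from the
        definition for a critic whose gradient is known exactly."""
        w = rng.standard_normal((8, 40)) * 0.7
        critic = LinearCritic(w)
        real = rng.standard_normal((5, 8, 40))
        fake = rng.standard_normal((5, 8, 40))
        rs = rng.standard_normal((5, 7, 120))
        fs = rng.standard_normal((5, 7, 120))
        lam_gp, lam_l1 = 7.5, 42.0
        loss_d, loss_g = wgan_gp_losses(critic, real, fake, lam_gp, lam_l1,
                                        rs, fs, np.random.default_rng(2))
        # straight-line recomputation
        sr = np.array([(w * real[i]).sum() for i in range(5)])
        sf = np.array([(w * fake[i]).sum() for i in range(5)])
        pen = (np.linalg.norm(w) - 1.0) ** 2     # gradient is w everywhere
        want_d = sf.mean() - sr.mean() + lam_gp * pen
        want_g = -sf.mean() + lam_l1 * np.abs(rs - fs).mean()
        assert loss_d == pytest.approx(want_d, rel=1e-12)
        assert loss_g == pytest.approx(want_g, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        critic = LinearCritic(rng.standard_normal((8, 50)))
        with pytest.raises(TrainingError):
            wgan_gp_losses(critic, np.zeros((2, 8, 50)), np.zeros((2, 8, 49)),
                           1.0, 1.0, np.zeros((2, 7, 50)), np.zeros((2, 7, 50)),
                           np.random.default_rng(0))

    def test_network_critic_input_gradient_matches_finite_differences(self, rng):
        crit = Critic(TINY_DISC, seed=3)
        x = rng.standard_normal((2, 8, 160)).astype(np.float32) * 0.3
        g = crit.input_gradient(x)
        h = 3e-3
        for _ in range(6):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (crit.score(xp)[idx[0]] - crit.score(xm)[idx[0]]) / (2 * h)
            assert g[idx] == pytest.approx(fd, abs=5e-3, rel=5e-2)


class TestTrainLoop:
    @pytest.fixture()
    def splits(self, desk_cohort):
        return desk_cohort[:10], desk_cohort[10:14]

    def test_zero_epochs_returns_initialized_model(self, splits):
        gen = Generator(TINY_GEN, seed=0)
        init = [v.copy() for v in gen.state()]
        crit = Critic(TINY_DISC, seed=1)
        gen, hist = train(gen, crit, *splits, desk_train_config(epochs=0, seed=2))
        assert hist.empty
        for a, b in zip(init, gen.state()):
            assert np.array_equal(a, b)

    @pytest.mark.parametrize("epochs,batch_size", [(2, 4), (3, 3)])
    def test_update_schedule_arithmetic(self, splits, epochs, batch_size):
        """After E epochs of B batches: E*B critic updates, ceil(E*B/2)
        generator updates."""
        tr, va = splits
        gen = Generator(TINY_GEN, seed=0)
        crit = Critic(TINY_DISC, seed=1)
        cfg = desk_train_config(epochs=epochs, batch_size=batch_size, seed=2)
        _, hist = train(gen, crit, tr, va, cfg)
        batches = math.ceil(len(tr) / batch_size)
        assert hist.d_updates.iloc[-1] == epochs * batches
        assert hist.g_updates.iloc[-1] == math.ceil(epochs * batches / 2)

    def test_fixed_seed_gives_identical_histories(self, splits):
        runs = []
        for _ in range(2):
            gen = Generator(TINY_GEN, seed=5)
            crit = Critic(TINY_DISC, seed=6)
            runs.append(train(gen, crit, *splits,
                              desk_train_config(epochs=2, batch_size=4, seed=7))[1])
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_gan_training_reduces_validation_error(self, desk_cohort):
        tr, va = desk_cohort[:32], desk_cohort[32:40]
        gen = Generator(TINY_GEN, seed=0)
        init_val = validation_error(gen, va)
        crit = Critic(TINY_DISC, seed=1)
        gen, hist = train(gen, crit, tr, va,
                          desk_train_config(epochs=4, batch_size=16, seed=2))
        assert hist.val_l1_uv.iloc[-1] < init_val
        assert hist.val_l1_uv.min() == pytest.approx(
            validation_error(gen, va), rel=1e-6)  # best-epoch selection

    def test_empty_split_rejected(self, splits):
        with pytest.raises(TrainingError):
            train(Generator(TINY_GEN, seed=0), Critic(TINY_DISC, seed=1),
                  [], splits[1], desk_train_config(epochs=1))


class TestTrainUnet:
    def test_mse_loss_closed_form(self, desk_cohort):
        """validation_error(..., 'mse') equals mean((y - c)^2) for the
        constant mean predictor's output."""
        records = desk_cohort[:6]
        mean_pred = baseline_mean_predictor(records)
        _, y = cohort_tensors(records, amplitude_scale=1.0)
        c = mean_pred.mean_uv
        want = float(np.mean((y.astype(np.float64) - c[None]) ** 2))

        class ConstantGen:
            class config:
                amplitude_scale = 1.0

            def forward_norm(self, x, train=False):
                return np.broadcast_to(c, (x.shape[0],) + c.shape)

        got = validation_error(ConstantGen(), records, metric="mse")
        assert got == pytest.approx(want, rel=1e-6)

    def test_identical_prediction_zero_error(self, desk_cohort):
        rec = desk_cohort[0]

        class Oracle:
            class config:
                amplitude_scale = 6000.0

            def forward_norm(self, x, train=False):
                _, y = cohort_tensors([rec], amplitude_scale=6000.0)
                return y

        assert validation_error(Oracle(), [rec], metric="mse") == 0.0

    def test_unet_training_reduces_validation_mse(self, desk_cohort):
        tr, va = desk_cohort[:32], desk_cohort[32:40]
        gen = Generator(TINY_GEN, seed=3)
        init = validation_error(gen, va, metric="mse")
        gen, hist = train_unet(gen, tr, va,
                               desk_train_config(epochs=4, batch_size=16, seed=4))
        assert hist.val_mse_uv2.iloc[-1] < init


class TestBaselines:
    def test_mean_predictor_on_single_record_returns_it(self, desk_cohort):
        rec = desk_cohort[0]
        pred = baseline_mean_predictor([rec])
        out = pred.reconstruct(np.stack([rec.signal.lead("I")]))
        want = np.stack([rec.signal.lead(l) for l in one_lead_set().output_leads])
        assert np.allclose(out, want, atol=1e-9)

    def test_mean_predictor_is_constant_across_inputs(self, desk_cohort, rng):
        pred = baseline_mean_predictor(desk_cohort[:5])
        a = pred.reconstruct(rng.standard_normal((1, 2000)))
        b = pred.reconstruct(rng.standard_normal((1, 2000)) * 50)
        assert np.array_equal(a, b)

    def test_linear_baseline_recovers_exact_linear_map(self, rng):
        coefs = rng.standard_normal(7)
        icepts = rng.standard_normal(7) * 10
        records = []
        for _ in range(4):
            i_lead = rng.standard_normal(500) * 100
            rows = [i_lead, coefs[0] * i_lead + icepts[0]]
            rows += [coefs[k] * i_lead + icepts[k] for k in range(1, 7)]
            records.append(MultiLeadSignal(np.stack(rows), 500.0,
                                           INDEPENDENT_LEADS))
        pred = baseline_linear(records)
        assert np.allclose(pred.coef[:, 0], coefs, atol=1e-8)
        assert np.allclose(pred.intercept, icepts, atol=1e-8)
        out = pred.reconstruct(records[0].samples[:1])
        want = np.stack([records[0].samples[1]] + [records[0].samples[k]
                                                   for k in range(2, 8)])
        assert np.allclose(out, want, atol=1e-6)

    def test_linear_baseline_zero_inputs_predict_training_mean(self, rng):
        records = []
        for _ in range(3):
            rows = [np.zeros(300)] + [rng.standard_normal(300) * 40
                                      for _ in range(7)]
            records.append(MultiLeadSignal(np.stack(rows), 500.0,
                                           INDEPENDENT_LEADS))
        pred = baseline_linear(records)
        targets = np.stack([np.stack(r.samples[1:]) for r in records])
        out = pred.reconstruct(np.zeros((1, 300)))
        assert np.allclose(out, targets.mean(axis=(0, 2))[:, None], atol=1e-8)

    def test_linear_baseline_finds_einthoven_identity(self, desk_cohort):
        """With leads I and II as inputs and lead III as target, the
        instantaneous fit recovers III = II - I exactly."""
        lead_set = LeadSet(independent=("I", "II", "III"), derived=(),
                           input_mode=("I", "II"))
        pred = baseline_linear(desk_cohort[:10], lead_set)
        assert pred.coef[0] == pytest.approx([-1.0, 1.0], abs=1e-9)
        assert pred.intercept[0] == pytest.approx(0.0, abs=1e-7)
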