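"""Rate-RNN simulator, task battery trials, and training."""

import numpy as np
import pytest

from neurodim import cogtasks as ct


def _zero_params(cfg):
    n = cfg.n_rec
    return ct.RNNParams(
        W_in=np.zeros((n, cfg.n_in)), W_rec=np.zeros((n, n)),
        W_out=np.zeros((cfg.n_out, n)), b=np.zeros(n),
    )


class TestTuningCurve:
    def test_peak_at_preferred_direction(self):
        psi_i = np.pi / 16 * 5
        u = ct.tuning_curve(psi_i, gamma=1.0)
        assert u[5] == pytest.approx(0.8)
        assert np.argmax(u) == 5

    def test_offset_by_pi_over_eight(self):
        u = ct.tuning_curve(np.pi / 16 * 5 + np.pi / 8, gamma=1.0)
        assert u[5] == pytest.approx(0.8 * np.exp(-0.5), rel=1e-9)

    def test_symmetric_between_two_preferred_directions(self):
        psi = np.pi / 16 * 5.5  # midway between units 5 and 6
        u = ct.tuning_curve(psi, gamma=1.0)
        assert u[5] == pytest.approx(u[6], rel=1e-9)

    def test_linear_in_gamma(self):
        u1 = ct.tuning_curve(1.0, gamma=1.0)
        u3 = ct.tuning_curve(1.0, gamma=3.0)
        np.testing.assert_allclose(u3, 3 * u1)

    def test_wrapping_across_zero(self):
        # angular distance is taken on the circle, not on the real line
        u = ct.tuning_curve(2 * np.pi - 0.01, gamma=1.0)
        assert np.argmax(u) == 0


class TestMakeTrial:
    def test_unknown_task_raises(self):
        with pytest.raises(ValueError, match="unknown task"):
            ct.make_trial("jump", 0)

    @pytest.mark.parametrize("task", ct.TASKS)
    def test_all_tasks_well_formed(self, task, small_cfg):
        tr = ct.make_trial(task, 3, small_cfg)
        T = tr.inputs.shape[0]
        assert tr.inputs.shape == (T, small_cfg.n_in)
        assert tr.targets.shape == tr.loss_mask.shape == (T, small_cfg.n_out)
        assert set(np.unique(tr.inputs[:, 0])) <= {0.0, 1.0}
        assert np.all(tr.inputs[:, 1:] >= 0)
        assert np.all(tr.inputs[:, 1:] <= 2 * 0.8 * 1.4 + 1e-9)

    def test_fd_go_response_matches_stimulus(self, small_cfg):
        tr = ct.make_trial("fd_go", 5, small_cfg)
        assert tr.meta["psi_resp"] == pytest.approx(tr.meta["psi"])
        t_go = tr.meta["epochs"]["go"]
        assert np.all(tr.inputs[:t_go, 0] == 1.0)  # fixation until go
        assert np.all(tr.inputs[t_go:, 0] == 0.0)
        # response target is a bump toward the stimulus
        peak = np.argmax(tr.targets[-1, 1:])
        assert abs(peak - tr.meta["psi"] / (np.pi / 16)) % 32 <= 1

    def test_fd_anti_response_opposite(self, small_cfg):
        tr = ct.make_trial("fd_anti", 5, small_cfg)
        diff = (tr.meta["psi_resp"] - tr.meta["psi"]) % (2 * np.pi)
        assert diff == pytest.approx(np.pi)

    def test_rt_go_go_cue_at_stimulus_onset(self, small_cfg):
        tr = ct.make_trial("rt_go", 1, small_cfg)
        assert tr.meta["epochs"]["go"] == tr.meta["epochs"]["stim_on"]

    def test_dm_second_stimulus_at_least_ninety_degrees_away(self, small_cfg):
        for seed in range(10):
            tr = ct.make_trial("dm1", seed, small_cfg)
            diff = (tr.meta["psi2"] - tr.meta["psi"]) % (2 * np.pi)
            assert np.pi / 2 - 1e-9 <= diff <= 3 * np.pi / 2 + 1e-9
            stronger = tr.meta["psi"] if tr.meta["gammas"][0] >= tr.meta["gammas"][1] \
                else tr.meta["psi2"]
            assert tr.meta["psi_resp"] == pytest.approx(stronger)

    def test_dms_match_responds_nonmatch_fixates(self, small_cfg):
        seen = set()
        for seed in range(30):
            tr = ct.make_trial("dms", seed, small_cfg)
            if tr.meta["match"]:
                assert tr.meta["psi_resp"] == pytest.approx(tr.meta["psi2"])
                seen.add("match")
            else:
                assert tr.meta["psi_resp"] is None
                # fixation output target stays high after the go cue
                assert np.all(tr.targets[-1, 0] == 0.8)
                seen.add("nonmatch")
        assert seen == {"match", "nonmatch"}

    def test_dnms_inverts_the_rule(self, small_cfg):
        for seed in range(30):
            tr = ct.make_trial("dnms", seed, small_cfg)
            responds = tr.meta["psi_resp"] is not None
            assert responds == (not tr.meta["match"])

    def test_dmc_category_rule(self, small_cfg):
        for seed in range(30):
            tr = ct.make_trial("dmc", seed, small_cfg)
            same_cat = (tr.meta["psi"] >= np.pi) == (tr.meta["psi2"] >= np.pi)
            assert tr.meta["match"] == same_cat


class TestSimulate:
    def test_zero_weights_converge_to_log_two(self, small_cfg):
        params = _zero_params(small_cfg)
        tr = ct.make_trial("fd_go", 0, small_cfg)
        silent = ct.TaskTrial(inputs=np.zeros_like(tr.inputs), targets=tr.targets,
                              loss_mask=tr.loss_mask, meta=tr.meta)
        r, z = ct.simulate(params, silent, noise_on=False, cfg=small_cfg)
        np.testing.assert_allclose(r[-1], np.log(2), atol=1e-4)
        np.testing.assert_allclose(z[-1], 0.5)  # logistic(0)

    def test_noise_free_runs_bit_identical(self, small_cfg):
        params = ct.init_params(small_cfg, 1)
        tr = ct.make_trial("rt_go", 2, small_cfg)
        r1, _ = ct.simulate(params, tr, noise_on=False, cfg=small_cfg)
        r2, _ = ct.simulate(params, tr, noise_on=False, cfg=small_cfg)
        np.testing.assert_array_equal(r1, r2)

    def test_noisy_runs_reproducible_per_seed(self, small_cfg):
        params = ct.init_params(small_cfg, 1)
        tr = ct.make_trial("rt_go", 2, small_cfg)
        r1, _ = ct.simulate(params, tr, seed=5, noise_on=True, cfg=small_cfg)
        r2, _ = ct.simulate(params, tr, seed=5, noise_on=True, cfg=small_cfg)
        r3, _ = ct.simulate(params, tr, seed=6, noise_on=True, cfg=small_cfg)
        np.testing.assert_array_equal(r1, r2)
        assert not np.array_equal(r1, r3)

    def test_activities_nonnegative(self, small_cfg):
        params = ct.init_params(small_cfg, 3)
        tr = ct.make_trial("dm1", 1, small_cfg)
        r, _ = ct.simulate(params, tr, seed=0, noise_on=True, cfg=small_cfg)
        assert np.all(r >= 0)  # blend of softplus outputs from r0 = 0

    def test_recurrent_noise_scales_with_sigma(self):
        # around the zero-weight fixed point the injected noise passes
        # through an approximately linear gain, so the activity variance
        # scales ~ sigma_rec^2
        variances = []
        for sigma in (0.05, 0.10):
            cfg = ct.SimConfig(n_rec=32, sigma_rec=sigma, sigma_in=0.0)
            params = _zero_params(cfg)
            tr = ct.make_trial("fd_go", 0, cfg)
            silent = ct.TaskTrial(inputs=np.zeros_like(tr.inputs),
                                  targets=tr.targets, loss_mask=tr.loss_mask,
                                  meta=tr.meta)
            r, _ = ct.simulate(params, silent, seed=9, noise_on=True, cfg=cfg)
            variances.append(np.var(r[20:] - np.log(2)))
        assert variances[1] / variances[0] == pytest.approx(4.0, rel=0.35)


class TestTraining:
    def test_untrained_network_is_at_chance(self, small_cfg):
        params = ct.init_params(small_cfg, 0)
        acc = ct.accuracy(params, "rt_go", n_trials=40, seed=1, cfg=small_cfg)
        assert acc < 0.5

    def test_rt_go_trains_to_high_accuracy(self, small_cfg):
        res = ct.train("rt_go", seed=0, budget=400, cfg=small_cfg, batch_size=24)
        assert res.accuracy > 0.9
        assert res.loss_history[-1] < res.loss_history[0] / 2

    def test_collect_manifold_shapes(self, small_cfg):
        params = ct.init_params(small_cfg, 0)
        tr = ct.make_trial("rt_go", 0, small_cfg)
        cloud = ct.collect_manifold(params, "rt_go", n_trials=1, seed=0,
                                    cfg=small_cfg)
        assert cloud.shape == (tr.inputs.shape[0], small_cfg.n_rec)
        cloud3 = ct.collect_manifold(params, "rt_go", n_trials=3, seed=0,
                                     cfg=small_cfg)
        assert cloud3.shape[0] == 3 * tr.inputs.shape[0]
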