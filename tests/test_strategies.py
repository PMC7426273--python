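"""Training engines: importance bookkeeping, replay generation, contracts."""

import numpy as np
import pytest

from bireplay import (
    ContinualLearner,
    GenerativePrior,
    ImportanceState,
    StrategyConfig,
    VAE,
    ewc_penalty,
    fisher_diagonal,
    generate_replay,
    lwf_targets,
    replay_active_set,
    si_accumulate,
    si_consolidate,
    si_penalty,
    soft_targets,
)
from bireplay._autodiff import Tensor, concat
from bireplay.networks import Classifier
from bireplay.nn import Adam, Module, Parameter


class TestReplayActiveSet:
    def test_class_il_previous_classes(self, split_protocol):
        assert replay_active_set(split_protocol, 3) == (0, 1, 2, 3)

    def test_domain_il_all_classes(self, split_protocol):
        act = replay_active_set(split_protocol, 2, scenario="domain_il")
        assert act == tuple(range(6))

    def test_task_il_intended_context(self, split_protocol):
        act = replay_active_set(split_protocol, 3, intended_context=2,
                                scenario="task_il")
        assert act == (2, 3)

    def test_task_il_without_intended_raises(self, split_protocol):
        with pytest.raises(ValueError):
            replay_active_set(split_protocol, 3, scenario="task_il")


class TestSiBookkeeping:
    def test_unchanged_parameter_contributes_zero(self):
        state = ImportanceState()
        si_accumulate(state, "w", np.array([1.0]), np.array([1.0]), np.array([5.0]))
        assert state.omega["w"] == 0.0

    def test_pure_gradient_step_contribution_nonnegative(self, rng):
        state = ImportanceState()
        g = rng.standard_normal(10)
        theta = rng.standard_normal(10)
        eta = 0.1
        si_accumulate(state, "w", theta, theta - eta * g, g)
        assert np.allclose(state.omega["w"], eta * g**2)
        assert np.all(state.omega["w"] >= 0)

    def test_scripted_trajectory_matches_hand_sum(self):
        state = ImportanceState()
        steps = [(np.array([0.0]), np.array([0.5]), np.array([-2.0])),
                 (np.array([0.5]), np.array([0.3]), np.array([1.0]))]
        for before, after, g in steps:
            si_accumulate(state, "w", before, after, g)
        hand = (0.5 - 0.0) * 2.0 + (0.3 - 0.5) * (-1.0)
        assert np.isclose(state.omega["w"][0], hand)

    def test_consolidate_zero_omega_gives_zero_importance(self):
        p = Parameter(np.array([1.0]), name="w")
        state = ImportanceState(xi=0.1)
        state.begin_task([("w", p)])
        si_consolidate(state, [("w", p)])
        assert np.allclose(state.Omega["w"], 0.0)

    def test_consolidate_arithmetic_with_damping(self):
        p = Parameter(np.array([2.0]), name="w")
        state = ImportanceState(xi=0.1)
        state.begin_task([("w", p)])
        state.omega["w"] = np.array([0.05])
        # delta = 0 (parameter back at start) -> contribution 0.05 / 0.1
        assert np.isclose(p.data[0] - state.start["w"][0], 0.0)
        si_consolidate(state, [("w", p)])
        assert np.isclose(state.Omega["w"][0], 0.5)

    def test_two_tasks_sum(self):
        p = Parameter(np.array([0.0]), name="w")
        state = ImportanceState(xi=0.1)
        for omega, theta_end in [(0.2, 1.0), (0.3, 1.5)]:
            state.begin_task([("w", p)])
            start = p.data.copy()
            p.data = np.array([theta_end])
            state.omega["w"] = np.array([omega])
            si_consolidate(state, [("w", p)])
        hand = 0.2 / (1.0**2 + 0.1) + 0.3 / (0.5**2 + 0.1)
        assert np.isclose(state.Omega["w"][0], hand)


class TestPenalties:
    def _scripted_state(self):
        p = Parameter(np.array([1.0, -2.0]), name="w")
        state = ImportanceState(xi=0.1, gamma=1.0)
        state.anchors = {"w": p.data.copy()}
        state.Omega = {"w": np.array([0.5, 1.5])}
        fisher = {"w": np.array([0.5, 1.5])}
        state.fishers = [fisher]
        state.fisher_anchors = [{"w": p.data.copy()}]
        state.f_tilde = {"w": fisher["w"].copy()}
        state.n_consolidated = 1
        return p, state

    def test_zero_at_anchor_for_all_three(self):
        p, state = self._scripted_state()
        named = [("w", p)]
        assert si_penalty(named, state).item() == 0.0
        assert ewc_penalty(named, state, "ewc").item() == 0.0
        assert ewc_penalty(named, state, "online").item() == 0.0

    def test_online_is_twice_ewc_for_single_task_gamma_one(self):
        p, state = self._scripted_state()
        p.data = p.data + np.array([0.3, -0.4])
        named = [("w", p)]
        e = ewc_penalty(named, state, "ewc").item()
        o = ewc_penalty(named, state, "online").item()
        assert np.isclose(o, 2.0 * e)  # the 1/2 factor only in per-task EWC

    def test_quadratic_homogeneity(self):
        p, state = self._scripted_state()
        anchor = state.anchors["w"].copy()
        p.data = anchor + np.array([0.2, 0.1])
        named = [("w", p)]
        vals1 = [si_penalty(named, state).item(),
                 ewc_penalty(named, state, "ewc").item(),
                 ewc_penalty(named, state, "online").item()]
        p.data = anchor + np.array([0.4, 0.2])
        vals2 = [si_penalty(named, state).item(),
                 ewc_penalty(named, state, "ewc").item(),
                 ewc_penalty(named, state, "online").item()]
        assert np.allclose(vals2, [4 * v for v in vals1])

    def test_penalty_before_consolidation_raises(self):
        p = Parameter(np.zeros(2), name="w")
        with pytest.raises(RuntimeError):
            si_penalty([("w", p)], ImportanceState())

    def test_strong_regularization_pins_parameters(self, rng):
        """With huge lambda, training leaves parameters near their anchors."""
        p = Parameter(np.array([1.0, -1.0]), name="w")
        state = ImportanceState()
        state.anchors = {"w": p.data.copy()}
        state.Omega = {"w": np.array([1.0, 1.0])}
        state.n_consolidated = 1
        opt = Adam([p], lr=0.01)
        lam = 1e6
        for _ in range(200):
            # pull away from the anchor, opposed by the quadratic penalty
            loss = (p * Tensor(np.array([1.0, 1.0]))).sum() + si_penalty([("w", p)], state) * lam
            p.grad = None
            loss.backward()
            opt.step()
        assert np.allclose(p.data, state.anchors["w"], atol=0.02)


class _LogisticToy(Module):
    """One-parameter two-class model: logits = (w * x, 0)."""

    def __init__(self, w0=0.7):
        super().__init__()
        self.w = Parameter(np.array([w0]), name="w")

    def logits(self, x, masks=None, from_hidden=False):
        xt = Tensor(np.asarray(x, dtype=np.float64).reshape(len(x), 1))
        zero = Tensor(np.zeros((len(x), 1)))
        return concat([xt * self.w, zero], axis=1)


class TestFisher:
    def test_logistic_toy_matches_analytic_fisher(self):
        """F = mean of p(1-p) x^2 for the binary logistic model."""
        model = _LogisticToy(w0=0.7)
        x = np.array([[0.5], [-1.2], [2.0]])
        F = fisher_diagonal(model, x, {0, 1})["w"][0]
        p = 1.0 / (1.0 + np.exp(-0.7 * x[:, 0]))
        analytic = np.mean(p * (1 - p) * x[:, 0] ** 2)
        assert abs(F - analytic) < 1e-6

    def test_disconnected_parameter_has_zero_fisher(self):
        class TwoParam(_LogisticToy):
            def __init__(self):
                super().__init__()
                self.unused = Parameter(np.array([3.0]), name="unused")

        F = fisher_diagonal(TwoParam(), np.array([[1.0], [2.0]]), {0, 1})
        assert np.allclose(F["unused"], 0.0)

    def test_deterministic_given_frozen_model(self, rng):
        model = Classifier((1, 3, 3), [8], 3, rng=rng)
        x = rng.random((4, 1, 3, 3))
        F1 = fisher_diagonal(model, x, {0, 1, 2})
        F2 = fisher_diagonal(model, x, {0, 1, 2})
        for k in F1:
            assert np.array_equal(F1[k], F2[k])

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            fisher_diagonal(_LogisticToy(), np.zeros((0, 1)), {0, 1})


class TestGenerateReplay:
    def _frozen(self, protocol, rng, conditional=False):
        shape = protocol.image_shape
        gen = VAE(shape, [32, 32], latent_dim=8, rng=rng)
        main = Classifier(shape, [32], protocol.n_classes_total, rng=rng)
        for p in list(gen.parameters()) + list(main.parameters()):
            p.requires_grad = False
        prior = None
        if conditional:
            prior = GenerativePrior(protocol.n_classes_total, 8)
            prior.mark_seen(protocol.classes_seen(protocol.n_contexts))
        return gen, main, prior

    def test_task_il_labels_lie_in_intended_context(self, synthetic_pair, rng):
        from bireplay import build_split_protocol
        train, test = synthetic_pair
        protocol = build_split_protocol(train, test, 3, 2, scenario="task_il")
        gen, main, _ = self._frozen(protocol, rng)
        cfg = StrategyConfig(method="gr", scenario="task_il", distill=False)
        rb = generate_replay(gen, main, None, 200, protocol, 3, cfg, rng,
                             distill=False)
        for k in np.unique(rb.intended_contexts):
            sel = rb.intended_contexts == k
            allowed = set(protocol.contexts[k - 1].class_ids)
            assert set(rb.hard[sel].tolist()) <= allowed

    def test_conditional_class_frequencies(self, split_protocol, rng):
        gen, main, prior = self._frozen(split_protocol, rng, conditional=True)
        prior.seen = {0, 1, 2, 3}
        cfg = StrategyConfig(method="bir", scenario="class_il", distill=False)
        rb = generate_replay(gen, main, prior, 10_000, split_protocol, 3, cfg, rng,
                             distill=False)
        freqs = np.bincount(rb.intended_classes, minlength=6) / 10_000
        assert np.allclose(freqs[:4], 0.25, atol=0.02)
        assert np.all(freqs[4:] == 0.0)

    def test_target_type_contract(self, split_protocol, rng):
        gen, main, _ = self._frozen(split_protocol, rng)
        cfg = StrategyConfig(method="gr", scenario="class_il")
        rb_hard = generate_replay(gen, main, None, 32, split_protocol, 2, cfg, rng,
                                  distill=False)
        assert rb_hard.soft is None and rb_hard.hard.dtype == np.int64
        rb_soft = generate_replay(gen, main, None, 32, split_protocol, 2, cfg, rng,
                                  distill=True)
        assert rb_soft.soft is not None
        assert np.allclose(rb_soft.soft.probs.sum(axis=1), 1.0)

    def test_first_context_raises(self, split_protocol, rng):
        gen, main, _ = self._frozen(split_protocol, rng)
        cfg = StrategyConfig(method="gr")
        with pytest.raises(RuntimeError):
            generate_replay(gen, main, None, 8, split_protocol, 1, cfg, rng,
                            distill=False)


def test_lwf_targets_equal_soft_targets(split_protocol, rng):
    main = Classifier(split_protocol.image_shape, [16], 6, rng=rng)
    x = rng.random((5,) + split_protocol.image_shape)
    a = lwf_targets(main, x, (0, 1), T=2.0)
    b = soft_targets(main, x, (0, 1), T=2.0)
    assert np.array_equal(a.probs, b.probs)
    assert np.allclose(a.probs.sum(axis=1), 1.0)


class TestTrainSequence:
    def test_xdg_outside_task_il_rejected(self, split_protocol):
        with pytest.raises(ValueError):
            ContinualLearner(split_protocol, method="xdg", scenario="class_il")

    def test_unknown_method_rejected(self, split_protocol):
        with pytest.raises(ValueError):
            ContinualLearner(split_protocol, method="gr+bir")

    def test_replay_provenance_is_previous_snapshot(self, split_protocol):
        res = ContinualLearner(split_protocol, method="gr", hidden_layers=(24,),
                               latent_dim=8, iters=12, batch_size=16).fit(seed=0)
        df = res.loss_frame()
        replayed = df.dropna(subset=["replay_source"])
        assert len(replayed) > 0
        assert np.all(replayed["replay_source"] == replayed["context"] - 1)

    def test_bir_plus_si_logs_penalty_and_replay_terms(self, split_protocol):
        res = ContinualLearner(split_protocol, method="bir+si", hidden_layers=(24,),
                               latent_dim=8, iters=12, batch_size=16,
                               reg_strength=0.5).fit(seed=0)
        df = res.loss_frame()
        later = df[df.context == 3]
        assert later["loss_replay"].notna().all()
        assert later["penalty"].notna().all()

    def test_single_context_none_reduces_to_plain_training(self, synthetic_pair):
        from bireplay import build_split_protocol
        train, test = synthetic_pair
        proto = build_split_protocol(train, test, 1, 6)
        res = ContinualLearner(proto, method="none", hidden_layers=(32,),
                               iters=150, batch_size=32).fit(seed=0)
        assert res.final_average_accuracy > 0.95  # separable synthetic data

    def test_determinism_same_seed_identical_trace(self, split_protocol):
        mk = lambda: ContinualLearner(split_protocol, method="gr",
                                      hidden_layers=(24,), latent_dim=8,
                                      iters=10, batch_size=16)
        a = mk().fit(seed=5)
        b = mk().fit(seed=5)
        assert np.array_equal(
            np.nan_to_num(a.accuracy_matrix), np.nan_to_num(b.accuracy_matrix)
        )
        assert a.losses[-1]["loss_total"] == b.losses[-1]["loss_total"]

    def test_ewc_runs_and_penalizes(self, split_protocol):
        res = ContinualLearner(split_protocol, method="ewc", hidden_layers=(16,),
                               iters=10, batch_size=16, reg_strength=10.0,
                               fisher_subsample=10).fit(seed=0)
        df = res.loss_frame()
        assert (df[df.context > 1]["penalty"].fillna(0) >= 0).all()


class TestEndToEndVariants:
    def test_internal_replay_with_frozen_conv_stack(self, rng):
        """Brain-inspired replay at the hidden level: frozen conv features
        are the reconstruction targets and replay enters after the conv."""
        from bireplay import ConvStack, SyntheticConfig, build_split_protocol, generate_synthetic_set

        train, test = generate_synthetic_set(
            SyntheticConfig(n_classes=4, images_per_class_train=16,
                            images_per_class_test=8, image_size=8, seed=2)
        )
        proto = build_split_protocol(train, test, 2, 2, scenario="class_il")
        conv = ConvStack(in_channels=1, channels=(4, 8), strides=(1, 2), rng=rng)
        conv.freeze()
        before = {n: p.data.copy() for n, p in conv.named_parameters()}
        learner = ContinualLearner(proto, method="bir", conv_stack=conv,
                                   hidden_layers=(24,), latent_dim=8,
                                   iters=8, batch_size=8)
        res = learner.fit(seed=0)
        assert np.isfinite(res.final_average_accuracy)
        for n, p in conv.named_parameters():
            assert np.array_equal(p.data, before[n])
        rb = res.generate_replay_samples(n=6, seed=0)
        assert rb.level == "hidden"
        assert rb.inputs.shape[1] == conv.n_features(8)

    def test_permuted_domain_il_runs(self, rng):
        from bireplay import SyntheticConfig, build_permuted_protocol, generate_synthetic_set

        train, test = generate_synthetic_set(
            SyntheticConfig(n_classes=3, images_per_class_train=12,
                            images_per_class_test=6, image_size=6, seed=4)
        )
        proto = build_permuted_protocol(train, test, 3, pad_to=8, seed=1,
                                        scenario="domain_il")
        res = ContinualLearner(proto, method="gr", hidden_layers=(20,),
                               latent_dim=6, iters=8, batch_size=8).fit(seed=0)
        assert res.accuracy_matrix.shape == (3, 3)

    def test_task_il_xdg_uses_task_masks(self, synthetic_pair):
        from bireplay import build_split_protocol

        train, test = synthetic_pair
        proto = build_split_protocol(train, test, 3, 2, scenario="task_il")
        res = ContinualLearner(proto, method="xdg", hidden_layers=(32, 32),
                               xdg_percent=50.0, iters=60, batch_size=16).fit(seed=0)
        assert res.final_average_accuracy > 0.6
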