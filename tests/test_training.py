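import math

import numpy as np
import pytest
from scipy import optimize

from formucomet.autodiff import Tensor
from formucomet.encoders import FormulationTokenizer
from formucomet.formulation import Formulation
from formucomet.model import CometConfig
from formucomet.training import (
    RankPair,
    TrainConfig,
    augment_molar_noise,
    cagrad_combine,
    make_pairs,
    ranking_loss,
    regression_loss,
    train,
)

LN2 = math.log(2.0)


def _labelled(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            Formulation(
                components=(("a", 35.0), ("b", 16.0), ("c", 46.5), ("d", 2.5)),
                np_ratio=6.0,
                labels={"t": float(rng.uniform())},
                id=f"f{i}",
            )
        )
    return out


class TestMakePairs:
    @pytest.mark.parametrize("n,expected", [(64, 2016), (2, 1), (10, 45)])
    def test_all_pairs_count(self, n, expected):
        pairs = make_pairs(_labelled(n), "t")
        assert len(pairs) == expected
        for p in pairs:
            assert p.y_h > p.y_l

    def test_exact_ties_excluded(self):
        fs = _labelled(4)
        fs = [f.with_labels({"t": 0.5}) for f in fs[:2]] + fs[2:]
        assert len(make_pairs(fs, "t")) == 5  # 6 pairs minus the tied one

    def test_too_small_batch(self):
        with pytest.raises(ValueError):
            make_pairs(_labelled(1), "t")

    def test_rank_pair_invariant(self):
        with pytest.raises(ValueError):
            RankPair(None, None, 0.2, 0.8)


class TestRankingLoss:
    def test_zero_gap_zero_margin_gives_ln2(self):
        assert ranking_loss(1.0, 1.0, 0.9, 0.1, 0.0) == pytest.approx(LN2)

    def test_margin_cancellation_gives_ln2(self):
        lam, yh, yl = 0.01, 0.9, 0.2
        gap = lam * (yh - yl)
        assert ranking_loss(gap, 0.0, yh, yl, lam) == pytest.approx(LN2)

    def test_closed_form_at_gap_two(self):
        expected = -math.log(1.0 / (1.0 + math.exp(-2.0)))
        assert ranking_loss(2.0, 0.0, 1.0, 0.0, 0.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.1269, abs=1e-4)

    def test_strictly_decreasing_in_score_gap(self):
        gaps = np.linspace(-3, 3, 25)
        losses = [ranking_loss(g, 0.0, 1.0, 0.0, 0.0) for g in gaps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_invariant_to_constant_shift(self):
        a = ranking_loss(1.3, 0.4, 0.8, 0.3)
        b = ranking_loss(1.3 + 7.0, 0.4 + 7.0, 0.8, 0.3)
        assert a == pytest.approx(b)

    def test_tensor_path_matches_scalar_path(self):
        s_h = Tensor(np.array([1.5, 0.2], np.float32))
        s_l = Tensor(np.array([0.5, 0.6], np.float32))
        t = ranking_loss(s_h, s_l, np.array([0.9, 0.8]), np.array([0.1, 0.2]), 0.01)
        s = ranking_loss(
            np.array([1.5, 0.2]), np.array([0.5, 0.6]),
            np.array([0.9, 0.8]), np.array([0.1, 0.2]), 0.01,
        )
        assert float(t.data) == pytest.approx(s, abs=1e-6)


class TestRegressionLoss:
    def test_values(self):
        assert regression_loss(0.4, 0.4) == 0.0
        assert regression_loss(1.4, 0.4) == pytest.approx(1.0)

    def test_batch_mean(self):
        s = np.array([0.1, 0.5, 0.9])
        y = np.array([0.2, 0.5, 0.4])
        assert regression_loss(s, y) == pytest.approx(np.mean((s - y) ** 2))


class TestNoiseAugmentation:
    def test_zero_fraction_is_identity(self, base_formulation):
        rng = np.random.default_rng(0)
        assert augment_molar_noise(base_formulation, rng, 0.0) is base_formulation

    def test_zero_percent_component_stays_zero(self):
        f = Formulation(
            components=(("a", 0.0), ("b", 100.0)), np_ratio=6.0
        )
        rng = np.random.default_rng(0)
        g = augment_molar_noise(f, rng, 0.1)
        assert g.components[0][1] == 0.0

    def test_noise_scale_monte_carlo(self):
        rng = np.random.default_rng(0)
        f = Formulation(components=(("a", 50.0), ("b", 50.0)), np_ratio=6.0)
        draws = np.array(
            [augment_molar_noise(f, rng, 0.1).components[0][1] for _ in range(100_000)]
        )
        assert draws.std() == pytest.approx(5.0, abs=0.05)
        assert draws.mean() == pytest.approx(50.0, abs=0.05)

    def test_labels_untouched(self):
        f = Formulation(
            components=(("a", 50.0), ("b", 50.0)), np_ratio=6.0, labels={"t": 0.7}
        )
        g = augment_molar_noise(f, np.random.default_rng(0), 0.1)
        assert g.labels == f.labels


def brute_force_cagrad(grads, c, n_grid=200_000, seed=0):
    """Direct numerical solve of max_d min_i <g_i, d> s.t. ||d - g0|| <= c||g0||."""
    G = np.stack(grads)
    g0 = G.mean(axis=0)
    r = c * np.linalg.norm(g0)

    def neg_worst(d):
        return -np.min(G @ d)

    cons = {"type": "ineq", "fun": lambda d: r**2 - np.sum((d - g0) ** 2)}
    best = None
    rng = np.random.default_rng(seed)
    for trial in range(8):
        d0 = g0 + (0 if trial == 0 else rng.normal(0, r / 2, size=g0.shape))
        res = optimize.minimize(neg_worst, d0, constraints=[cons], method="SLSQP")
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestCagrad:
    def test_identical_gradients_pass_through(self):
        g = np.array([1.0, -2.0, 3.0])
        out = cagrad_combine([g, g, g], c=0.2)
        assert out == pytest.approx(g, rel=1e-6)

    def test_c_zero_returns_average(self):
        g1, g2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert cagrad_combine([g1, g2], c=0.0) == pytest.approx([0.5, 0.5])

    def test_single_task_returns_gradient(self):
        g = np.array([2.0, -1.0])
        assert cagrad_combine([g], c=0.5) == pytest.approx(g)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cagrad_combine([np.ones(3), np.ones(4)])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_2d_toys(self, seed):
        rng = np.random.default_rng(seed)
        grads = [rng.normal(size=2), rng.normal(size=2)]
        ours = cagrad_combine(grads, c=0.2)
        ref = brute_force_cagrad(grads, c=0.2)
        # the returned scale is a step-size convention; the direction
        # must match the maximin solution
        cos = ours @ ref / (np.linalg.norm(ours) * np.linalg.norm(ref))
        assert cos > 1 - 1e-5
        G = np.stack(grads)
        scaled = ours * (1.2)  # undo the 1/(1+c) convention
        assert np.min(G @ scaled) >= np.min(G @ ref) - 1e-4 * (1 + np.linalg.norm(ref))

    @pytest.mark.parametrize("seed", range(3))
    def test_nonnegative_inner_products_on_5task_toys(self, seed):
        rng = np.random.default_rng(100 + seed)
        grads = [rng.normal(size=6) for _ in range(5)]
        d = cagrad_combine(grads, c=0.2)
        ref = brute_force_cagrad(grads, c=0.2)
        worst_ref = np.min(np.stack(grads) @ ref)
        if worst_ref >= 0:  # feasible set allows non-conflicting direction
            assert np.min(np.stack(grads) @ d) >= -1e-6


class TestTrainLoop:
    def test_recovers_noiseless_oracle_ranking(self, noiseless_dataset, tokenizer):
        data, _, _ = noiseless_dataset
        cfg = TrainConfig(max_epochs=50, patience=50, seed=0)
        mcfg = CometConfig(tasks=["efficacy"], n_blocks=1, seed=0)
        model, hist = train(data, ["efficacy"], cfg, mcfg, tokenizer=tokenizer)
        assert hist.best_val_spearman > 0.9
        assert hist.best_epoch < 50

    def test_determinism_under_fixed_seed(self, noiseless_dataset, tokenizer):
        data, _, _ = noiseless_dataset
        cfg = TrainConfig(max_epochs=3, patience=10, seed=4)
        mcfg = CometConfig(tasks=["efficacy"], n_blocks=1, seed=4)
        _, h1 = train(data[:100], ["efficacy"], cfg, mcfg, tokenizer=tokenizer)
        _, h2 = train(data[:100], ["efficacy"], cfg, mcfg, tokenizer=tokenizer)
        assert h1.epochs[-1]["val_spearman"] == h2.epochs[-1]["val_spearman"]

    def test_needs_distinct_labels(self, tokenizer, catalogue):
        fs = [
            Formulation(
                components=(("IL-MC3", 35.0), ("HL-DOPE", 16.0), ("ST-CHOL", 46.5), ("PEG-C14", 2.5)),
                np_ratio=6.0,
                labels={"t": 0.5},
                id=f"f{i}",
            )
            for i in range(20)
        ]
        with pytest.raises(ValueError, match="distinct labels"):
            train(fs, ["t"], TrainConfig(max_epochs=1), tokenizer=tokenizer)

    def test_loss_falls_below_ln2_on_separable_labels(self, noiseless_dataset, tokenizer):
        data, _, _ = noiseless_dataset
        cfg = TrainConfig(max_epochs=12, patience=12, seed=1)
        mcfg = CometConfig(tasks=["efficacy"], n_blocks=1, seed=1)
        _, hist = train(data, ["efficacy"], cfg, mcfg, tokenizer=tokenizer)
        assert hist.epochs[-1]["losses"]["efficacy"] < LN2
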