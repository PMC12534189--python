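import numpy as np
import pytest

from formucomet.ensemble import (
    diverse_hits,
    drop_uncertain_half,
    ensemble_score,
    fivefold_ensemble,
    normalize_scores,
    relative_uncertainty,
    select_top_fraction,
    top_fraction_count,
)
from formucomet.formulation import (
    Catalogue,
    ComponentClass,
    Formulation,
    FormulationError,
    MoleculeRecord,
)


def _f(pcts, ids=("a", "b", "c", "d"), fid=None):
    return Formulation(components=tuple(zip(ids, pcts)), np_ratio=6.0, id=fid)


class TestNormalization:
    def test_reference_mean_maps_to_zero(self):
        ref_means, ref_stds = np.array([2.0]), np.array([0.5])
        out = normalize_scores(np.array([[2.0]]), ref_means, ref_stds)
        assert out[0, 0] == 0.0

    def test_hand_example_population_sd(self):
        ref = np.array([[1.0, 2.0, 3.0]])
        means, stds = ref.mean(axis=1), ref.std(axis=1)
        out = normalize_scores(np.array([[3.0]]), means, stds)
        assert out[0, 0] == pytest.approx(1.2247, abs=1e-4)

    def test_normalized_reference_has_unit_moments(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(3.0, 7.0, size=(4, 50))
        out = normalize_scores(ref, ref.mean(axis=1), ref.std(axis=1))
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=1), 1.0, atol=1e-9)


class TestEnsembleScore:
    def test_mean(self):
        assert ensemble_score(np.array([[0.5], [-0.5]]))[0] == 0.0

    def test_single_model_identity(self):
        assert ensemble_score(np.array([[1.7]]))[0] == pytest.approx(1.7)

    def test_copies(self):
        assert ensemble_score(np.tile(0.3, (5, 1)))[0] == pytest.approx(0.3)


class TestRelativeUncertainty:
    def test_identical_scores_zero_uncertainty(self):
        u, dropped, _ = relative_uncertainty(np.array([[1.0], [1.0]]), ref_ensemble_min=0.0)
        assert u[0] == 0.0 and not dropped[0]

    def test_hand_example(self):
        u, dropped, shifted = relative_uncertainty(
            np.array([[1.0], [3.0]]), ref_ensemble_min=-1.0
        )
        assert shifted[0] == pytest.approx(3.0)
        assert u[0] == pytest.approx(1.0 / 3.0)

    def test_negative_shifted_dropped(self):
        u, dropped, _ = relative_uncertainty(
            np.array([[-2.0], [-3.0]]), ref_ensemble_min=0.0
        )
        assert dropped[0]

    def test_needs_two_models(self):
        with pytest.raises(FormulationError):
            relative_uncertainty(np.array([[1.0]]), 0.0)


class TestSelection:
    def test_top_fraction_counts(self):
        assert top_fraction_count(1000, 0.1) == 100
        assert top_fraction_count(27_354_600, 0.001) == 27_354
        assert top_fraction_count(34_539_960, 0.001) == 34_539

    def test_select_all_at_fraction_one(self):
        scored = [(_f((25, 25, 25, 25)), float(s)) for s in range(5)]
        assert len(select_top_fraction(scored, 1.0)) == 5

    def test_ties_broken_by_enumeration_order(self):
        scored = [(_f((25, 25, 25, 25), fid=f"f{i}"), 1.0) for i in range(4)]
        out = select_top_fraction(scored, 0.5)
        assert [f.id for f, _ in out] == ["f0", "f1"]

    def test_empty_stream(self):
        with pytest.raises(FormulationError):
            select_top_fraction([], 0.1)

    def test_drop_uncertain_half_floor(self):
        cands = [(_f((25, 25, 25, 25), fid=f"f{i}"), 1.0, float(i)) for i in range(5)]
        out = drop_uncertain_half(cands)
        assert [f.id for f, _, _ in out] == ["f0", "f1"]
        assert drop_uncertain_half(cands[:1]) == []

    def test_drop_uncertain_half_paper_counts(self):
        cands = [(_f((25, 25, 25, 25)), 1.0, float(i)) for i in range(27_354)]
        assert len(drop_uncertain_half(cands)) == 13_677

    def test_all_equal_uncertainty_keeps_first_half(self):
        cands = [(_f((25, 25, 25, 25), fid=f"f{i}"), 1.0, 0.5) for i in range(4)]
        assert [f.id for f, _, _ in drop_uncertain_half(cands)] == ["f0", "f1"]


class TestDiverseHits:
    @pytest.fixture()
    def tiny_catalogue(self):
        return Catalogue(
            [
                MoleculeRecord("a", "CCN", ComponentClass.IONIZABLE, 1, 300.0),
                MoleculeRecord("b", "CCO", ComponentClass.HELPER),
                MoleculeRecord("c", "CCC", ComponentClass.STEROL),
                MoleculeRecord("d", "COC", ComponentClass.PEG),
            ]
        )

    def test_two_separated_blobs(self, tiny_catalogue):
        rng = np.random.default_rng(0)
        cands = []
        for i in range(20):
            base = (60.0, 10.0, 27.5, 2.5) if i < 10 else (15.0, 40.0, 42.5, 2.5)
            jit = rng.normal(0, 0.5, 3)
            pcts = (base[0] + jit[0], base[1] + jit[1], base[2] + jit[2],
                    100.0 - sum(base[:3]) - sum(jit))
            cands.append((_f(pcts), float(rng.uniform())))
        picks = diverse_hits(cands, tiny_catalogue, k=2, n_restarts=10, seed=0)
        assert len(picks) == 2
        sides = {p[0].components[0][1] > 40 for p in picks}
        assert sides == {True, False}  # one pick per blob
        # and each pick is the top scorer of its blob
        top_by_blob = {
            True: max(cands[:10], key=lambda t: t[1])[1],
            False: max(cands[10:], key=lambda t: t[1])[1],
        }
        for f, s in picks:
            assert s == top_by_blob[f.components[0][1] > 40]

    def test_k_equals_n_returns_all(self, tiny_catalogue):
        cands = [(_f((25, 25, 25, 25)), 1.0), (_f((30, 20, 25, 25)), 2.0)]
        assert diverse_hits(cands, tiny_catalogue, k=2, n_restarts=5) == cands

    def test_k_too_large(self, tiny_catalogue):
        with pytest.raises(FormulationError):
            diverse_hits([(_f((25, 25, 25, 25)), 1.0)], tiny_catalogue, k=2)


class TestFivefoldEnsemble:
    def test_folds_partition_dataset(self, noiseless_dataset, tokenizer):
        from formucomet.model import CometConfig
        from formucomet.training import TrainConfig

        data, _, _ = noiseless_dataset
        data = data[:60]
        models = fivefold_ensemble(
            data,
            ["efficacy"],
            TrainConfig(max_epochs=2, patience=2, seed=0),
            CometConfig(tasks=["efficacy"], n_blocks=1, d_token=64, n_heads=4,
                        mlp_hidden=64, head_hidden=32, seed=0),
            tokenizer=tokenizer,
            n_models=5,
        )
        assert len(models) == 5
        seeds = {m.config.seed for m in models}
        assert len(seeds) == 5

    def test_too_few_samples(self, tokenizer):
        with pytest.raises(FormulationError):
            fivefold_ensemble([], ["t"], tokenizer=tokenizer, n_models=5)


class TestAffineInvariance:
    def test_selection_invariant_to_per_model_rescaling(self):
        rng = np.random.default_rng(3)
        ref_raw = rng.normal(size=(3, 40))
        cand_raw = rng.normal(size=(3, 100))

        def select(ref, cand):
            means, stds = ref.mean(axis=1), ref.std(axis=1)
            norm = normalize_scores(cand, means, stds)
            scored = [(_f((25, 25, 25, 25), fid=f"f{i}"), float(s))
                      for i, s in enumerate(ensemble_score(norm))]
            return [f.id for f, _ in select_top_fraction(scored, 0.1)]

        base = select(ref_raw, cand_raw)
        scale = np.array([[2.0], [0.3], [5.0]])
        shift = np.array([[1.0], [-4.0], [0.5]])
        rescaled = select(ref_raw * scale + shift, cand_raw * scale + shift)
        assert base == rescaled
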