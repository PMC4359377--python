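"""Ridge RTP models: closed form, loo-CV, scoring, bundled weights."""

import numpy as np
import pytest
import scipy.stats

from readthrough import (
    DEFAULT_K,
    RidgeModel,
    TrainingSet,
    default_k_grid,
    fit_ridge,
    loo_cv_sse,
    predict_btr,
    published_model,
    rtp_score,
    select_k,
)
from readthrough.context import BASES, STOP_CODONS
from readthrough.ridge import design_matrix, raw_sum
from readthrough.synth import gen_scc_dataset, random_context


# -- independent oracles (coded separately from the implementation) ---------

def oracle_design_matrix(contexts, positions):
    """Feature matrix built by direct enumeration, no shared encoder."""
    rows = []
    for c in contexts:
        row = []
        for p in positions:
            base = c.upstream[p + 6] if p < 0 else c.downstream[p - 4]
            row.extend(1.0 if b == base else 0.0 for b in "ACGT")
        row.extend(1.0 if s == c.stop else 0.0 for s in ("TAA", "TAG", "TGA"))
        rows.append(row)
    X = np.array(rows)
    return X / np.sqrt(len(positions) + 1)


def oracle_ridge(contexts, y, positions, k):
    X = oracle_design_matrix(contexts, positions)
    return np.linalg.solve(X.T @ X + k * np.eye(X.shape[1]), X.T @ y)


def oracle_loo_sse(train, positions, k):
    """Refit n models from scratch, each without one example."""
    n = train.n
    sse = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        w = oracle_ridge(
            [train.contexts[j] for j in keep], train.y[keep], positions, k
        )
        x_i = oracle_design_matrix([train.contexts[i]], positions)[0]
        sse += (train.y[i] - w @ x_i) ** 2
    return sse


def rng_contexts(n, seed):
    rng = np.random.default_rng(seed)
    return [random_context(rng) for _ in range(n)]


class TestFitRidge:
    def test_matches_independent_dense_solve(self):
        positions = (4, 5, 6)  # d = 15, n = 12: small dense instance
        contexts = rng_contexts(12, seed=3)
        y = np.abs(np.sin(np.arange(12)))
        train = TrainingSet(contexts=contexts, y=y)
        model = fit_ridge(train, positions, k=1.0)
        expected = oracle_ridge(contexts, y, positions, 1.0)
        np.testing.assert_allclose(model.weight_vector(), expected, rtol=1e-10)

    def test_three_contexts_k_one(self):
        contexts = rng_contexts(3, seed=9)
        y = np.array([0.1, 1.2, 0.4])
        train = TrainingSet(contexts=contexts, y=y)
        model = fit_ridge(train, k=1.0)
        expected = oracle_ridge(contexts, y, tuple(model.positions), 1.0)
        np.testing.assert_allclose(model.weight_vector(), expected, rtol=1e-10)

    def test_heavy_shrinkage(self):
        contexts = rng_contexts(10, seed=1)
        y = np.linspace(0.1, 3.0, 10)
        model = fit_ridge(TrainingSet(contexts=contexts, y=y), k=1e9)
        assert np.abs(model.weight_vector()).max() < 1e-6 * y.max()

    def test_invalid_k_rejected(self):
        contexts = rng_contexts(5, seed=2)
        train = TrainingSet(contexts=contexts, y=np.ones(5))
        with pytest.raises(ValueError):
            fit_ridge(train, k=0.0)

    def test_shrinkage_monotone_in_k(self):
        ds = gen_scc_dataset(40, noise_sd=0.05, seed=4)
        norms = [
            fit_ridge(ds.train, k=k).weight_norm for k in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_permutation_invariance(self):
        ds = gen_scc_dataset(30, noise_sd=0.1, seed=6)
        perm = np.random.default_rng(0).permutation(30)
        shuffled = TrainingSet(
            contexts=[ds.train.contexts[i] for i in perm], y=ds.train.y[perm]
        )
        np.testing.assert_allclose(
            fit_ridge(ds.train, k=1.0).weight_vector(),
            fit_ridge(shuffled, k=1.0).weight_vector(),
            rtol=1e-10, atol=1e-12,
        )


class TestLooCV:
    def test_zero_targets_give_zero_sse(self):
        contexts = rng_contexts(6, seed=7)
        train = TrainingSet(contexts=contexts, y=np.zeros(6))
        assert loo_cv_sse(train, k=1.0).sse == 0.0

    def test_matches_naive_refit_oracle(self):
        contexts = rng_contexts(8, seed=8)
        y = np.abs(np.cos(np.arange(8))) + 0.1
        train = TrainingSet(contexts=contexts, y=y)
        for positions in [(4, 5, 6), (-6, 4, 5, 6, 7)]:
            got = loo_cv_sse(train, positions, k=0.5).sse
            want = oracle_loo_sse(train, positions, 0.5)
            assert got == pytest.approx(want, rel=1e-9)

    def test_too_few_examples_rejected(self):
        contexts = rng_contexts(2, seed=1)
        train = TrainingSet(contexts=contexts, y=np.ones(2))
        with pytest.raises(ValueError):
            loo_cv_sse(train, k=1.0)


class TestSelectK:
    def test_single_value_grid(self):
        ds = gen_scc_dataset(20, noise_sd=0.1, seed=3)
        k, _ = select_k(ds.train, grid=[7.0])
        assert k == 7.0

    def test_default_grid_enumeration(self):
        grid = default_k_grid()
        assert len(grid) == 21
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e3)
        assert grid[11] == pytest.approx(10 ** 0.3)
        # uniform step of 0.3 in the exponent
        assert np.allclose(np.diff(np.log10(grid)), 0.3)

    def test_matches_exhaustive_grid_evaluation(self):
        ds = gen_scc_dataset(40, noise_sd=0.0, seed=12)
        k_best, sse_best = select_k(ds.train)
        sses = {k: loo_cv_sse(ds.train, k=k).sse for k in default_k_grid()}
        assert sse_best == min(sses.values())
        assert sses[k_best] == sse_best

    def test_empty_grid_rejected(self):
        ds = gen_scc_dataset(10, seed=0)
        with pytest.raises(ValueError):
            select_k(ds.train, grid=[])


def zero_model(positions=(4, 5, 6)):
    return RidgeModel(
        positions=positions,
        context_weights={(p, b): 0.0 for p in positions for b in BASES},
        stop_weights={s: 0.0 for s in STOP_CODONS},
        k=1.0,
    )


class TestScoring:
    def test_zero_model_predicts_zero(self, ldhb):
        assert predict_btr(zero_model(), ldhb) == 0.0

    def test_single_weight_model(self, ldhb):
        m = zero_model()
        m.context_weights[(4, "C")] = 0.5  # LDHB has C at +4
        assert predict_btr(m, ldhb) == pytest.approx(0.5 / 2.0)

    def test_linfs3_ldhb_hand_sum(self, linfs3, ldhb):
        # published cells TGA + C@+4 + T@+5 + A@+6, divided by sqrt(4)
        assert raw_sum(linfs3, ldhb) == pytest.approx(0.01185)
        assert predict_btr(linfs3, ldhb) == pytest.approx(0.005925)

    def test_linfs3_ldhb_rtp_printed_shortcut(self, linfs3, ldhb):
        score = rtp_score(linfs3, ldhb)
        # dividing the raw sum by the printed shortcut 0.0126 reproduces
        # the exact normalised score within weight-rounding (~0.940)
        assert score.rtp == pytest.approx(0.01185 / 0.0126, rel=2e-3)
        assert score.rtp == pytest.approx(score.predicted_btr / linfs3.weight_norm)

    def test_negative_rtp_allowed(self, linfs3):
        from readthrough import StopCodonContext

        # G at +4, A at +5, G at +6 match only negative LINfs3 weights
        ctx = StopCodonContext("AAAAAA", "TAG", "GAGAAA")
        assert rtp_score(linfs3, ctx).rtp < 0

    def test_rtp_scale_invariance(self, linfs3, ldhb):
        scaled = RidgeModel(
            positions=linfs3.positions,
            context_weights={k: 10 * w for k, w in linfs3.context_weights.items()},
            stop_weights={s: 10 * w for s, w in linfs3.stop_weights.items()},
            k=linfs3.k,
        )
        assert rtp_score(scaled, ldhb).rtp == pytest.approx(
            rtp_score(linfs3, ldhb).rtp
        )

    def test_zero_norm_model_rejected(self, ldhb):
        with pytest.raises(ValueError):
            rtp_score(zero_model(), ldhb)


class TestPublishedModels:
    def test_linfs3_cells(self, linfs3):
        assert linfs3.stop_weights["TGA"] == 0.00229
        assert linfs3.context_weights[(4, "C")] == 0.00351
        assert linfs3.positions == (4, 5, 6)

    def test_liniter_cells(self, liniter):
        assert liniter.context_weights[(4, "C")] == 0.00375
        assert liniter.context_weights[(-6, "T")] == 0.00200
        assert len(liniter.positions) == 12

    def test_weight_norms_match_printed_values(self, linfs3, liniter):
        assert linfs3.weight_norm == pytest.approx(0.0063, rel=0.02)
        assert liniter.weight_norm == pytest.approx(0.0088, rel=0.02)

    def test_default_k(self, linfs3):
        assert DEFAULT_K == pytest.approx(1.995, abs=5e-4)
        assert linfs3.k == DEFAULT_K

    def test_unpublished_model_rejected(self):
        with pytest.raises(KeyError):
            published_model("LINfs5")


class TestParameterRecovery:
    def test_noise_free_recovery(self, small_noisefree_set):
        ds = small_noisefree_set
        fitted = fit_ridge(ds.train, k=1e-8)
        err = np.abs(fitted.weight_vector() - ds.planted.weight_vector()).max()
        assert err < 1e-6

    def test_heldout_correlation_under_noise(self):
        clean = gen_scc_dataset(120, noise_sd=0.0, seed=2)
        noisy = gen_scc_dataset(120, noise_sd=0.02, seed=2)  # same contexts
        k, _ = select_k(noisy.train)
        preds = loo_cv_sse(noisy.train, k=k).predictions
        r, _ = scipy.stats.pearsonr(preds, clean.train.y)
        assert r > 0.9


class TestSerialization:
    def test_round_trip(self, tmp_path, linfs3, ldhb):
        path = tmp_path / "model.json"
        linfs3.save(path)
        loaded = RidgeModel.load(path)
        assert loaded.positions == linfs3.positions
        assert rtp_score(loaded, ldhb).rtp == pytest.approx(
            rtp_score(linfs3, ldhb).rtp
        )

    def test_corrupted_norm_detected(self, tmp_path, linfs3):
        import json

        d = linfs3.to_dict()
        d["weight_norm"] = d["weight_norm"] * 2
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(d))
        with pytest.raises(ValueError):
            RidgeModel.load(path)
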