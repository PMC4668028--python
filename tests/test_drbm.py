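import numpy as np
import pytest

from mccad.drbm import DRBM, DRBMTrainConfig, classify_patches, extract_patch
from mccad.io import MammogramImage


def _random_model(rng, n_visible=None, n_hidden=None, scale=1.0):
    nv = n_visible if n_visible is not None else int(rng.integers(2, 7))
    nh = n_hidden if n_hidden is not None else int(rng.integers(1, 13))
    model = DRBM(nv, nh, seed=int(rng.integers(1 << 30)))
    model.W = rng.normal(0, scale, size=(nh, nv))
    model.U = rng.normal(0, scale, size=(nh, 2))
    model.b = rng.normal(0, scale, size=nv)
    model.c = rng.normal(0, scale, size=nh)
    model.d = rng.normal(0, scale, size=2)
    return model


def _enumerate_conditional(model, x):
    """p(y|x) by summing exp(-E) over every hidden configuration."""
    nh = model.n_hidden
    states = ((np.arange(2**nh)[:, None] >> np.arange(nh)) & 1).astype(float)
    log_terms = np.empty((2, 2**nh))
    for y in (0, 1):
        for k, h in enumerate(states):
            log_terms[y, k] = -model.energy(y, x, h)
    m = log_terms.max()
    totals = np.exp(log_terms - m).sum(axis=1)
    return totals / totals.sum()


class TestConditionalProbability:
    def test_enumeration_oracle_100_random_models(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            model = _random_model(rng)
            x = rng.uniform(size=model.n_visible)
            want = _enumerate_conditional(model, x)
            got = model.conditional_prob(x)[0]
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst < 1e-8

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        model = _random_model(rng, n_visible=5, n_hidden=7)
        X = rng.uniform(size=(11, 5))
        p = model.conditional_prob(X)
        assert p.shape == (11, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=0, atol=1e-12)

    def test_zero_model_is_uninformative(self):
        model = DRBM(5, 4, seed=0)
        model.W[:] = 0.0
        model.U[:] = 0.0
        X = np.random.default_rng(2).uniform(size=(10, 5))
        p = model.conditional_prob(X)
        np.testing.assert_allclose(p, 0.5, rtol=0, atol=1e-12)
        y = np.random.default_rng(3).integers(0, 2, size=10)
        assert model.nll(X, y) == pytest.approx(10 * np.log(2), abs=1e-10)

    def test_label_symmetry(self):
        rng = np.random.default_rng(4)
        model = _random_model(rng, n_visible=4, n_hidden=5)
        swapped = DRBM(4, 5, seed=0)
        swapped.W = model.W.copy()
        swapped.b = model.b.copy()
        swapped.c = model.c.copy()
        swapped.U = model.U[:, ::-1].copy()
        swapped.d = model.d[::-1].copy()
        X = rng.uniform(size=(6, 4))
        np.testing.assert_allclose(
            model.conditional_prob(X), swapped.conditional_prob(X)[:, ::-1], atol=1e-12
        )

    def test_non_finite_parameters_rejected(self):
        model = DRBM(3, 2, seed=0)
        model.W[0, 0] = np.nan
        with pytest.raises(ValueError):
            model.conditional_prob(np.zeros(3))

    def test_dimension_mismatch(self):
        model = DRBM(3, 2, seed=0)
        with pytest.raises(ValueError):
            model.conditional_prob(np.zeros((2, 4)))
        with pytest.raises(ValueError):
            model.energy(0, np.zeros(4), np.zeros(2))


class TestGradients:
    def test_discriminative_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        model = _random_model(rng, n_visible=6, n_hidden=4, scale=0.5)
        X = rng.uniform(size=(5, 6))
        y = np.array([0, 1, 0, 1, 1])
        grads = model.discriminative_gradient(X, y)
        eps = 1e-6
        for name in ("W", "U", "b", "c", "d"):
            param = getattr(model, name)
            numeric = np.zeros_like(param)
            it = np.nditer(param, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                up = model.nll(X, y)
                param[idx] = orig - eps
                dn = model.nll(X, y)
                param[idx] = orig
                numeric[idx] = (up - dn) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(grads[name], numeric, rtol=1e-5, atol=1e-5)

    def test_visible_bias_gradient_is_zero(self):
        # b'x cancels in p(y|x), so the conditional objective ignores b
        rng = np.random.default_rng(6)
        model = _random_model(rng, n_visible=4, n_hidden=3)
        g = model.discriminative_gradient(rng.uniform(size=(3, 4)), np.array([0, 1, 0]))
        assert (g["b"] == 0).all()


def _toy_patches(rng, n_per_class=20, noise=0.1):
    proto = {0: np.array([1.0, 1.0, 0.0, 0.0]), 1: np.array([0.0, 0.0, 1.0, 1.0])}
    X, y = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            X.append(np.clip(proto[cls] + rng.uniform(-noise, noise, size=4), 0, 1))
            y.append(cls)
    return np.stack(X), np.asarray(y)


class TestTraining:
    def test_cd_learns_toy_prototypes(self):
        rng = np.random.default_rng(7)
        X, y = _toy_patches(rng)
        model = DRBM(4, 8, seed=0)
        nll0 = model.nll(X, y)
        log = []
        model.fit(
            X, y,
            DRBMTrainConfig(learning_rate=0.5, n_epochs=100, batch_size=10, seed=0, patch_side=3),
            method="cd", log=log,
        )
        assert model.nll(X, y) < nll0
        pred = model.conditional_prob(X)[:, 1] > 0.5
        assert (pred == (y == 1)).mean() == 1.0
        assert len(log) == 100

    def test_disc_training_reduces_nll(self):
        rng = np.random.default_rng(8)
        X, y = _toy_patches(rng)
        model = DRBM(4, 8, seed=1)
        nll0 = model.nll(X, y)
        model.fit(
            X, y,
            DRBMTrainConfig(learning_rate=0.5, n_epochs=50, batch_size=10, seed=0, patch_side=3),
            method="disc",
        )
        assert model.nll(X, y) < 0.5 * nll0

    def test_unknown_method_rejected(self):
        X, y = _toy_patches(np.random.default_rng(9))
        with pytest.raises(ValueError):
            DRBM(4, 4, seed=0).fit(
                X, y, DRBMTrainConfig(n_epochs=1, patch_side=3), method="mcmc"
            )

    def test_fit_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        X, y = _toy_patches(rng)
        cfg = DRBMTrainConfig(learning_rate=0.2, n_epochs=5, seed=4, patch_side=3)
        a = DRBM(4, 6, seed=2).fit(X, y, cfg, method="cd")
        b = DRBM(4, 6, seed=2).fit(X, y, cfg, method="cd")
        np.testing.assert_array_equal(a.W, b.W)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DRBMTrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            DRBMTrainConfig(cd_steps=0)
        with pytest.raises(ValueError):
            DRBMTrainConfig(patch_side=4)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        model = _random_model(rng, n_visible=5, n_hidden=3)
        path = tmp_path / "drbm.json"
        model.save(path)
        back = DRBM.load(path)
        for name in ("W", "U", "b", "c", "d"):
            np.testing.assert_array_equal(getattr(model, name), getattr(back, name))

    def test_version_check(self, tmp_path):
        path = tmp_path / "drbm.json"
        path.write_text('{"format_version": 99, "n_visible": 1, "n_hidden": 1}')
        with pytest.raises(ValueError):
            DRBM.load(path)


class TestPatches:
    def _image(self):
        px = np.arange(36, dtype=float).reshape(6, 6)
        return MammogramImage(pixels=px, spacing_mm=0.1, bit_depth=8)

    def test_interior_patch(self):
        img = self._image()
        patch = extract_patch(img, (3, 3), 3)
        np.testing.assert_allclose(patch, img.pixels[2:5, 2:5].ravel() / 255.0)

    def test_border_patch_matches_pad_oracle(self):
        img = self._image()
        padded = np.pad(img.pixels, 1, mode="symmetric")
        patch = extract_patch(img, (0, 0), 3)
        np.testing.assert_allclose(patch, padded[0:3, 0:3].ravel() / 255.0)

    def test_patch_length_and_range(self):
        img = self._image()
        patch = extract_patch(img, (2, 2), 5)
        assert patch.shape == (25,)
        assert patch.min() >= 0.0 and patch.max() <= 1.0

    def test_patch_side_validation(self):
        img = self._image()
        with pytest.raises(ValueError):
            extract_patch(img, (3, 3), 4)
        with pytest.raises(ValueError):
            extract_patch(img, (3, 3), 7)

    def test_classify_patches_threshold(self):
        img = self._image()
        model = DRBM(9, 4, seed=0)
        model.W[:] = 0.0
        model.U[:] = 0.0  # p = 0.5 everywhere
        cands = [(1, 1), (4, 4)]
        kept = classify_patches(model, cands, img, theta_drbm=0.5, patch_side=3, image_id="x")
        assert [r.point for r in kept] == cands
        assert all(r.score == pytest.approx(0.5) and r.stage == "drbm" for r in kept)
        assert classify_patches(model, cands, img, 0.6, 3) == []
        assert classify_patches(model, [], img, 0.5, 3) == []
        with pytest.raises(ValueError):
            classify_patches(model, cands, img, 1.5, 3)
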