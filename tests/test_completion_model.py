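"""Encoders, latent distributions, losses, training and MAP inference."""

import dataclasses

import numpy as np
import pytest

from sonocomplete._autodiff import Tensor
from sonocomplete.completion_model import (
    CompletionModel,
    LatentDist,
    ModelConfig,
    PRESETS,
    TrainingPair,
    complete,
    composite_loss,
    kl_divergence,
    make_sphere_benchmark,
    split_by_spine,
    train,
)
from sonocomplete.geometry_io import PointCloud

TINY = ModelConfig(
    n_in=64, n_coarse=32, n_out=64, latent_dim=8, feature_dim=32,
    attention_scales=(4,), epochs=2, batch_size=4, learning_rate=1e-3,
)


@pytest.fixture(scope="module")
def tiny_model():
    return CompletionModel(TINY)


@pytest.fixture(scope="module")
def cloud(rng):
    pts = rng.normal(size=(64, 3))
    return pts / np.linalg.norm(pts, axis=1).max()


class TestEncoders:
    def test_permutation_invariance(self, tiny_model, cloud, rng):
        g1, d1 = tiny_model.encode_partial(cloud)
        perm = rng.permutation(len(cloud))
        g2, d2 = tiny_model.encode_partial(cloud[perm])
        assert np.abs(g1.value - g2.value).max() < 1e-5
        assert np.abs(d1.mean.value - d2.mean.value).max() < 1e-5
        p1 = tiny_model.encode_complete(cloud)
        p2 = tiny_model.encode_complete(cloud[perm])
        assert np.abs(p1.log_var.value - p2.log_var.value).max() < 1e-5

    def test_distinct_clouds_distinct_features(self, tiny_model, rng):
        a = rng.normal(size=(64, 3)) * 0.3
        b = a + np.array([0.0, 0.6, 0.0])
        b[:32] *= 0.2  # different shape, not just translation
        ga, _ = tiny_model.encode_partial(a)
        gb, _ = tiny_model.encode_partial(b)
        va, vb = ga.value.ravel(), gb.value.ravel()
        cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        assert cos < 0.999

    def test_output_dimensions(self, tiny_model, cloud):
        g, dist = tiny_model.encode_partial(cloud)
        assert g.value.shape == (1, TINY.feature_dim)
        assert dist.mean.value.shape == (1, TINY.latent_dim)
        assert dist.log_var.value.shape == (1, TINY.latent_dim)

    def test_wrong_cardinality_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="64"):
            tiny_model.encode_partial(rng.normal(size=(32, 3)))

    def test_degenerate_cloud_finite(self, tiny_model):
        dup = np.tile([[0.1, 0.2, 0.3]], (64, 1))
        dist = tiny_model.encode_complete(dup)
        assert np.all(np.isfinite(dist.mean.value))
        assert np.all(np.isfinite(dist.log_var.value))


class TestKL:
    def test_identity_zero(self, rng):
        q = LatentDist(mean=rng.normal(size=8), log_var=rng.normal(size=8))
        assert float(kl_divergence(q, q).value) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        q = LatentDist(mean=np.zeros(1), log_var=np.zeros(1))
        p = LatentDist(mean=np.ones(1), log_var=np.zeros(1))
        assert float(kl_divergence(q, p).value) == pytest.approx(0.5, abs=1e-12)

    def test_matches_monte_carlo(self, rng):
        d = 4
        q = LatentDist(mean=rng.normal(size=d), log_var=rng.uniform(-1, 1, d))
        p = LatentDist(mean=rng.normal(size=d), log_var=rng.uniform(-1, 1, d))
        n = 100_000
        sq = np.exp(0.5 * q.log_var.value)
        x = q.mean.value + sq * rng.standard_normal((n, d))

        def logpdf(x, m, lv):
            return -0.5 * (((x - m) ** 2) / np.exp(lv) + lv + np.log(2 * np.pi)).sum(axis=1)

        samples = logpdf(x, q.mean.value, q.log_var.value) - logpdf(x, p.mean.value, p.log_var.value)
        mc, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n)
        assert float(kl_divergence(q, p).value) == pytest.approx(mc, abs=3 * se)

    def test_dim_mismatch(self, rng):
        q = LatentDist(mean=np.zeros(3), log_var=np.zeros(3))
        p = LatentDist(mean=np.zeros(5), log_var=np.zeros(5))
        with pytest.raises(ValueError):
            kl_divergence(q, p)


class TestDecodersAndLoss:
    def test_decode_deterministic_and_bounded(self, tiny_model, cloud):
        g, prior = tiny_model.encode_partial(cloud)
        a = tiny_model.decode_coarse(prior.mean, g)
        b = tiny_model.decode_coarse(prior.mean, g)
        assert np.array_equal(a.value, b.value)
        assert a.value.shape == (1, TINY.n_coarse, 3)
        assert np.linalg.norm(a.value, axis=2).max() < 10.0

    def test_refine_contract(self, tiny_model, cloud):
        g, prior = tiny_model.encode_partial(cloud)
        coarse = tiny_model.decode_coarse(prior.mean, g)
        fine = tiny_model.refine(cloud[None], coarse)
        fine2 = tiny_model.refine(cloud[None], coarse)
        assert fine.value.shape == (1, TINY.n_out, 3)
        assert np.all(np.isfinite(fine.value))
        assert np.array_equal(fine.value, fine2.value)

    def test_composite_loss_perfect_fit_zero(self, cloud, rng):
        q = LatentDist(mean=rng.normal(size=(1, 8)), log_var=rng.normal(size=(1, 8)))
        gt = cloud[None]
        t = Tensor(gt)
        total, comp = composite_loss(t, t, gt, q, q, kl_weight=0.5)
        assert float(total.value) == pytest.approx(0.0, abs=1e-12)

    def test_composite_loss_decomposition(self, cloud, rng):
        q = LatentDist(mean=rng.normal(size=(1, 8)), log_var=np.zeros((1, 8)))
        p = LatentDist(mean=np.zeros((1, 8)), log_var=np.zeros((1, 8)))
        coarse = Tensor(rng.normal(size=(1, 32, 3)) * 0.3)
        fine = Tensor(rng.normal(size=(1, 64, 3)) * 0.3)
        total0, comp0 = composite_loss(coarse, fine, cloud[None], q, p, kl_weight=0.0)
        assert float(total0.value) == pytest.approx(comp0["cd_coarse"] + comp0["cd_fine"], rel=1e-12)
        total1, comp1 = composite_loss(coarse, fine, cloud[None], q, p, kl_weight=1.0)
        assert float(total1.value) >= max(comp1.pop("total") - 1e-12, comp1["kl"], comp1["cd_fine"])


class TestTraining:
    def test_split_by_spine_disjoint(self):
        pairs = make_sphere_benchmark(60, TINY, seed=1)
        tr, va, te = split_by_spine(pairs, (0.6, 0.2, 0.2), seed=0)
        spines = lambda idx: {pairs[i].spine_id for i in idx}
        assert spines(tr) & spines(va) == set()
        assert spines(tr) & spines(te) == set()
        assert spines(va) & spines(te) == set()
        assert len(tr) + len(va) + len(te) == 60

    def test_too_few_pairs_rejected(self):
        pairs = make_sphere_benchmark(8, TINY, seed=1)
        with pytest.raises(ValueError):
            train(pairs, TINY)

    def test_training_deterministic(self):
        pairs = make_sphere_benchmark(24, TINY, seed=2)
        _, h1 = train(pairs, TINY)
        _, h2 = train(pairs, TINY)
        assert h1["train"] == h2["train"]
        assert h1["val"] == h2["val"]

    def test_pair_outside_slack_rejected(self, rng):
        with pytest.raises(ValueError, match="unit sphere"):
            TrainingPair(
                partial=PointCloud(points=rng.normal(size=(8, 3)) * 5),
                complete=PointCloud(points=rng.normal(size=(8, 3)) * 0.1),
                transform=(np.zeros(3), 1.0),
            )


class TestSmokeBenchmark:
    def test_validation_loss_decreases(self, smoke_model):
        _, history = smoke_model
        assert history["val"][-1] < history["val"][0]
        assert history["best_val"] <= history["val"][0]

    def test_completion_beats_identity_baseline(self, smoke_model, sphere_pairs):
        from sonocomplete.metrics import chamfer

        model, history = smoke_model
        ratios = []
        for i in history["split"]["test"]:
            pair = sphere_pairs[i]
            g, prior = model.encode_partial(pair.partial.points)
            coarse = model.decode_coarse(prior.mean, g)
            fine = model.refine(pair.partial.points[None], coarse)
            cd_fine = chamfer(fine.value[0], pair.complete.points, scale=1.0)
            cd_part = chamfer(pair.partial.points, pair.complete.points, scale=1.0)
            ratios.append(cd_fine / cd_part)
        assert np.median(ratios) <= 0.7

    def test_fine_preserves_input_better_than_coarse(self, smoke_model, sphere_pairs):
        from scipy.spatial import cKDTree

        model, history = smoke_model
        wins = []
        for i in history["split"]["test"][:20]:
            pair = sphere_pairs[i]
            g, prior = model.encode_partial(pair.partial.points)
            coarse = model.decode_coarse(prior.mean, g)
            fine = model.refine(pair.partial.points[None], coarse)
            d_fine = cKDTree(fine.value[0]).query(pair.partial.points)[0].mean()
            d_coarse = cKDTree(coarse.value[0]).query(pair.partial.points)[0].mean()
            wins.append(d_fine <= d_coarse)
        assert np.mean(wins) > 0.5


class TestInference:
    def test_map_complete_deterministic_and_in_sphere(self, smoke_model, sphere_pairs):
        model, _ = smoke_model
        pair = sphere_pairs[0]
        mm = PointCloud(points=pair.partial.points * 30.0 + np.array([5.0, -2.0, 1.0]))
        r1 = complete(mm, model)
        r2 = complete(mm, model)
        assert np.array_equal(r1.fine.points, r2.fine.points)
        center, scale = r1.transform
        # denormalized completion stays near the input's normalization sphere
        assert np.linalg.norm(r1.fine.points.mean(axis=0) - center) < scale

    def test_empty_input_rejected(self, smoke_model):
        model, _ = smoke_model
        with pytest.raises(ValueError):
            complete(PointCloud(points=np.empty((0, 3))), model)

    def test_save_load_roundtrip(self, tiny_model, tmp_path, cloud):
        path = tmp_path / "ck.npz"
        tiny_model.save(path)
        back = CompletionModel.load(path)
        g1, d1 = tiny_model.encode_partial(cloud)
        g2, d2 = back.encode_partial(cloud)
        assert np.array_equal(g1.value, g2.value)
        assert back.config == tiny_model.config
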