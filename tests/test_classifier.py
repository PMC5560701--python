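"""Stratum forests, membership fusion, ERP confidence, argmax labeling."""

import numpy as np
import pytest
from shapely.geometry import box

from freshmap import classifier, scene_sim
from freshmap.classifier import (
    align_classes,
    argmax_label,
    compute_erp,
    erp_image,
    fuse_memberships,
    predict_memberships,
    train_stratum_rf,
)
from freshmap.types import FeatureImage, MembershipImage, TrainingSet


def make_training(rng, n=300, sep=4.0, flip=0.0):
    """Two linearly separable Gaussian classes in 12-D."""
    half = n // 2
    X = np.vstack([rng.normal(0, 1, (half, 12)), rng.normal(sep, 1, (n - half, 12))])
    y = np.r_[np.ones(half, int), np.full(n - half, 2, int)]
    if flip > 0:
        k = int(flip * n)
        idx = rng.choice(n, k, replace=False)
        y[idx] = 3 - y[idx]
    return TrainingSet(
        X=X, y=y, stratum=np.zeros(n, int), rows=np.arange(n), cols=np.zeros(n, int)
    )


class TestRandomForest:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_classes_high_oob(self, seed):
        ts = make_training(np.random.default_rng(seed))
        assert train_stratum_rf(ts, seed=seed).oob_score_ >= 0.98

    def test_label_noise_robustness(self, rng):
        """25% symmetric flips degrade clean hold-out accuracy by < 5 pts."""
        clean = make_training(rng, n=400)
        noisy = make_training(np.random.default_rng(1), n=400, flip=0.25)
        hold = make_training(np.random.default_rng(2), n=400)
        acc_clean = (train_stratum_rf(clean, 0).predict(hold.X) == hold.y).mean()
        acc_noisy = (train_stratum_rf(noisy, 0).predict(hold.X) == hold.y).mean()
        assert acc_clean - acc_noisy < 0.05

    def test_deterministic_predictions(self, rng):
        ts = make_training(rng)
        grid = np.random.default_rng(9).normal(2, 2, (50, 12))
        p1 = train_stratum_rf(ts, seed=4).predict_proba(grid)
        p2 = train_stratum_rf(ts, seed=4).predict_proba(grid)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        ts = make_training(rng)
        ts.y[:] = 1
        with pytest.raises(ValueError):
            train_stratum_rf(ts)


class TestPredictMemberships:
    def make_features(self, rng, h=12, w=12):
        data = rng.uniform(0, 1, (h, w, 12))
        nodata = np.zeros((h, w), bool)
        nodata[0, 0] = True
        return FeatureImage(data, nodata, np.full((h, w), 10))

    def test_nodata_feature_gives_nodata_membership(self, rng):
        ts = make_training(rng)
        model = train_stratum_rf(ts, 0)
        feats = self.make_features(rng)
        member = predict_memberships(model, feats)
        assert member.nodata_mask[0, 0]
        assert not member.nodata_mask[5, 5]

    def test_buffered_polygon_controls_coverage(self, rng):
        ts = make_training(rng)
        model = train_stratum_rf(ts, 0)
        feats = self.make_features(rng)
        left = predict_memberships(model, feats, box(0, 0, 6, 12), buffer=2.0)
        right = predict_memberships(model, feats, box(6, 0, 12, 12), buffer=2.0)
        # overlap zone columns 4..7 covered by both models
        assert not left.nodata_mask[5, 5] and not right.nodata_mask[5, 5]
        assert left.nodata_mask[5, 10] and right.nodata_mask[5, 1]

    def test_band_mismatch_rejected(self, rng):
        ts = make_training(rng)
        model = train_stratum_rf(ts, 0)
        model.n_features_in_ = 11
        with pytest.raises(ValueError):
            predict_memberships(model, self.make_features(rng))

    def test_pure_training_centroid_confidently_classified(self):
        cfg = scene_sim.SceneConfig(width=48, height=48, n_dates=10, noise_sd=0.01,
                                    cloud_fraction=0.0, seed=3)
        bundle = scene_sim.generate_scene(cfg)
        from freshmap.features import extract_features

        feats = extract_features(bundle.stack)
        rng = np.random.default_rng(0)
        ok = bundle.truth.mask() & ~feats.nodata_mask
        rows, cols = np.nonzero(ok)
        sel = rng.choice(len(rows), 500, replace=False)
        ts = TrainingSet(
            X=feats.data[rows[sel], cols[sel]],
            y=bundle.truth.labels[rows[sel], cols[sel]],
            stratum=np.zeros(500, int), rows=rows[sel], cols=cols[sel],
        )
        model = train_stratum_rf(ts, 0)
        member = predict_memberships(model, feats)
        # deep-interior cropland pixel: argmax = cropland with p >= 0.8
        from freshmap.sampler import erode_class_boundaries

        interior = erode_class_boundaries(
            erode_class_boundaries(bundle.truth)
        ).labels == 1
        r, c = np.argwhere(interior)[0]
        vec = member.probs[r, c]
        assert member.classes[np.argmax(vec)] == 1
        assert vec.max() >= 0.8


def mk_member(probs, classes=(1, 2), nodata=None):
    probs = np.asarray(probs, dtype=float)
    if nodata is None:
        nodata = np.zeros(probs.shape[:2], bool)
    return MembershipImage(probs, tuple(classes), nodata)


class TestFusion:
    def test_idempotent_on_identical_sources(self):
        m = mk_member([[[0.6, 0.4]]])
        fused = fuse_memberships([m, m])
        assert np.allclose(fused.probs[0, 0], [0.6, 0.4])

    def test_opposed_vectors_fuse_to_uniform(self):
        a = mk_member([[[0.8, 0.2]]])
        b = mk_member([[[0.2, 0.8]]])
        fused = fuse_memberships([a, b])
        # geometric means sqrt(0.8*0.2) = 0.4 each -> renormalized (0.5, 0.5)
        assert np.allclose(fused.probs[0, 0], [0.5, 0.5], atol=1e-12)

    def test_source_order_irrelevant(self, rng):
        stack = [mk_member(p / p.sum(axis=-1, keepdims=True))
                 for p in rng.uniform(0.01, 1, (3, 4, 4, 2))]
        f1 = fuse_memberships(stack)
        f2 = fuse_memberships(stack[::-1])
        assert np.allclose(f1.probs, f2.probs, atol=1e-12)

    def test_single_coverage_copied_verbatim(self):
        a = mk_member([[[0.7, 0.3], [0.6, 0.4]]], nodata=np.array([[False, True]]))
        b = mk_member([[[0.5, 0.5], [0.1, 0.9]]], nodata=np.array([[True, False]]))
        fused = fuse_memberships([a, b])
        assert np.array_equal(fused.probs[0, 0], [0.7, 0.3])
        assert np.array_equal(fused.probs[0, 1], [0.1, 0.9])

    def test_normalization_conserved(self, rng):
        stack = [mk_member(p / p.sum(axis=-1, keepdims=True), classes=(1, 2, 3))
                 for p in rng.uniform(0, 1, (4, 8, 8, 3)) + 1e-12]
        fused = fuse_memberships(stack)
        assert np.allclose(fused.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_zero_vote_survives_epsilon_floor(self):
        a = mk_member([[[1.0, 0.0]]])
        b = mk_member([[[0.0, 1.0]]])
        fused = fuse_memberships([a, b])
        assert np.all(np.isfinite(fused.probs))
        assert np.allclose(fused.probs[0, 0], [0.5, 0.5])

    def test_class_order_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_memberships([mk_member([[[0.5, 0.5]]], classes=(1, 2)),
                              mk_member([[[0.5, 0.5]]], classes=(2, 1))])

    def test_align_classes_expands_union(self):
        a = mk_member([[[0.7, 0.3]]], classes=(1, 2))
        b = mk_member([[[0.4, 0.6]]], classes=(2, 5))
        aligned = align_classes([a, b])
        assert aligned[0].classes == (1, 2, 5)
        assert np.allclose(aligned[0].probs[0, 0], [0.7, 0.3, 0.0])
        assert np.allclose(aligned[1].probs[0, 0], [0.0, 0.4, 0.6])


class TestERP:
    def test_uniform_is_lower_endpoint(self):
        for n in (2, 3, 9):
            assert compute_erp(np.full(n, 1.0 / n)) == pytest.approx(1.0 / n, abs=1e-8)

    def test_degenerate_is_one(self):
        p = np.zeros(5)
        p[0] = 1.0
        assert compute_erp(p) == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("m,n", [(0.7, 3), (0.9, 5), (0.4, 4), (0.55, 9)])
    def test_reference_shaped_recovers_maximum(self, m, n):
        p = np.full(n, (1.0 - m) / (n - 1))
        p[0] = m
        assert compute_erp(p) == pytest.approx(m, abs=1e-6)

    def test_monotone_decreasing_in_entropy(self, rng):
        n = 5
        p = rng.dirichlet(np.ones(n), size=1000)
        ent = -(np.where(p > 0, p * np.log(np.where(p > 0, p, 1)), 0)).sum(axis=1)
        erp = np.array([compute_erp(v) for v in p])
        order = np.argsort(ent)
        # ERP sorted by entropy must be non-increasing (solver tolerance)
        diffs = np.diff(erp[order])
        assert diffs.max() <= 1e-6
        assert np.all(erp >= 1.0 / n - 1e-9) and np.all(erp <= 1.0 + 1e-9)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            compute_erp(np.array([0.5, 0.2]))

    def test_erp_image_masks_nodata(self):
        m = mk_member([[[0.9, 0.1], [0.5, 0.5]]], nodata=np.array([[False, True]]))
        conf = erp_image(m)
        assert np.isfinite(conf.erp[0, 0]) and conf.erp[0, 0] > 0.5
        assert np.isnan(conf.erp[0, 1])


class TestArgmax:
    def test_picks_maximum(self):
        labels, ties = argmax_label(mk_member([[[0.1, 0.9]]], classes=(1, 2)))
        assert labels.labels[0, 0] == 2 and ties == 0

    def test_tie_goes_to_lowest_class_and_is_counted(self):
        labels, ties = argmax_label(mk_member([[[0.5, 0.5]]], classes=(4, 2)))
        assert labels.labels[0, 0] == 2 and ties == 1

    def test_nodata_propagates(self):
        m = mk_member([[[0.5, 0.5]]], nodata=np.array([[True]]))
        labels, _ = argmax_label(m, nodata=0)
        assert labels.labels[0, 0] == 0


def test_fused_map_seamless_across_strata():
    """With identical class behaviour in both strata, the fused map barely
    disagrees with either single-stratum map inside the overlap.

    The seam property presumes both stratum models are trained on the same
    class set (a model that never saw a class cannot agree on it), so the
    fixture uses three well-separated classes abundant enough to appear in
    both stratum cores, and asserts that precondition."""
    profiles = {
        1: scene_sim.ClassProfile(0.45, 0.40, 0.00, 0.50),
        3: scene_sim.ClassProfile(0.40, 0.12, 0.30, 0.40),
        6: scene_sim.ClassProfile(-0.40, 0.05, 0.0, 0.12, (0.04, 0.03), (0.02, 0.01)),
    }
    cfg = scene_sim.SceneConfig(
        width=96, height=128, n_dates=12, seed=17, stratum_count=2,
        class_profiles=profiles, class_weights={1: 0.35, 3: 0.35, 6: 0.30},
        field_size_range=(8, 16),
    )
    bundle = scene_sim.generate_scene(cfg)
    from freshmap import pipeline as pl
    from freshmap.features import extract_features
    from freshmap.sampler import harvest_training_set

    feats = extract_features(bundle.stack)
    outdated = bundle.truth  # no degradation: isolate the seam question
    members = []
    class_sets = []
    rng = np.random.default_rng(0)
    for sid, core in enumerate(pl.stratum_masks(bundle)):
        training, _ = harvest_training_set(
            feats, outdated, stratum_id=sid, stratum_mask=core,
            n_total=800, seed=int(rng.integers(0, 2**31 - 1)), som_shape=(4, 4),
        )
        model = train_stratum_rf(training, seed=sid)
        class_sets.append(set(model.classes_.tolist()))
        members.append(predict_memberships(model, feats, bundle.strata[sid], buffer=10.0))
    assert class_sets[0] == class_sets[1] == {1, 3, 6}
    aligned = align_classes(members)
    fused = fuse_memberships(aligned)
    fused_lab, _ = argmax_label(fused, legend=dict(bundle.truth.legend))
    overlap = ~aligned[0].nodata_mask & ~aligned[1].nodata_mask
    assert overlap.any()
    for m in aligned:
        single_lab, _ = argmax_label(m, legend=dict(bundle.truth.legend))
        disagree = (fused_lab.labels[overlap] != single_lab.labels[overlap]).mean()
        assert disagree < 0.02
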