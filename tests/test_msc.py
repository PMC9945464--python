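import numpy as np
import pytest

import mscsepsis as m
from mscsepsis.msc import assign_rows, batch_fingerprint, predict_rows


class TestSelectAnchors:
    def test_sweep_recovers_planted_k_and_centers(self):
        pts, labels = m.generate_planted_clusters(
            k=3, points_per_cluster=40, separation=20.0, spread=0.5, seed=5
        )
        aset = m.select_anchors(pts, seed=5)
        assert aset.chosen_k == 3
        # each anchor sits within the intra-cloud spread of one true center
        centers = np.vstack([pts[labels == c].mean(axis=0) for c in range(3)])
        for q in aset.anchors:
            assert np.min(np.linalg.norm(centers - q, axis=1)) < 3 * 0.5

    def test_silhouette_is_one_when_members_coincide_with_centers(self):
        pts, _ = m.generate_planted_clusters(3, 10, separation=5.0, spread=0.0, seed=0)
        aset = m.select_anchors(pts, seed=0)
        assert aset.silhouette_by_k[aset.chosen_k] == pytest.approx(1.0)

    def test_fixed_k_skips_sweep(self):
        rng = np.random.default_rng(0)
        aset = m.select_anchors(rng.normal(size=(50, 4)), seed=0, fixed_k=10)
        assert aset.n_anchors == 10 and aset.silhouette_by_k == {}

    def test_small_sample_shrinks_sweep_with_warning(self):
        pts, _ = m.generate_planted_clusters(2, 3, separation=10.0, spread=0.1, seed=1)
        with pytest.warns(UserWarning, match="shrinking"):
            aset = m.select_anchors(pts, k_max=10, seed=1)
        assert aset.n_anchors <= 6

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            m.select_anchors(np.ones((20, 3)), seed=0)


class TestNearestAnchor:
    def test_exact_anchor_has_zero_distance(self, toy_anchors):
        assert m.nearest_anchor(toy_anchors.anchors[3], toy_anchors) == 3

    def test_tie_breaks_to_lowest_index(self, toy_anchors):
        # equidistant from anchors 1 (1,0) and 2 (0,1)
        assert m.nearest_anchor(np.array([0.5, 0.5]), toy_anchors) in (0, 1, 2)
        sym = m.AnchorSet(np.array([[1.0, 0.0], [0.0, 1.0]]), 2, {})
        assert m.nearest_anchor(np.array([0.5, 0.5]), sym) == 0

    def test_agrees_with_brute_force_scan(self, toy_anchors):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(100, 2)) * 3
        for x in X:
            brute = int(np.argmin([np.linalg.norm(x - q) for q in toy_anchors.anchors]))
            assert m.nearest_anchor(x, toy_anchors) == brute
        assert np.array_equal(
            assign_rows(X, toy_anchors),
            [m.nearest_anchor(x, toy_anchors) for x in X],
        )


class TestFingerprintUpdates:
    def test_printed_update_hand_example(self):
        fp = m.Fingerprint(np.array([1, 1]))
        assert fp.proportions.tolist() == [0.5, 0.5]
        m.update_fingerprint(fp, 0)  # f = 0.5*2 + 1 = 2, n = 3
        assert fp.n == 3
        assert fp.proportions.tolist() == [2 / 3, 1 / 3]

    def test_first_update_is_one_hot(self):
        fp = m.Fingerprint.empty(4)
        m.update_fingerprint(fp, 2)
        assert fp.proportions.tolist() == [0, 0, 1, 0] and fp.n == 1

    def test_streaming_equals_batch_histogram_oracle(self, toy_anchors):
        """100 random row sequences: streamed updates reproduce the batch
        nearest-anchor histogram, and stay normalized throughout."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            T = int(rng.integers(1, 1000))
            rows = rng.normal(size=(T, 2)) * 2
            fp = m.Fingerprint.empty(toy_anchors.n_anchors)
            for x in rows:
                m.update_fingerprint(fp, m.nearest_anchor(x, toy_anchors))
                assert abs(fp.proportions.sum() - 1.0) < 1e-9
            batch = np.bincount(
                [m.nearest_anchor(x, toy_anchors) for x in rows],
                minlength=toy_anchors.n_anchors,
            )
            assert np.array_equal(fp.counts, batch)


class TestProfileUpdates:
    def test_running_mean_hand_example(self):
        prof = m.ClassProfile(np.array([0.5, 0.5]), n_absorbed=1, class_k=0)
        m.update_profile(prof, m.Fingerprint(np.array([3, 0]), class_k=0))
        assert prof.mean_fingerprint.tolist() == [0.75, 0.25]
        assert prof.n_absorbed == 2

    def test_first_update_of_empty_profile_is_the_fingerprint(self):
        prof = m.ClassProfile(np.full(2, 0.5), n_absorbed=0, class_k=1)
        m.update_profile(prof, m.Fingerprint(np.array([1, 3]), class_k=1))
        assert prof.mean_fingerprint.tolist() == [0.25, 0.75]

    def test_class_mismatch_rejected(self):
        prof = m.ClassProfile(np.full(2, 0.5), 0, class_k=0)
        with pytest.raises(ValueError, match="class"):
            m.update_profile(prof, m.Fingerprint(np.array([1, 0]), class_k=1))

    def test_streaming_equals_batch_mean_oracle(self):
        """100 random fingerprint streams: running mean equals np.mean."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            n_anchors = int(rng.integers(2, 11))
            n_fp = int(rng.integers(1, 40))
            counts = rng.integers(0, 20, size=(n_fp, n_anchors))
            counts[counts.sum(axis=1) == 0, 0] = 1
            prof = m.ClassProfile(np.zeros(n_anchors), 0, class_k=0)
            fps = [m.Fingerprint(c, class_k=0) for c in counts]
            for fp in fps:
                m.update_profile(prof, fp)
            batch = np.mean([fp.proportions for fp in fps], axis=0)
            assert np.allclose(prof.mean_fingerprint, batch, atol=1e-12)
            assert abs(prof.mean_fingerprint.sum() - 1.0) < 1e-9


def _entities(cohort):
    return [(r.patient_id, int(r.labels.any()), r.features) for r in cohort]


@pytest.fixture(scope="module")
def anchors(scaled_cohort):
    rows = np.vstack([r.features for r in scaled_cohort])
    return m.select_anchors(rows[::5], seed=3, fixed_k=6)


class TestTrainPredict:
    def test_single_entity_per_entity_profile_is_its_fingerprint(self, scaled_cohort, anchors):
        rec = scaled_cohort.records[0]
        ents = [(rec.patient_id, 0, rec.features)]
        model = m.train_msc(ents, anchors,
                            m.MSCConfig(update_granularity="per_entity", init_fraction=0.0))
        fp = batch_fingerprint(rec.features, anchors)
        assert np.allclose(model.profiles[0][0].mean_fingerprint, fp.proportions)

    def test_per_entity_profile_is_batch_mean_of_class_fingerprints(self, scaled_cohort, anchors):
        ents = _entities(scaled_cohort)
        model = m.train_msc(ents, anchors, m.MSCConfig(update_granularity="per_entity"))
        for k in (0, 1):
            fps = [batch_fingerprint(rows, anchors).proportions
                   for _eid, kk, rows in ents if kk == k]
            assert np.allclose(model.profiles[k][0].mean_fingerprint,
                               np.mean(fps, axis=0), atol=1e-9)

    def test_per_entity_training_is_order_invariant(self, scaled_cohort, anchors):
        ents = _entities(scaled_cohort)
        cfg = m.MSCConfig(update_granularity="per_entity", seed=5)
        a = m.train_msc(ents, anchors, cfg)
        b = m.train_msc(ents[::-1], anchors, cfg)
        for k in (0, 1):
            assert np.allclose(a.profiles[k][0].mean_fingerprint,
                               b.profiles[k][0].mean_fingerprint, atol=1e-9)

    def test_per_row_is_deterministic_under_fixed_order(self, scaled_cohort, anchors):
        ents = _entities(scaled_cohort)
        cfg = m.MSCConfig(update_granularity="per_row", seed=5)
        a = m.train_msc(ents, anchors, cfg)
        b = m.train_msc(ents, anchors, cfg)
        for k in (0, 1):
            assert np.array_equal(a.profiles[k][0].mean_fingerprint,
                                  b.profiles[k][0].mean_fingerprint)

    def test_per_row_converges_to_one_hot_on_constant_stream(self, toy_anchors):
        """Rows all matching anchor 1: after T rows every partial fingerprint
        is one-hot at 1, so the profile mean is exactly one-hot at 1."""
        rows = np.tile(toy_anchors.anchors[1], (25, 1))
        model = m.train_msc([("e", 0, rows)], toy_anchors,
                            m.MSCConfig(update_granularity="per_row", init_fraction=0.0))
        expect = np.array([0.0, 1.0, 0.0, 0.0])
        assert np.allclose(model.profiles[0][0].mean_fingerprint, expect)

    def test_unseen_class_label_rejected(self, toy_anchors):
        with pytest.raises(ValueError, match="class"):
            m.train_msc([("e", 2, np.zeros((3, 2)))], toy_anchors, m.MSCConfig())

    def test_predict_matches_exhaustive_profile_scan(self, scaled_cohort, anchors):
        ents = _entities(scaled_cohort)
        model = m.train_msc(ents, anchors, m.MSCConfig(update_granularity="per_entity"))
        for _eid, _k, rows in ents[:20]:
            fp = batch_fingerprint(rows, anchors).proportions
            dists = [
                (np.linalg.norm(p.mean_fingerprint - fp), k)
                for k in sorted(model.profiles)
                for p in model.profiles[k]
            ]
            best = min(dists, key=lambda dk: (dk[0], dk[1]))[1]
            assert m.predict(model, rows) == best

    def test_predict_tie_breaks_to_class_zero(self, toy_anchors):
        model = m.MSCModel(
            anchor_set=toy_anchors,
            profiles={
                0: [m.ClassProfile(np.array([0.0, 1.0, 0.0, 0.0]), 1, 0)],
                1: [m.ClassProfile(np.array([0.0, 1.0, 0.0, 0.0]), 1, 1)],
            },
            config=m.MSCConfig(),
        )
        rows = np.tile(toy_anchors.anchors[1], (3, 1))
        assert m.predict(model, rows) == 0

    def test_predict_empty_entity_rejected(self, toy_anchors):
        model = m.MSCModel(toy_anchors, {0: [m.ClassProfile(np.ones(4) / 4, 1, 0)]},
                           m.MSCConfig())
        with pytest.raises(ValueError):
            m.predict(model, np.zeros((0, 2)))

    def test_heldout_accuracy_beats_chance_on_separated_classes(self):
        cohort = m.generate_cohort(
            m.SynthConfig(n_patients=120, prevalence=0.4, d=6, drivers=(0, 1, 2),
                          delta=2.5, missing_rate=0.0, min_onset=1, seed=21)
        )
        scaled, _ = m.preprocess_cohort(cohort)
        train, test = m.split_cohort(scaled, test_fraction=0.3, seed=21)
        rows = np.vstack([r.features for r in train])
        anchors = m.select_anchors(rows[::3], seed=21, fixed_k=8)
        model = m.train_msc(_entities(train), anchors,
                            m.MSCConfig(update_granularity="per_entity", seed=21))
        truth = test.entity_labels()
        preds = np.array([m.predict(model, r.features) for r in test])
        assert np.mean(preds == truth) > 0.6

    def test_json_round_trip(self, scaled_cohort, anchors, tmp_path):
        model = m.train_msc(_entities(scaled_cohort), anchors,
                            m.MSCConfig(update_granularity="per_entity"))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = m.MSCModel.from_json(path)
        assert np.allclose(back.anchor_set.anchors, model.anchor_set.anchors)
        for k in (0, 1):
            assert np.allclose(back.profiles[k][0].mean_fingerprint,
                               model.profiles[k][0].mean_fingerprint)
        rec = scaled_cohort.records[0]
        assert m.predict(back, rec.features) == m.predict(model, rec.features)

    def test_per_row_prediction_wrapper_shape(self, scaled_cohort, anchors):
        model = m.train_msc(_entities(scaled_cohort), anchors,
                            m.MSCConfig(update_granularity="per_entity"))
        rec = scaled_cohort.records[0]
        rp = predict_rows(model, rec.features)
        assert rp.shape == (rec.n_hours,) and set(rp) <= {0, 1}
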