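import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import cytobench as cb
from cytobench.csi import (
    ClusterModel,
    KnownMarkerSet,
    cluster_cells,
    criterion_accuracy,
    criterion_correspondence_csi,
    criterion_robustness_csi,
    criterion_tightness,
)
from cytobench.errors import ArgumentError, EvaluationError, MetadataError
from cytobench.fcs import MergedData, SampleAnnotation, StudyKind, Technique
from cytobench.pipeline import ProcessedData


def processed_from(values, origin, sample_ids, labels, study_kind=StudyKind.CSI):
    ann = SampleAnnotation(study_kind=study_kind, entries=list(zip(sample_ids, labels)))
    values = np.asarray(values, float)
    md = MergedData(
        sample_ids=list(sample_ids),
        technique=Technique.FC,
        channels=[f"Ch{i}" for i in range(values.shape[1])],
        markers=[f"M{i}" for i in range(values.shape[1])],
        values=values,
        origin=np.asarray(origin, int),
        annotation=ann,
    )
    return ProcessedData(data=md, removed_mask=np.zeros(values.shape[0], bool), log=[])


def blobs(rng, n_per, centers, scale=1.0):
    return np.vstack([rng.normal(c, scale, size=(n_per, len(c))) for c in centers])


class TestClustering:
    def test_recovers_well_separated_blobs(self, rng):
        X = blobs(rng, 200, [(0, 0), (10, 10)])  # 10 sigma apart
        proc = processed_from(X, np.repeat([0, 1], 200), ["a", "b"], ["x", "x"])
        model = cluster_cells(proc, k=2, seed=0)
        truth = np.repeat([0, 1], 200)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_too_few_events(self, rng):
        proc = processed_from(rng.normal(size=(15, 2)), np.zeros(15), ["a", "b"], ["x", "x"])
        with pytest.raises(ArgumentError, match="10"):
            cluster_cells(proc, k=2, seed=0)

    def test_k_below_two(self, rng):
        proc = processed_from(rng.normal(size=(50, 2)), np.zeros(50), ["a", "b"], ["x", "x"])
        with pytest.raises(ArgumentError):
            cluster_cells(proc, k=1, seed=0)

    def test_seeded_determinism(self, csi_processed):
        a = cluster_cells(csi_processed, k=6, seed=3)
        b = cluster_cells(csi_processed, k=6, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAccuracy:
    def _abundance_design(self, rng, shift=True):
        # condition y doubles the first population's abundance
        samples, origin, values, labels = [], [], [], []
        for si in range(6):
            cond = "x" if si < 3 else "y"
            w0 = 0.2 if cond == "x" else 0.4
            n = 400
            pop = rng.choice(2, size=n, p=[w0, 1 - w0])
            X = np.where(pop[:, None] == 0, rng.normal(0, 1, (n, 3)), rng.normal(6, 1, (n, 3)))
            samples.append(f"s{si}")
            labels.append(cond)
            origin.append(np.full(n, si))
            values.append(X)
        return processed_from(np.vstack(values), np.concatenate(origin), samples, labels)

    def test_planted_abundance_effect_detected(self, rng):
        proc = self._abundance_design(rng)
        model = cluster_cells(proc, k=4, seed=0)
        res = criterion_accuracy(proc, model, proc.data.annotation)
        assert res.criterion == "Ca" and res.value >= 0.9

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for rep in range(10):
            proc = self._abundance_design(rng)
            perm = rng.permutation(proc.data.annotation.labels)
            while len(set(perm[:3])) == 1:  # keep both conditions in each fold
                perm = rng.permutation(perm)
            proc.data.annotation.entries = list(zip(proc.data.sample_ids, perm))
            model = cluster_cells(proc, k=4, seed=rep)
            accs.append(criterion_accuracy(proc, model, proc.data.annotation).value)
        assert 0.2 <= np.mean(accs) <= 0.8  # chance level, generous band

    def test_single_sample_condition_rejected(self, rng):
        proc = processed_from(
            rng.normal(size=(60, 2)), np.repeat([0, 1, 2], 20),
            ["a", "b", "c"], ["x", "x", "y"],
        )
        model = ClusterModel(k=2, labels=np.zeros(60, int), centroids=np.zeros((2, 2)), seed=0)
        with pytest.raises(MetadataError, match="two samples"):
            criterion_accuracy(proc, model, proc.data.annotation)


class TestTightness:
    # brute-force oracle values for A={(0,0),(0,1)}, B={(10,10),(10,11)}
    FOUR_POINT_MEAN_SIL = 0.9292895427118657

    def _four_points(self):
        X = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], float)
        return processed_from(X, [0, 0, 1, 1], ["a", "b"], ["x", "x"])

    def test_four_point_oracle(self):
        proc = self._four_points()
        model = ClusterModel(k=2, labels=np.array([0, 0, 1, 1]), centroids=np.zeros((2, 2)), seed=0)
        res = criterion_tightness(proc, model)
        assert res.value == round((self.FOUR_POINT_MEAN_SIL + 1) / 2, 3) == 0.965

    def test_anti_clustering_scores_below_half(self):
        proc = self._four_points()
        model = ClusterModel(k=2, labels=np.array([0, 1, 0, 1]), centroids=np.zeros((2, 2)), seed=0)
        assert criterion_tightness(proc, model).value < 0.5

    def test_single_cluster_undefined(self):
        proc = self._four_points()
        model = ClusterModel(k=1, labels=np.zeros(4, int), centroids=np.zeros((1, 2)), seed=0)
        with pytest.raises(EvaluationError, match="silhouette"):
            criterion_tightness(proc, model)

    def test_agrees_with_brute_force_oracle(self, rng):
        """sklearn silhouette vs an O(n^2) hand computation, <= 200 points."""
        X = rng.normal(size=(120, 3))
        labels = rng.integers(0, 3, 120)
        proc = processed_from(X, np.zeros(120), ["a", "b"], ["x", "x"])
        model = ClusterModel(k=3, labels=labels, centroids=np.zeros((3, 3)), seed=0)

        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        sils = []
        for i in range(120):
            same = labels == labels[i]
            if same.sum() == 1:
                sils.append(0.0)
                continue
            a = D[i, same].sum() / (same.sum() - 1)
            b = min(D[i, labels == c].mean() for c in set(labels) - {labels[i]})
            sils.append((b - a) / max(a, b))
        oracle = (np.mean(sils) + 1) / 2
        res = criterion_tightness(proc, model)
        assert abs(res.value - round(oracle, 3)) <= 0.001
        # unrounded agreement of the underlying statistic
        from sklearn.metrics import silhouette_score

        assert abs(silhouette_score(X, labels) - np.mean(sils)) < 1e-9


class TestRobustness:
    def test_separated_blobs_are_stable(self, rng):
        X = blobs(rng, 300, [(0, 0), (10, 10)])
        proc = processed_from(X, np.repeat([0, 1], 300), ["a", "b"], ["x", "x"])
        res = criterion_robustness_csi(proc, k=2, seed=0, reps=5)
        assert res.value >= 0.95

    def test_isotropic_noise_less_stable_than_structure(self, rng):
        """Structureless data re-clusters far less consistently than real
        clusters: the criterion separates the two regimes.  (A k=2 split of
        an isotropic cloud is itself quite reproducible - the top-variance
        hyperplane - so the contrast is assessed at larger k, where the
        partition of noise is arbitrary.)"""
        noise = rng.normal(size=(600, 5))
        proc_noise = processed_from(noise, np.repeat([0, 1], 300), ["a", "b"], ["x", "x"])
        noise_cc = criterion_robustness_csi(proc_noise, k=8, seed=0, reps=5).value

        X = blobs(rng, 300, [(0, 0, 0, 0, 0), (10, 10, 10, 10, 10)])
        proc_blobs = processed_from(X, np.repeat([0, 1], 300), ["a", "b"], ["x", "x"])
        blob_cc = criterion_robustness_csi(proc_blobs, k=2, seed=0, reps=5).value

        assert noise_cc <= 0.6
        assert blob_cc >= 0.95
        assert noise_cc < blob_cc - 0.3

    def test_single_rep_rejected(self, csi_processed):
        with pytest.raises(ArgumentError):
            criterion_robustness_csi(csi_processed, k=4, reps=1)


class TestCorrespondence:
    def test_planted_markers_fully_recovered(self, csi_processed, csi_dataset):
        res = criterion_correspondence_csi(
            csi_processed, csi_processed.data.annotation, csi_dataset.known_markers
        )
        assert res.value == 1.0

    def test_inverted_signs_score_zero(self, csi_processed, csi_dataset):
        flipped = KnownMarkerSet(
            conditions=csi_dataset.known_markers.conditions,
            entries=[(m, "down" if d == "up" else "up")
                     for m, d in csi_dataset.known_markers.entries],
        )
        res = criterion_correspondence_csi(
            csi_processed, csi_processed.data.annotation, flipped
        )
        assert res.value == 0.0

    def test_missing_marker_named(self, csi_processed):
        bad = KnownMarkerSet(conditions=("B", "A"), entries=[("CD999", "up")])
        with pytest.raises(EvaluationError, match="CD999"):
            criterion_correspondence_csi(csi_processed, csi_processed.data.annotation, bad)

    def test_empty_set_skips_criterion(self, csi_processed):
        empty = KnownMarkerSet(conditions=("B", "A"), entries=[])
        assert criterion_correspondence_csi(
            csi_processed, csi_processed.data.annotation, empty
        ) is None

    def test_known_marker_csv_round_trip(self, csi_dataset):
        km = cb.read_known_markers(csi_dataset.known_markers_path)
        assert km.conditions == csi_dataset.known_markers.conditions
        assert km.entries == csi_dataset.known_markers.entries
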