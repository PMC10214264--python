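import numpy as np
import pytest
from scipy import stats

import cytobench as cb
from cytobench.errors import ArgumentError, EvaluationError, MetadataError
from cytobench.fcs import MergedData, SampleAnnotation, StudyKind, Technique
from cytobench.pipeline import ProcessedData
from cytobench.pti import (
    PathwayHierarchy,
    Pseudotime,
    criterion_conformance,
    criterion_correspondence_pti,
    criterion_robustness_pti,
    criterion_smoothness,
    infer_trajectory,
    smoothness_pvalue,
)


def pti_processed_from(values, origin, sample_ids, timepoints):
    order = {tp: i + 1 for i, tp in enumerate(dict.fromkeys(timepoints))}
    ann = SampleAnnotation(
        study_kind=StudyKind.PTI,
        entries=list(zip(sample_ids, timepoints)),
        label_order=order,
    )
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


def latent_merged(pti_dataset, pti_merged):
    u = np.concatenate([np.array(pti_dataset.truth["latent"][s]) for s in pti_merged.sample_ids])
    return u


class TestTrajectory:
    def test_recovers_latent_time(self, pti_dataset, pti_processed, pti_merged):
        ann = pti_processed.data.annotation
        pt = infer_trajectory(pti_processed, ann, seed=0)
        u = latent_merged(pti_dataset, pti_merged)
        rho = abs(stats.spearmanr(pt.t, u).statistic)
        assert rho >= 0.9

    def test_duplicated_events_get_identical_pseudotime(self, rng):
        u = rng.uniform(0, 1, 400)
        X = np.column_stack([u + rng.normal(0, 0.05, 400) for _ in range(4)])
        X = np.vstack([X, X[:50]])  # duplicates of the first 50 events
        origin = (np.concatenate([u, u[:50]]) > 0.5).astype(int)
        proc = pti_processed_from(X, origin, ["a", "b"], ["0", "1"])
        pt = infer_trajectory(proc, proc.data.annotation, seed=0)
        np.testing.assert_array_equal(pt.t[:50], pt.t[400:])

    def test_single_timepoint_rejected(self, rng):
        with pytest.raises(MetadataError):
            SampleAnnotation(
                study_kind=StudyKind.PTI, entries=[("a", "0"), ("b", "0")],
                label_order={"0": 1},
            )
            proc = pti_processed_from(rng.normal(size=(100, 3)), np.repeat([0, 1], 50),
                                      ["a", "b"], ["0", "0"])
            infer_trajectory(proc, proc.data.annotation, seed=0)

    def test_normalized_range(self, pti_processed):
        pt = infer_trajectory(pti_processed, pti_processed.data.annotation, seed=0)
        assert pt.t.min() == 0.0 and pt.t.max() == 1.0

    def test_deterministic(self, pti_processed):
        a = infer_trajectory(pti_processed, pti_processed.data.annotation, seed=4)
        b = infer_trajectory(pti_processed, pti_processed.data.annotation, seed=4)
        np.testing.assert_array_equal(a.t, b.t)


class TestConformance:
    def _proc(self, n=2000, rng=None):
        rng = rng or np.random.default_rng(0)
        origin = np.repeat([0, 1], n // 2)
        proc = pti_processed_from(rng.normal(size=(n, 3)), origin, ["a", "b"], ["0", "1"])
        return proc

    def _pt(self, t):
        t = np.asarray(t, float)
        t = (t - t.min()) / (t.max() - t.min())
        return Pseudotime(t=t, root=0, method_seed=0)

    def test_perfect_concordance(self):
        proc = self._proc()
        ordinal = np.repeat([0.0, 1.0], 1000)
        res = criterion_conformance(self._pt(ordinal), proc, proc.data.annotation)
        assert res.value == 1.0

    def test_perfect_discordance(self):
        proc = self._proc()
        ordinal = np.repeat([1.0, 0.0], 1000)
        res = criterion_conformance(self._pt(ordinal), proc, proc.data.annotation)
        assert res.value == 0.0

    def test_random_pseudotime_near_half(self, rng):
        proc = self._proc(rng=rng)
        res = criterion_conformance(self._pt(rng.uniform(0, 1, 2000)), proc,
                                    proc.data.annotation)
        assert abs(res.value - 0.5) <= 0.05

    def test_invariant_under_monotone_transform(self, pti_processed):
        ann = pti_processed.data.annotation
        pt = infer_trajectory(pti_processed, ann, seed=0)
        warped = Pseudotime(t=pt.t ** 3, root=pt.root, method_seed=0)
        a = criterion_conformance(pt, pti_processed, ann)
        b = criterion_conformance(warped, pti_processed, ann)
        assert a.value == b.value


class TestSmoothness:
    # toy roughness table: d = (-1.0, -2.0, -1.5), t = -5.196152422706631,
    # p = Student-t CDF at t with 2 df = 0.017549359322992328 (hand value)
    TOY_P = 0.017549359322992328

    def test_hand_computed_p_value(self):
        r = np.array([0.2, 0.1, 0.3])
        naive = np.array([1.2, 2.1, 1.8])
        assert smoothness_pvalue(r, naive) == pytest.approx(self.TOY_P, abs=1e-9)

    def test_all_zero_differences_convention(self):
        r = np.array([0.4, 0.5, 0.6])
        assert smoothness_pvalue(r, r.copy()) == 0.5

    def test_monotone_ramps_score_high(self, rng):
        n = 2000
        u = np.sort(rng.uniform(0, 1, n))
        X = np.column_stack([u * (j + 1) + rng.normal(0, 0.05, n) for j in range(14)])
        proc = pti_processed_from(X, (u > 0.5).astype(int), ["a", "b"], ["0", "1"])
        pt = Pseudotime(t=(u - u.min()) / (u.max() - u.min()), root=0, method_seed=0)
        res = criterion_smoothness(pt, proc, seed=0)
        assert res.value > 0.95

    def test_adversarial_ordering_scores_low(self, rng):
        # ordering whose pseudotime bins alternate between low-u and high-u
        # groups: bin-mean profiles zigzag, far rougher than a random shuffle
        n = 1000
        u = np.sort(rng.uniform(0, 1, n))
        X = np.column_stack([u, u * 2, u * 3])
        groups = np.array_split(np.arange(n), 50)
        alternating = []
        lo, hi = 0, 49
        while lo <= hi:
            alternating.append(groups[lo])
            if hi != lo:
                alternating.append(groups[hi])
            lo, hi = lo + 1, hi - 1
        t = np.empty(n)
        t[np.concatenate(alternating)] = np.arange(n)
        proc = pti_processed_from(X, (u > 0.5).astype(int), ["a", "b"], ["0", "1"])
        pt = Pseudotime(t=(t - t.min()) / np.ptp(t), root=0, method_seed=0)
        res = criterion_smoothness(pt, proc, seed=0)
        assert res.value < 0.05

    def test_too_few_markers(self, rng):
        proc = pti_processed_from(rng.normal(size=(200, 2)), np.repeat([0, 1], 100),
                                  ["a", "b"], ["0", "1"])
        pt = Pseudotime(t=np.linspace(0, 1, 200), root=0, method_seed=0)
        with pytest.raises(ArgumentError, match="3 markers"):
            criterion_smoothness(pt, proc, seed=0)


class TestRobustnessPTI:
    def test_strong_trajectory_is_stable(self, pti_processed):
        res = criterion_robustness_pti(
            pti_processed, pti_processed.data.annotation, seed=0, reps=3
        )
        assert res.value >= 0.9

    def test_isotropic_noise_is_unstable(self, rng):
        X = rng.normal(size=(1000, 5))
        proc = pti_processed_from(X, np.repeat([0, 1], 500), ["a", "b"], ["0", "1"])
        res = criterion_robustness_pti(proc, proc.data.annotation, seed=0, reps=5)
        assert res.value <= 0.4

    def test_single_rep_rejected(self, pti_processed):
        with pytest.raises(ArgumentError):
            criterion_robustness_pti(pti_processed, pti_processed.data.annotation, reps=1)


class TestCorrespondencePTI:
    def test_planted_cascade_fully_consistent(self, pti_dataset, pti_processed, pti_merged):
        u = latent_merged(pti_dataset, pti_merged)
        pt = Pseudotime(t=(u - u.min()) / np.ptp(u), root=0, method_seed=0)
        res = criterion_correspondence_pti(pt, pti_processed, pti_dataset.hierarchy)
        assert res.value == 1.0

    def test_violation_fraction_arithmetic(self, rng):
        # construct 39 proteins in known peak order, then force 5 violations
        n = 4000
        u = np.sort(rng.uniform(0, 1, n))
        mids = np.linspace(0.1, 0.9, 39)
        X = np.column_stack([np.exp(-0.5 * ((u - m) / 0.08) ** 2) for m in mids])
        proc = pti_processed_from(X, (u > 0.5).astype(int), ["a", "b"], ["0", "1"])
        pathways = []
        prots = proc.data.markers
        # pathway layout: first pathway's key protein peaks *after* 5 of its
        # members -> exactly five violating proteins out of 39
        pathways.append([prots[5], prots[0], prots[1], prots[2], prots[3], prots[4], prots[6]])
        rest = prots[7:]
        for i in range(4):
            pathways.append(list(rest[i * 8 : (i + 1) * 8]))
        hierarchy = PathwayHierarchy(pathways=pathways)
        pt = Pseudotime(t=(u - u.min()) / np.ptp(u), root=0, method_seed=0)
        res = criterion_correspondence_pti(pt, proc, hierarchy)
        assert res.value == round(1 - 5 / 39, 3) == 0.872

    def test_missing_protein_named(self, pti_processed):
        bad = PathwayHierarchy(pathways=[["pXYZ", "P01"]])
        with pytest.raises(EvaluationError, match="pXYZ"):
            criterion_correspondence_pti(
                Pseudotime(t=np.linspace(0, 1, pti_processed.data.n_events), root=0, method_seed=0),
                pti_processed, bad,
            )

    def test_hierarchy_csv_round_trip(self, pti_dataset):
        h = cb.read_pathway_hierarchy(pti_dataset.hierarchy_path)
        assert h.pathways == pti_dataset.hierarchy.pathways
        assert len(h.pathways) == 7
        assert len(h.proteins) == 39
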