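"""Compensation, normalization, signal cleaning and workflow composition."""

import numpy as np
import pytest

import cytobench as cb
from cytobench.compensate import SpilloverMatrix, apply_compensation, estimate_spillover_from_controls
from cytobench.errors import ArgumentError, CompensationError, NormalizationError, SignalCleanError
from cytobench.fcs import MergedData, SampleAnnotation, StudyKind, Technique
from cytobench.normalize import apply_normalization
from cytobench.signal_clean import apply_signal_clean
from cytobench.synth import SyntheticSpec, generate_csi_dataset

from conftest import make_frame


def two_sample_merged(values_a, values_b, technique=Technique.FC, with_time=False, rng=None):
    ann = SampleAnnotation(study_kind=StudyKind.CSI, entries=[("a", "x"), ("a2", "x"), ("b", "y"), ("b2", "y")][:2])
    ann = SampleAnnotation(study_kind=StudyKind.CSI, entries=[("a", "x"), ("b", "x")])
    va, vb = np.asarray(values_a, float), np.asarray(values_b, float)
    p = va.shape[1]
    time = None
    if with_time:
        r = rng or np.random.default_rng(0)
        time = np.concatenate([np.sort(r.uniform(0, 100, va.shape[0])),
                               np.sort(r.uniform(0, 100, vb.shape[0]))])
    return MergedData(
        sample_ids=["a", "b"],
        technique=technique,
        channels=[f"Ch{i}" for i in range(p)],
        markers=[f"M{i}" for i in range(p)],
        values=np.vstack([va, vb]),
        origin=np.concatenate([np.zeros(va.shape[0], int), np.ones(vb.shape[0], int)]),
        annotation=ann,
        time=time,
    )


class TestCompensation:
    def test_identity_spillover_is_identity(self, rng):
        x = rng.uniform(0, 100, (50, 3))
        data = two_sample_merged(x[:25], x[25:])
        spill = SpilloverMatrix(channels=data.channels, S=np.eye(3))
        for method in ("FLC", "CTS"):
            out = apply_compensation(data, method, spill=spill)
            np.testing.assert_allclose(out.values, data.values, atol=1e-9)

    def test_exact_linear_inversion(self):
        # observed (100, 60) under S = [[1, .1], [0, 1]] came from (100, 50)
        data = two_sample_merged([[100.0, 60.0]], [[100.0, 60.0]])
        spill = SpilloverMatrix(channels=data.channels, S=np.array([[1.0, 0.1], [0.0, 1.0]]))
        out = apply_compensation(data, "FLC", spill=spill)
        np.testing.assert_allclose(out.values[0], [100.0, 50.0], atol=1e-9)

    def test_nnls_output_non_negative(self):
        data = two_sample_merged([[-5.0, 10.0]], [[-8.0, 3.0]], technique=Technique.MC)
        spill = SpilloverMatrix(channels=data.channels, S=np.array([[1.0, 0.2], [0.1, 1.0]]))
        out = apply_compensation(data, "CTS", spill=spill)
        assert np.all(out.values >= 0)

    def test_missing_spillover_is_configuration_error(self):
        data = two_sample_merged([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(CompensationError, match="spillover"):
            apply_compensation(data, "FLC")

    def test_ats_recovers_spillover_from_controls(self, rng):
        true_S = np.array([[1.0, 0.15], [0.05, 1.0]])
        controls = {}
        for i, ch in enumerate(["Ch0", "Ch1"]):
            signal = np.zeros((400, 2))
            signal[:, i] = rng.lognormal(4, 0.5, 400)
            observed = signal @ true_S + rng.normal(0, 0.5, (400, 2))
            frame = make_frame(observed)
            frame.channels = ["Ch0", "Ch1"]
            controls[ch] = frame
        est = estimate_spillover_from_controls(controls, ["Ch0", "Ch1"])
        np.testing.assert_allclose(est.S, true_S, atol=0.02)

    def test_event_count_preserved(self, rng):
        x = rng.uniform(0, 50, (40, 3))
        data = two_sample_merged(x[:20], x[20:])
        spill = SpilloverMatrix(channels=data.channels, S=np.eye(3) + np.diag([0.1, 0.1], k=1))
        assert apply_compensation(data, "MTC", spill=spill).n_events == 40


class TestNormalization:
    def test_gsn_aligns_shifted_peaks(self, rng):
        from scipy.stats import gaussian_kde

        base = rng.normal(5.0, 0.5, 4000)
        data = two_sample_merged(base[:2000, None], base[2000:, None] + 2.0)
        out = apply_normalization(data, "GSN")

        def peak(col):
            grid = np.linspace(col.min(), col.max(), 512)
            return grid[np.argmax(gaussian_kde(col)(grid))]

        peak_a = peak(out.values[out.origin == 0, 0])
        peak_b = peak(out.values[out.origin == 1, 0])
        assert abs(peak_a - peak_b) < 0.1  # kernel-bandwidth scale

    def test_wps_aligns_deciles(self, rng):
        a = rng.lognormal(2, 0.4, 3000)
        b = rng.lognormal(2, 0.4, 3000) * 1.5
        data = two_sample_merged(a[:, None], b[:, None])
        out = apply_normalization(data, "WPS")
        qa = np.quantile(out.values[out.origin == 0, 0], [0.25, 0.5, 0.75])
        qb = np.quantile(out.values[out.origin == 1, 0], [0.25, 0.5, 0.75])
        np.testing.assert_allclose(qa, qb, rtol=0.05)

    @pytest.mark.parametrize("method", ["GSN", "WPS", "FDN"])
    def test_monotone_per_sample_and_count_preserved(self, method, rng):
        a = np.sort(rng.lognormal(2, 0.5, 500))
        b = np.sort(rng.lognormal(2.2, 0.5, 500))
        data = two_sample_merged(a[:, None], b[:, None])
        out = apply_normalization(data, method)
        assert out.n_events == 1000
        for si in (0, 1):
            col = out.values[out.origin == si, 0]
            assert np.all(np.diff(col) >= -1e-9)  # inputs sorted -> outputs sorted

    def test_single_sample_rejected(self, rng):
        data = two_sample_merged(rng.uniform(0, 1, (30, 1)), rng.uniform(0, 1, (30, 1)))
        data = data.copy(sample_ids=["a"], origin=np.zeros(60, int))
        with pytest.raises(NormalizationError, match="2 samples"):
            apply_normalization(data, "GSN")

    def test_tiny_sample_passes_through_with_warning(self, rng, caplog):
        a = rng.normal(5, 1, 2000)
        b = rng.normal(8, 1, 30)  # below the density-estimation minimum
        data = two_sample_merged(a[:, None], b[:, None])
        with caplog.at_level("WARNING"):
            out = apply_normalization(data, "GSN")
        np.testing.assert_array_equal(out.values[out.origin == 1, 0], b)

    def test_non_is_identity(self, rng):
        data = two_sample_merged(rng.uniform(0, 1, (20, 2)), rng.uniform(0, 1, (20, 2)))
        np.testing.assert_array_equal(apply_normalization(data, "NON").values, data.values)


class TestSignalClean:
    @pytest.fixture(scope="class")
    @staticmethod
    def anomalous(tmp_path_factory):
        ds = generate_csi_dataset(
            SyntheticSpec(seed=7, anomaly=(0.5, 0.02, 10.0), events_per_sample=3000),
            tmp_path_factory.mktemp("anom"),
        )
        ann = cb.read_metadata(ds.metadata_path, "CSI")
        frames = [cb.read_fcs(p) for p in ds.fcs_paths]
        merged = cb.merge_samples(frames, ann, per_file_n=10**9, seed=1)
        amask = np.concatenate(
            [np.array(ds.truth["anomaly_mask"][s]) for s in merged.sample_ids]
        )
        return merged, amask

    @pytest.mark.parametrize("method", ["FAI", "FCL", "FCU"])
    def test_rate_spike_detected(self, anomalous, method):
        merged, amask = anomalous
        _, mask = apply_signal_clean(merged, method, {"bins": 100})
        assert mask[amask].mean() >= 0.90, "spike events must be flagged"
        assert mask[~amask].mean() < 0.05, "stable events must survive"

    @pytest.mark.parametrize("method", ["FAI", "FCL", "FCU"])
    def test_stable_data_mostly_retained(self, csi_merged, method):
        cleaned, mask = apply_signal_clean(csi_merged, method, {})
        assert 1.0 - mask.mean() >= 0.95

    def test_non_identity_and_all_false_mask(self, csi_merged):
        cleaned, mask = apply_signal_clean(csi_merged, "NON")
        assert not mask.any()
        np.testing.assert_array_equal(cleaned.values, csi_merged.values)

    def test_retained_events_bit_identical(self, anomalous):
        merged, _ = anomalous
        cleaned, mask = apply_signal_clean(merged, "FAI", {"bins": 100})
        np.testing.assert_array_equal(cleaned.values, merged.values[~mask])

    def test_missing_time_channel_rejected(self, csi_merged):
        data = csi_merged.copy(time=None)
        with pytest.raises(SignalCleanError, match="Time"):
            apply_signal_clean(data, "FAI")


class TestRunWorkflow:
    def test_all_non_is_identity(self, csi_merged):
        proc = cb.run_workflow(csi_merged, cb.parse_workflow("NON+NON+NON+NON"))
        np.testing.assert_array_equal(proc.data.values, csi_merged.values)
        assert not proc.removed_mask.any()

    def test_single_step_equals_direct_transform(self, csi_merged):
        from cytobench.transforms import apply_transform

        proc = cb.run_workflow(csi_merged, cb.parse_workflow("NON+LOG+NON+NON"))
        expected = apply_transform(csi_merged.values, "LOG", csi_merged.technique)
        np.testing.assert_allclose(proc.data.values, expected)

    def test_deterministic(self, csi_merged):
        spec = cb.parse_workflow("NON+ACS+GSN+FAI")
        a = cb.run_workflow(csi_merged, spec)
        b = cb.run_workflow(csi_merged, spec)
        np.testing.assert_array_equal(a.data.values, b.data.values)
        np.testing.assert_array_equal(a.removed_mask, b.removed_mask)

    def test_log_has_four_entries_in_step_order(self, csi_merged):
        proc = cb.run_workflow(csi_merged, cb.parse_workflow("NON+ACS+WPS+FAI"))
        assert [r.step for r in proc.log] == [
            "compensation", "transformation", "normalization", "signal_clean",
        ]
        assert proc.workflow == "NON+ACS+WPS+FAI"

    def test_inapplicable_workflow_rejected(self, csi_merged):
        with pytest.raises(cb.errors.CytobenchError, match="CTS"):
            cb.run_workflow(csi_merged, cb.parse_workflow("CTS+ACS+NON+NON"))

    def test_step_error_carries_context(self, csi_merged):
        constant = csi_merged.copy(values=np.ones_like(csi_merged.values))
        with pytest.raises(cb.errors.TransformError, match="transformation:BOX"):
            cb.run_workflow(constant, cb.parse_workflow("NON+BOX+NON+NON"))
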