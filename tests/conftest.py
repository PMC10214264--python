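import numpy as np
import pytest

import cytobench as cb
from cytobench.fcs import StudyKind, Technique
from cytobench.synth import SyntheticSpec, generate_csi_dataset, generate_pti_dataset


@pytest.fixture(scope="session")
def csi_dataset(tmp_path_factory):
    """Small two-condition dataset with planted markers and abundance shift."""
    out = tmp_path_factory.mktemp("csi")
    return generate_csi_dataset(SyntheticSpec(seed=3, events_per_sample=800), out)


@pytest.fixture(scope="session")
def csi_merged(csi_dataset):
    ann = cb.read_metadata(csi_dataset.metadata_path, "CSI")
    frames = [cb.read_fcs(p) for p in csi_dataset.fcs_paths]
    return cb.merge_samples(frames, ann, per_file_n=300, seed=1)


@pytest.fixture(scope="session")
def csi_processed(csi_merged):
    return cb.run_workflow(csi_merged, cb.parse_workflow("NON+ACS+NON+NON"))


@pytest.fixture(scope="session")
def pti_dataset(tmp_path_factory):
    """Four-time-point cascade dataset: 39 proteins in 7 pathways."""
    out = tmp_path_factory.mktemp("pti")
    spec = SyntheticSpec(
        study_kind=StudyKind.PTI, n_channels=39, samples_per_group=1,
        events_per_sample=500, seed=5,
    )
    return generate_pti_dataset(spec, out)


@pytest.fixture(scope="session")
def pti_merged(pti_dataset):
    ann = cb.read_metadata(pti_dataset.metadata_path, "PTI")
    frames = [cb.read_fcs(p) for p in pti_dataset.fcs_paths]
    return cb.merge_samples(frames, ann, per_file_n=10**9, seed=1)


@pytest.fixture(scope="session")
def pti_processed(pti_merged):
    return cb.run_workflow(pti_merged, cb.parse_workflow("NON+ACS+NON+NON"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_frame(values, technique=Technique.FC, sample_id="s1", with_time=False, rng=None):
    """Build an ExpressionFrame around a plain matrix."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    channels = [f"Ch{i + 1:02d}" for i in range(p)]
    markers = [f"M{i + 1:02d}" for i in range(p)]
    if with_time:
        t = np.sort((rng or np.random.default_rng(0)).uniform(0, 100, n))
        values = np.column_stack([values, t])
        channels.append("Time")
        markers.append("Time")
    return cb.ExpressionFrame(
        sample_id=sample_id, technique=technique,
        channels=channels, markers=markers, values=values,
    )
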