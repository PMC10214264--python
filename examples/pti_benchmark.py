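"""Pseudotime evaluation on a synthetic signaling time course.

The generator drives 39 proteins (7 known cascades) with sigmoid activation
pulses along a latent pseudotime, sampled at 4 collection time points.  A
workflow is scored on Conformance (pseudotime vs collection time),
Smoothness (expression profiles vs a random ordering), Robustness
(subsample stability) and Correspondence (peak-activation order vs the
known cascade hierarchy).
"""

import tempfile

import cytobench as cb
from cytobench.fcs import StudyKind
from cytobench.pti import evaluate_pti, infer_trajectory
from cytobench.synth import SyntheticSpec, generate_pti_dataset

workdir = tempfile.mkdtemp()
spec = SyntheticSpec(
    study_kind=StudyKind.PTI, n_channels=39, samples_per_group=1,
    events_per_sample=500, seed=5,
)
dataset = generate_pti_dataset(spec, workdir)
print(f"{len(dataset.hierarchy.pathways)} pathways over "
      f"{len(dataset.hierarchy.proteins)} proteins; key proteins: "
      f"{[pw[0] for pw in dataset.hierarchy.pathways]}")

annotation = cb.read_metadata(dataset.metadata_path, "PTI")
frames = [cb.read_fcs(p) for p in dataset.fcs_paths]
merged = cb.merge_samples(frames, annotation, per_file_n=500, seed=1)

for workflow in ["NON+NON+NON+NON", "NON+ACS+NON+NON", "NON+ACS+WPS+FAI"]:
    processed = cb.run_workflow(merged, cb.parse_workflow(workflow))
    results = evaluate_pti(processed, annotation, seed=0, hierarchy=dataset.hierarchy)
    line = "  ".join(f"{r.criterion}={r.value:.3f}" for r in results)
    print(f"{workflow}:  {line}")

print(
    "\nCa near 1 means the inferred pseudotime tracks collection time; "
    "Cd = 1 means every protein peaks no earlier than its cascade's key protein."
)
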