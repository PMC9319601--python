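"""The full pipeline: synthetic EEG -> scalogram images -> grid-stats
features -> entropy channel selection -> BoDF histograms -> classifiers,
with leakage-free 5-fold cross-validation, plus a permuted-label control.

Runtime: about one minute on a laptop-class CPU.
"""

from eegemo import (
    ChannelMontage,
    PipelineConfig,
    SyntheticDatasetSpec,
    generate_dataset,
    permute_labels,
    run_pipeline,
)

montage = ChannelMontage(tuple(f"ch{i:02d}" for i in range(8)), (1, 3, 4, 6))
spec = SyntheticDatasetSpec(
    n_subjects=5, n_trials_per_class=6, montage=montage, seed=0
).with_beta_contrast(3.0)

report = run_pipeline(PipelineConfig(dataset=spec, seed=0))
print("cross-validated accuracy per classifier head:")
for name, acc in sorted(report.accuracies.items()):
    print(f"  {name:22s} {acc:.3f}")
print("selected channels:", report.selected_channels)
print("vocabulary size: 3 classes x k =", report.chosen_k)

control = run_pipeline(
    PipelineConfig(dataset=permute_labels(generate_dataset(spec), seed=0), seed=0)
)
print("permuted-label control (should sit near 1/3):")
for name, acc in sorted(control.accuracies.items()):
    print(f"  {name:22s} {acc:.3f}")

# High accuracy on the structured data together with chance-level
# accuracy on permuted labels shows the pipeline reads real class
# structure, not an artifact of the evaluation protocol.
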