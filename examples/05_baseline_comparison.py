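"""Compare the CNN against LDA, SVM, and MLP on one synthetic collection.

Runs a reduced protocol (5 subjects x 5 patterns x 20 windows, a slim CNN,
15 epochs) so it finishes in about a minute; the full-scale comparison is
performed by scripts/acceptance.py.  All methods see identical per-window
standardized inputs.
"""

from respiradar import (
    ParamCombo,
    SplitSpec,
    TrainConfig,
    build_model,
    evaluate_model,
    generate_dataset,
    run_baseline,
    split_dataset,
    train,
)

windows, _ = generate_dataset(n_subjects=5, per_pattern=20, seed=9)
train_s, test_s = split_dataset(windows, SplitSpec(train_fraction=0.6, seed=9))
print(f"{len(train_s)} train / {len(test_s)} test windows")

combo = ParamCombo(conv_layers=((9, 8), (9, 16)), dense_neurons=(64, 32))
cfg = TrainConfig(epochs=15, batch_size=10, seed=9)
trained = train(build_model(combo, cfg), train_s, test_s, cfg)
reports = [evaluate_model(trained, test_s, method_name="1D CNN")]
for name in ("LDA", "SVM", "MLP"):
    reports.append(run_baseline(name, train_s, test_s, seed=9))

print("\naverage recognition rate (mean per-class recall) by method:")
for rep in reports:
    extra = f"   [{rep.details}]" if rep.details else ""
    print(f"  {rep.method_name:6s} {rep.average_rate:.3f}{extra}")
print("\nPer-class recalls for the CNN:")
print(reports[0].to_frame().to_string(index=False))
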