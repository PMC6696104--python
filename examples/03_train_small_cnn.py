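"""Train a small 1D CNN on a reduced synthetic collection (quick demo).

Uses 3 subjects x 5 patterns x 20 windows and a slimmed architecture so it
runs in well under a minute; the full study-scale run (10 subjects, the
reference depth-3 architecture, 40 epochs) is what scripts/acceptance.py
executes.
"""

from respiradar import (
    ParamCombo,
    SplitSpec,
    TrainConfig,
    build_model,
    evaluate_model,
    generate_dataset,
    split_dataset,
    train,
)

windows, meta = generate_dataset(n_subjects=3, per_pattern=20, seed=5)
train_s, test_s = split_dataset(windows, SplitSpec(train_fraction=0.6, seed=5))
print(f"{len(windows)} windows -> {len(train_s)} train / {len(test_s)} test")

combo = ParamCombo(conv_layers=((9, 8), (9, 16)), dense_neurons=(64, 32))
cfg = TrainConfig(epochs=15, batch_size=10, seed=5)
trained = train(build_model(combo, cfg), train_s, test_s, cfg)

print(trained.history[["epoch", "train_acc", "train_loss", "val_acc"]]
      .to_string(index=False))
rep = evaluate_model(trained, test_s)
print("\nconfusion matrix (rows true, columns predicted):")
print(rep.matrix.to_frame())
print(f"\naverage recognition rate (mean per-class recall): "
      f"{rep.average_rate:.3f}")
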