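"""Train the healthy-vs-ALL sigmoid head on extracted features.

Extracts features from synthetic scenes with the deterministic toy extractor
(global average pooling + one sigmoid unit on top; d+1 trainable parameters),
trains by full-batch gradient descent, and prints the best epoch chosen by
the highest-validation-accuracy / lowest-validation-loss rule.
"""

import numpy as np

from wbcseg import (
    HeadParameters,
    SmearSceneConfig,
    TrainConfig,
    count_trainable_parameters,
    generate_dataset,
    predict,
    select_best_epoch,
    toy_feature_extractor,
    train_head,
)

DEPTH = 256  # keep the demo quick; the canonical backbone depth is 2048

cfg = SmearSceneConfig(image_size=(96, 96), n_rbc=5, wbc_radius_range=(14, 18), seed=13)
scenes, manifest = generate_dataset(60, cfg, class_balance=0.5)
features = [toy_feature_extractor(s.image, depth=DEPTH, seed=0) for s in scenes]
labels = [s.label for s in scenes]

head, curve = train_head(
    features, labels, TrainConfig(epochs=300, seed=1, learning_rate=1.0)
)
best = select_best_epoch(curve)

print(f"Trainable parameters at depth {DEPTH}: {count_trainable_parameters(head)}")
print("Canonical backbone depth 2048 ->",
      count_trainable_parameters(HeadParameters(np.zeros(2048), 0.0)), "parameters")
print(f"Best epoch: {best} "
      f"(val acc {curve.val_accuracy[best - 1]:.3f}, val loss {curve.val_loss[best - 1]:.3f})")
print(f"Final training accuracy: {curve.train_accuracy[-1]:.3f}")

demo = predict(head, features[0])
print(f"\nScene 0 (true label {labels[0]}): p(healthy)={demo['probability']:.3f} "
      f"-> predicted {demo['label']}")
print("A probability over 0.5 is read as healthy; 0.5 or below as ALL.")
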