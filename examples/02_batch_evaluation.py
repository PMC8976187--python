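"""Batch-evaluate segmentation over 20 seeded scenes.

Mirrors the published evaluation protocol: segment every scene, compare each
predicted mask with its ground truth, and print the mean pixel accuracy,
structural similarity and Dice coefficient as a summary table.
"""

import numpy as np

from wbcseg import (
    SmearSceneConfig,
    evaluate_batch,
    generate_scene,
    triple_threshold_segment,
)

rng = np.random.default_rng(0)
pairs = []
for i, seed in enumerate(rng.integers(0, 2**31 - 1, size=20)):
    cfg = SmearSceneConfig(seed=int(seed), wbc_class="healthy" if i % 2 else "ALL")
    scene = generate_scene(cfg)
    pairs.append((triple_threshold_segment(scene.image), scene.wbc_mask))

result = evaluate_batch(pairs)
print(result.table())
print("\nEach row is the 20-scene mean of one segmentation metric; values "
      "close to 1 indicate near-perfect WBC recovery on synthetic smears.")
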