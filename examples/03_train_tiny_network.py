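"""Train a desk-scale variant of the segmentation network on synthetic data.

The full model carries ~1.1 M parameters (13 contracting / 15 expansive
convolutions, deep supervision with weights 0.15/0.3); this example trains
the two-level 8-channel variant for a couple of epochs — enough to watch the
deep-supervision objective fall.
"""

import numpy as np

from mito3d import (
    NetworkConfig,
    PatchSpec,
    SceneConfig,
    TrainConfig,
    build_model,
    count_parameters,
    generate_scene,
    make_training_set,
    train,
)
from mito3d.volume import LabelVolume

volume, instances, _ = generate_scene(SceneConfig(shape=(16, 64, 64), n_objects=(3, 4)), seed=11)
binary = LabelVolume((instances.data > 0).astype(np.uint8), volume.spacing, semantics="binary")

dataset = make_training_set(volume, binary, PatchSpec(shape=(8, 32, 32)), augment=True, seed=0)
model = build_model(NetworkConfig.tiny(8), seed=0)
print(f"tiny model: {count_parameters(model):,} trainable parameters")
print(f"training samples (16x augmented): {len(dataset)}")

model, history = train(
    model, dataset, TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4)
)
for epoch, loss in enumerate(history.epoch_loss):
    print(f"epoch {epoch}: mean loss {loss:.4f}")

full = build_model(NetworkConfig(), seed=0)
print(f"full model for comparison: {count_parameters(full):,} parameters, "
      f"census {full.layer_census()} (contracting, expansive)")
# The loss combines the main cross-entropy, discounted auxiliary classifier
# losses and an L2 term; it should drop steeply on this easy synthetic task.
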