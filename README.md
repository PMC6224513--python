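# mito3d

Automatic 3D mitochondria segmentation, instance reconstruction and
morphometry for serial electron-microscopy volumes.

Mitochondrial shape and distribution are tightly coupled to neuronal energy
budgets and to neurodegenerative disease, but counting and measuring
organelles in EM stacks by hand is prohibitively slow. `mito3d` implements a
complete desk-scale pipeline for doing it automatically:

1. **Pre-processing** — per-slice global histogram equalization to remove
   section-to-section brightness drift of ATUM-SEM stacks.
2. **Voxel classification** — a deeply supervised 3D residual fully
   convolutional network (a pure-numpy implementation, ~1.1 M trainable
   parameters at full size; 13 convolutions on the contracting path, 15 on
   the expansive path, summation-based skip connections, 2×2×1 anisotropic
   pooling). Training minimises

   L = CE(main) + Σ_c ω_c · CE(aux_c) + (λ/2)(‖W‖² + Σ_c‖W_c‖²)

   with auxiliary classifier weights ω = (0.15, 0.3), Adam
   (lr 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8), and the 16-element
   rotation/flip augmentation group. At test time auxiliary heads are
   discarded and whole volumes are predicted on overlapping tiles blended
   by averaging, optionally with 8- or 16-variant test-time augmentation.
3. **3D connection** — per-slice 2D components are linked across adjacent
   slices when the IoU of their xy footprints reaches T = 0.1; connected
   components of the link graph (union-find) are the mitochondrion
   instances. Instances under 1,500 voxels are discarded before detection
   scoring.
4. **Evaluation** — pixel level: Jaccard J = |X∩Y|/|X∪Y|, Dice
   2|X∩Y|/(|X|+|Y|), conformity (2J−1)/J; instance level: greedy one-to-one
   matching with a ≥ 70 % overlap criterion for a true positive, then
   precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R), with an
   overlap-threshold sweep (0.65–0.85).
5. **Morphometry** — per instance: volume (μm³), isosurface area (μm²),
   principal-axis length and width (μm), flatness √(λ₃/λ₂); per population:
   count and number density (N/μm³).

A synthetic-volume generator (dark-membraned ellipsoids and bent tubes in
textured cytoplasm, anisotropic spacing, slice jitter, noise, exact
instance ground truth and analytic geometry) makes every stage testable
without external data.

## Worked example

```python
import numpy as np
from mito3d import (SceneConfig, generate_scene, connect, match_instances,
                    detection_scores, measure_instances, summarize)

volume, labels, objects = generate_scene(SceneConfig(), seed=7)
instances = connect((labels.data > 0).astype(np.uint8))
print(instances.data.max())              # 6  — all generator objects recovered

counts = match_instances(instances, labels)
print(detection_scores(counts))          # (1.0, 1.0, 1.0) — perfect detection

records = measure_instances(labels)
extent = np.prod(np.array(labels.shape) * np.array(labels.spacing.as_tuple()) * 1e-3)
s = summarize(records, float(extent))
print(round(s.density_per_um3, 3))       # 6.104 instances per um^3
print(round(s.means["volume_um3"], 4))   # 0.0086 um^3 mean instance volume
```

The measured instance volumes agree with the generator's analytic geometry
to better than 1 %, and the detection scores confirm that IoU linking
recovers exactly the simulated instance partition.

The same stages are available from the shell:

```bash
mito3d simulate --seed 7 --out-prefix sim/
mito3d connect  --in sim/instances.h5 --out sim/linked.h5 --iou-t 0.1
mito3d evaluate --pred sim/linked.h5 --gt sim/instances.h5 --mode det
mito3d morph    --in sim/linked.h5 --spacing 30,10,10 --out sim/stats.csv
mito3d run      --config my_pipeline.yaml --seed 7   # full pipeline + manifest
```

See `examples/` for one narrative script per capability (simulation,
preprocessing, training, tiled/TTA inference, instance linking, evaluation,
morphometry).

## Limitations

Full-size benchmark accuracy on real ATUM-SEM/FIB-SEM data requires the
external volumes and GPU-scale training, which are out of scope here; the
package demonstrates the complete method at desk scale. Serial-section
registration is assumed to have been applied upstream. See
`docs/methods.md` for model details, parameter choices and numerical notes.
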