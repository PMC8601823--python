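# alrls — adaptive localizing region-based level set

Segmentation of the maxillary sinus — a dark, air-filled cavity bounded by
bright bone on CT — fails with classical active contours whenever lesions
(mucosal thickening, polyps) occlude part of the cavity: the contour stalls
on the lesion edge, a local minimum of the energy, instead of reaching the
true wall.  `alrls` implements a localizing region-based level set whose
stalled contour points are classified by a small CNN as *sinus boundary*
vs *lesion*; lesion verdicts receive a probability-weighted outward speed
compensation

    exp(|λ₁+λ₂|^(1/2)) · ((1+p₂)/(1+p₁) − 1/2)

that frees the contour from the lesion rim.  Confirmed boundary points
hold their position until convergence, and ambiguous answers
(|p₁−p₂| ≤ 0.2) are dropped.

The contour is driven by either of two localized energies evaluated in a
disk around each contour point: the uniform-modelling (Chan–Vese)
residual or the mean-separation (Yezzi) energy.  Since real sinus CT with
expert annotations is not redistributable, the package ships a synthetic
phantom generator (irregular dark cavity, bright wall, wall-attached
textured lesions, bias field, noise) with exact ground truth; every
experiment below runs on phantoms.  See `docs/methods.md` for the model,
the numerical scheme and its assumptions.

## Worked example

```python
import numpy as np
from alrls import RunConfig, SinusLevelSet
from alrls.phantom import generate_phantom, stalling_spec, GroundTruthClassifier

sample = generate_phantom(stalling_spec(seed=3))       # lesioned phantom
center = sample.cavity_centroid

fls = SinusLevelSet(sample.image, center, 7,
                    config=RunConfig(energy_model="MS")).fit()
print("FLS   Dice:", round(fls.dice(sample.cavity_mask), 3))

comp = SinusLevelSet(sample.image, center, 7,
                     config=RunConfig(energy_model="MS", compensation_enabled=True),
                     classifier=GroundTruthClassifier(sample)).fit()
print("ALRLS Dice:", round(comp.dice(sample.cavity_mask), 3))
print(comp.summary())
```

Output:

```
FLS   Dice: 0.792
ALRLS Dice: 0.939
Localizing region-based level set with CNN speed compensation
============================================================
energy model:        MS
mu, lambda1, lambda2: 0.05, 1.0, 1.0
ball radius / band:  15 / 8.0 px
iterations:          400 (converged=False, vanished=False)
foreground area:     725 px
final energy:        -33.5001
stalled points classified: 285 (compensated 84)
```

The fixed-parameter baseline (FLS) wraps around the lesions and misses
roughly a fifth of the cavity (Dice 0.79); with compensation, 84 of the
285 stalled contour points are recognised as lesion rim and pushed
through, and the contour recovers most of the occluded area (Dice 0.94).
The example uses the ground-truth oracle classifier for a quick snippet;
training the real CNN takes a few minutes, see below.

The same workflows are available from the shell:

```sh
alrls make-phantoms --n 20 --preset stalling --seed 1 --outdir cohort/
alrls train-cnn --cohort cohort/ --steps 3000 --checkpoint model
alrls segment --image cohort/phantom_000.png --center 64 64 --radius 7 \
      --energy MS --compensate --checkpoint model --out mask.png
alrls compare --cohort cohort/ --checkpoint model --outdir results/
```

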