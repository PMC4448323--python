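# pcnaphase

Automatic discrimination of cell-cycle phases — G (gap), early S, mid S and
late S — for individual nuclei in single-time-point fluorescence microscopy
images of PCNA-immunolabeled cells.

PCNA (proliferating cell nuclear antigen) is a DNA-polymerase processivity
factor whose nuclear distribution tracks replication: spread homogeneously
over the nucleus in the gap phases, condensed into many small uniform
replication foci in early S, peripheral foci in mid S, and a few large
central foci in late S. `pcnaphase` turns that visual signature into an
automated pipeline for fixed-cell (antibody-stained) images from either
confocal or widefield microscopes:

1. **Segmentation** — minimum cross-entropy (Li) thresholding: the global
   threshold *t* minimizes
   `−[m₀(t)·log μ₀(t) + m₁(t)·log μ₁(t)]`, where `m` and `μ` are the mass
   and mean intensity below/above *t*; connected components become nucleus
   candidates.
2. **Cluster splitting** — touching nuclei are separated geometrically:
   concave curvature maxima of the segment outline propose split chords,
   filtered by anti-parallel-normal, non-intersection, convexity and size
   constraints, scored by
   `J = Σᵢ (1 − |Sᵢ|/|conv Sᵢ|) + λ·Σ len(chord)/perimeter`,
   searched over n = 2, 3, … parts. A watershed-on-distance-map baseline is
   included for comparison.
3. **Features** — rotation-invariant per-nucleus descriptors built on the
   *polar image* (radius × angle resampling; rotation becomes a cyclic
   shift): basic intensity statistics + radial zone means, and 104 Haralick
   texture statistics (13 statistics × 2 polar stripes × 2 directions × 2
   pair distances) from gray-level co-occurrence matrices
   `P_{d,θ}(i,j)`. A 64-bin intensity histogram and a 64-bin
   intensity-surface-curvature histogram form the comparison set.
4. **Classification** — ID3-style information-gain decision tree (the
   recommended model), soft-margin SVMs combined by error-correcting output
   codes with Hamming decoding, and multi-class AdaBoost over stumps; all
   scikit-learn-compatible, with z-score normalization fitted on training
   folds only and seeded 10-fold cross-validation.

A synthetic-scene generator renders the four PCNA patterns, touching-nuclei
clusters, and confocal/widefield blur and noise with exact ground truth, so
every stage is testable without microscope data. Evaluation follows the
point-annotation scheme: over-segmentation = unmatched fragments / nuclei,
under-segmentation = multiply-matched segments / nuclei,
correct = 1 − over − under, plus per-class precision/recall.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Simulate a scene (20 nuclei, 5 of them in touching pairs), run the pipeline,
and score it against the generated ground truth:

```bash
pcna simulate --seed 7 --out scene/
pcna segment  --in scene/image.tif --out labels.tif
pcna split    --in labels.tif --out labels_split.tif --method geometric
pcna features --in scene/image.tif --labels labels_split.tif \
              --set proposed --out features.csv
pcna train    --features features.csv --labels train_labels.csv \
              --classifier tree --out model.bin
pcna predict  --model model.bin --features features.csv --out pred.csv
pcna evaluate --pred pred.csv --ann scene/annotations.csv \
              --labels labels_split.tif --out report/
```

The stages print:

```
wrote scene/image.tif, scene/truth_labels.tif, scene/annotations.csv, scene/spec.json
18 components -> labels.tif
20 nuclei (rejected 0 small, 0 large) -> labels_split.tif
20 nuclei x 118 features -> features.csv
trained tree on 20 nuclei -> model.bin
20 predictions -> pred.csv
```

and the report ends with

```
accuracy: 1.0000
segmentation: correct=1.0000 over=0.0000 under=0.0000
```

Reading: thresholding found 18 components because two touching pairs merged;
the geometric splitter recovered all 20 nuclei (`correct=1.0`, no over- or
under-segmentation), and the tree — here trained and applied on the same 20
nuclei, so this is a resubstitution sanity check, not a performance estimate
— reproduces every phase label. Honest performance numbers come from
cross-validation on a larger benchmark; with 400 nuclei (100 per phase,
seed 42) and 10-fold CV the decision tree on the proposed feature set
reaches ≈ 1.00 pooled accuracy on confocal renderings and ≈ 0.92 on
widefield renderings, where the dominant confusion is G ↔ early S: the
widefield blur washes the small early-S foci into a near-homogeneous
pattern.

The same pipeline is available as a library:

```python
from pcnaphase import (PipelineConfig, segment_image, split_labels,
                       compute_feature_table, cross_validate)
```

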