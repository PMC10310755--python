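# spinemorph

Quantitative 3D morphology of dendritic spines from confocal microscopy.

Dendritic spines — the micrometre-scale protrusions that carry most
excitatory synapses — are conventionally sorted by eye into mushroom, thin,
stubby and filopodia classes, a process that is slow, subjective and poorly
reproducible. `spinemorph` implements a complete computational alternative
for neuroscientists working with high-resolution confocal stacks:

1. **Segmentation.** A stack is binarized with a blended global/adaptive
   threshold, `Thres(v) = BaseThres·(1−t) + t·LocalThres(v)`, a closed
   surface mesh of the dendrite is reconstructed from oriented surface
   samples, a curve skeleton is extracted, the dendrite shaft is identified
   as the straightest of the longest skeleton paths (minimum sum of turning
   angles `α(P) = Σ angle(v_{i−1}v_i, v_i v_{i+1})`), and surface vertices
   are labeled spine/shaft with a distance-quantile `SENSITIVITY` rule.
   Each spine is cut out as a watertight mesh closed by a fan-triangulated
   base patch.
2. **Morphometry.** Eleven classic features per spine — length `L` (mean
   distance from the base centroid `c` over the farthest 5% of surface
   vertices), volume `V`, surface area `S`, convex hull volume `CHV`,
   convex hull ratio `CHR = (CHV−V)/V`, average distance `AD`, coefficient
   of variation in distance `CVD`, open angle `OA`, foot area `FA`, and the
   ratios `LVR = L/V`, `LAR = L/S`.
3. **Chord length distribution histogram (CLDH).** A shape descriptor free
   of head/neck assumptions: random surface point pairs define rays cast
   from outside the mesh; consecutive surface intersections bound interior
   chords, whose max-normalized lengths are binned into a 100-bin histogram
   (invariant to translation, rotation and scale). Histograms are compared
   with the Jensen–Shannon distance
   `JSD(P,Q) = sqrt(½ KL(P‖M) + ½ KL(Q‖M))`, `M = (P+Q)/2`, base-2 logs.
4. **Classification and clustering.** Expert vote tables are reduced to a
   consensus label (modal vote; ties → outlier); balanced datasets train
   one-vs-one SVMs with linear, RBF, histogram-intersection or Laplacian
   kernels in classic, CLDH or combined feature space. Unsupervised
   k-means/DBSCAN clustering selects the cluster number by WSS elbow,
   silhouette, or the max-class-divergence criterion: the mean pairwise
   distance between rows of the cluster-by-class distribution matrix
   `M_ij = |X_i ∩ Y_j| / |X_i|` (normalized so disjoint pure clusters
   score 1).

A first-class synthetic-data generator (`spinemorph.synthetic`) builds
archetypal spines as solids of revolution with closed-form volume and
area, composes them into ground-truthed dendrite scenes, rasterizes the
scenes into realistic anisotropic noisy stacks, and simulates expert vote
tables — so every stage of the pipeline is testable against known truth.

## Worked example

```python
import numpy as np
from spinemorph import synthetic, pipeline, features, cldh

img, truth = synthetic.recovery_benchmark(n_spines=5, seed=7)
print("stack shape:", img.shape, "voxel size (um):", img.spacing)

out = pipeline.segment_stack(img, **synthetic.BENCHMARK_ANALYSIS_PARAMS)
print(f"segmented {len(out.spines)} spines")

table = features.feature_table(out.spines)
print(table[["L", "V", "S", "CHR", "OA"]].round(3))

h = cldh.compute_cldh(out.spines[0].mesh, n_chords=30000, seed=0)
print("CLDH bins sum:", h.bins.sum(), "max chord (um): %.3f" % h.max_length)
```

prints

```
stack shape: (26, 160, 585) voxel size (um): (0.1, 0.025, 0.025)
segmented 5 spines
              L      V      S    CHR     OA
spine_id
0         1.142  0.255  2.385  0.343  0.464
1         1.073  0.198  2.066  0.390  0.486
2         1.012  0.194  1.945  0.304  0.487
3         1.252  0.373  2.992  0.267  0.473
4         1.241  0.512  3.508  0.183  0.541
CLDH bins sum: 1.0 max chord (um): 1.179
```

All five planted spines are recovered; `L` and `V` are micrometres and
cubic micrometres, `CHR ≈ 0.2–0.4` reflects the concave waist under each
mushroom head, and `OA ≈ 0.5 rad` is the mean angular spread of the spine
surface about its axis. The CLDH is a probability vector over normalized
chord lengths; its `max_length` restores the absolute scale.

A command-line interface mirrors the library
(`spinemorph segment|features|cldh|classify|cluster|simulate`); run
`spinemorph --help` for the flags.

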