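# polyclass

Classification of convex polyhedral shapes from single, incomplete
3-d reconstructions.

Cryo-electron tomography images individual macromolecular objects —
bacterial microcompartments, virus capsids — but the limited tilt range
leaves a "missing wedge": every reconstructed object is effectively cut
off by two parallel planes perpendicular to the beam axis. For objects
with convex polyhedral shape, what can be extracted is an *incomplete
polyhedral graph* (PG): observed vertices, complete edges, edges with
only one visible endpoint, and partially outlined faces. `polyclass`
identifies which convex solid an observed PG came from, using only the
combinatorial structure (which survives the affine distortions of
imaging), and quantifies how reliable that identification is.

The package provides:

* the reference library of all 123 convex regular-faced solids
  (5 Platonic, 13 Archimedean, 13 Catalan duals, 92 Johnson), with
  edges and faces derived from vertex coordinates via the convex hull;
* a missing-wedge simulator: random orientation φ = (φx, φy) ~
  U[0, 2π)², truncation by parallel planes at ±d, with the normalized
  truncation percentage p = 200(1 − d/d_max);
* the 231-dimensional **topological profile** of a PG — global counts
  (V, E, F), face-type and vertex-degree distributions of the fully
  observed features, right-censored "at least k" versions of both for
  the partially observed ones, and 10×10 edge- and face-adjacency
  matrices;
* an empirical-density **Bayes classifier**: for each reference class Θ
  the distribution of truncated profiles T is estimated by the
  empirical density p̂(T|Θ) = n⁻¹ Σᵢ I(TPᵢ = T) over n simulated
  orientations, and a PG is assigned to
  argmax_Θ p̂(T|Θ) p(Θ) / Σ_θ p̂(T|θ) p(θ) with a uniform prior over
  the 115 classes that remain after merging the 8 pairs of solids with
  identical complete profiles;
* SVM and LDA classifiers on the same profile vectors, which tolerate
  mis-specified PGs (e.g. a missed vertex) that defeat the exact-match
  Bayes rule, plus evaluation tooling (confusion matrices, per-class
  misclassification, regret vs Bayes, PPV, cross-truncation agreement);
* voxel-space morphometry: least-squares fusion of directional
  interior/exterior profiles and ellipsoid-based size/shape summaries
  (sphericities sp₂ = r₂/r₁, sp₃ = r₃/r₁).

## Worked example

```python
import numpy as np
from polyclass import (build_library, find_duplicate_profiles,
                       TruncationSampler, truncate, compute_profile,
                       TTPDensity, BayesClassifier, generate_ttps)

lib = build_library()
cmap = find_duplicate_profiles(lib)
print(len(lib), len(cmap.duplicate_pairs), cmap.n_classes)
# 123 8 115

cube = lib[1]
phi = (np.arctan2(1.0, 1.0), np.arcsin(-1.0 / np.sqrt(3.0)))  # body diagonal
pg = truncate(cube, phi, 0.6)       # planes cut one vertex at each end
prof = compute_profile(pg)
print(prof.global_block, prof.face_censored[:2])
# [ 6 12  0] [6 6]
```

The truncated cube keeps 6 of its 8 vertices; 12 edges remain visible
(6 complete, 6 clipped), no face is completely observed (F = 0), and
all six partially visible faces have at least 3 and at least 4 observed
edges (F3+ = F4+ = 6) — the censored counts carry the information that
Euler's relation can no longer provide.

Classifying simulated incomplete observations:

```python
densities = {}
for solid_id in (1, 2, 5):          # tetrahedron, cube, icosahedron
    label = cmap.class_labels[solid_id]
    ttps = generate_ttps(lib[solid_id - 1], 500, 20.0, seed=[7, solid_id])
    densities[label] = TTPDensity.estimate(ttps, label)
clf = BayesClassifier(densities)
test = generate_ttps(cube, 10, 20.0, seed=11)
print(clf.classify(test))
# [2 2 2 2 2 2 2 2 2 2]      (class 2 = the cube)
```

A command-line interface wraps the same machinery:

```sh
polyclass build-library --out manifest.json
polyclass simulate --solid all --percent 20 --n 100 --seed 1 --out ttps.csv
polyclass evaluate --percent 20 --n 1000 --nt 100 --method svm \
    --vertex-cap 20 --perturb delete-vertex --seed 1 --outdir results
polyclass fixture --solid 5 --grid 96 --percent 20 --out prof.npz
polyclass morphometry --profiles prof.npz --sigma 1.5
```

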