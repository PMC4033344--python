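# gaitdiff

Silhouette-based human gait recognition built around the **average gait
differential image (AGDI)**: a motion template that averages the
frame-to-frame differences of an aligned walking-silhouette sequence,
extracts features with **two-dimensional PCA (2DPCA)**, and identifies or
verifies subjects by nearest-neighbour matching over feature-matrix
distances.

Gait is a biometric that works at a distance and without cooperation.
Model-free approaches compress a walking sequence into a single template
image; the widely used gait energy image (GEI) averages the silhouettes
themselves, which emphasizes the static body shape. The AGDI instead
averages where consecutive silhouettes *differ*, so the template carries
the kinematics of the walk (limb swing) along the silhouette boundary —
information a shape average dilutes.

## The method

Given binary silhouettes `I_1 .. I_N`, each height-normalized (bicubic)
and aligned by its centroid `(x_c, y_c) = (Σx_i/n, Σy_i/n)` on a common
canvas:

* **Template.** `D_j(x,y) = [I_j(x,y) ≠ I_{j+1}(x,y)]` is the gait
  differential image (XOR of adjacent frames), and the AGDI is
  `G = (1/(N−1)) Σ_{j=1}^{N−1} D_j`. The GEI baseline is
  `(1/N) Σ_j I_j`.
* **Features (2DPCA).** For training templates `G_1 .. G_M` (each `m×n`)
  with mean `Ḡ`, the image covariance is the `n×n` matrix
  `C_t = Σ_i (G_i − Ḡ)ᵀ(G_i − Ḡ)`. The projection axes `W_1 .. W_d` are
  the top-d unit eigenvectors of `C_t`; a template maps to the `m×d`
  feature matrix with columns `Y_k = G W_k`. Unlike classical PCA this
  never flattens the image, so the eigenproblem is `n×n` instead of
  `mn×mn`. A rank-d reconstruction `G̃ = Σ_k Y_k W_kᵀ` is available, and
  a flattened-PCA baseline (`VectorizedPCA`) is included for comparison.
* **Matching.** Distance between feature matrices is
  `d(Y,Y') = Σ_k ‖Y_k − Y'_k‖`. Identification is nearest neighbour over
  the gallery (reported as a CMC curve); verification uses the similarity
  `Sim = −d`, z-normed per probe over the gallery, scored by FAR/FRR
  sweeps and the equal error rate (EER).

A parametric synthetic walker (ellipse torso, circle head, articulated
two-segment limbs with sinusoidal joint angles, subject-specific
proportions, stride/arm amplitudes and cycle length) generates
reproducible populations so the whole pipeline runs with no external
dataset. Real datasets in the common directory-per-sequence layout
(e.g. CASIA-B-style `subject/sequence/angle/frame.png`) load through the
same readers.

## Worked example

```python
import gaitdiff as gd

pop = gd.generate_population(10, 2, 40, seed=7)   # 10 subjects x 2 walks x 40 frames
gallery = [s for s in pop if s.sequence_id == "seq00"]
probes  = [s for s in pop if s.sequence_id == "seq01"]

rep = gd.evaluate(gallery, probes, kind="agdi", n_components=20)
print(f"rank-1 = {rep.rank1:.2f}, rank-5 = {rep.rank5:.2f}, EER = {rep.eer:.3f}")
```

prints

```
rank-1 = 1.00, rank-5 = 1.00, EER = 0.000
```

i.e. every probe walk is matched to the correct subject at the top rank
(CMC starts at 1.0), and genuine/impostor z-normed similarity scores
separate perfectly on this easy synthetic population.

The same experiment from the shell:

```sh
gaitdiff synth --subjects 5 --seqs 2 --frames 40 --seed 7 --out data
gaitdiff template --kind agdi --in data/s000/seq00 --out templates/s000.png
gaitdiff fit --templates templates --d 4 --out basis.bin
gaitdiff evaluate --gallery data --probe data --kind agdi --d 4 --report report.csv
```

The last command prints `rank-1 1.0000  rank-5 1.0000  EER 0.0000` and
writes the CMC curve and FAR/FRR sweep to `report.csv`; `fit` reports the
leading eigenvalues of the image covariance (here
`37.5 22 9.51 8.21 5.76`), whose fast decay is why a small `d` suffices.

The estimators follow the scikit-learn protocol: `TwoDPCA` /
`VectorizedPCA` are transformers over `(M, m, n)` template stacks and
`NearestTemplateClassifier` is a classifier over feature stacks, so they
compose with sklearn pipelines and model selection.

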