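# crownedge

Spectral–spatial classification of UAV hyperspectral imagery for extracting
the crowns of pest-damaged trees.

Defoliating pests such as the pine caterpillar strip conifer crowns and leave
grey, ragged canopies that must be mapped quickly over whole stands.
Pixel-wise classifiers resolve the *spectral* signal of damage well but
produce noisy label maps that ignore spatial structure: probability speckle
inside crowns, smeared class boundaries from mixed pixels, and within-crown
shadow pixels flipped to the wrong class. `crownedge` implements the
spectral–spatial remedy: classify per pixel, then regularize the per-class
probability maps with edge-preserving filters driven by a sharper
co-registered guidance image, and only then assign labels.

It is a library first (importable API plus `examples/`), with a thin
`crownedge` command-line wrapper for shell use.

## Method

1. **Pixel-wise SVM.** A one-vs-one soft-margin SVM with the Gaussian
   radial-basis kernel

   K(x_i, x) = exp(−‖x − x_i‖² / γ²),  γ > 0,

   with per-band standardization and Platt probability calibration, turns the
   B-band reflectance of every pixel into K class-membership probabilities —
   the *initial probability maps*. Penalty C and kernel width γ are chosen by
   grid search on a held-out verification split (default optimum C = 20,
   γ = 0.5).

2. **Edge-preserving filtering.** Each probability map P is smoothed while
   respecting the edges of a guidance image I (a resampled RGB frame or a
   PCA false-color composite of the cube):

   * **Joint bilateral filter (JBF):**
     Q_i = (1/K_i) Σ_j exp(−‖i−j‖/σ_d²) · exp(−|I_i−I_j|²/σ_r²) · P_j —
     a normalized convex combination whose range kernel is evaluated on the
     guidance, not on P. (The unsquared spatial distance is deliberate;
     `spatial_squared=True` gives the conventional Gaussian form.)
   * **Guided filter (GF):** per (2r+1)×(2r+1) window fit Q = a_k I + b_k by
     ridge-regularized least squares (penalty ε·a_k²), then average the
     per-window predictions.

3. **Fusion and evaluation.** Labels are the per-pixel argmax over the
   filtered stack; the damaged-pine mask and crown outlines (8-connected
   components → GeoJSON) follow. Accuracy is reported as overall accuracy
   (OA), Cohen's κ, and CADP — the producer accuracy (recall) of the
   damaged-pine class. Edge preservation of a filter setting is scored by
   MSSIM (mean structural similarity, K1 = 0.01, K2 = 0.03, 11×11 Gaussian
   windows) between the initial and the filtered probability map.

Because real UAV campaigns are rarely redistributable, the package ships a
first-class synthetic-scene generator (`crownedge.scene`) that emulates the
relevant physics: irregular class regions, smooth per-class spectra with
band-correlated noise, mixed boundary pixels (spatial blur of the cube),
within-crown shading blotches shared between cube and guidance, and a
guidance image with strictly sharper edges.

## Worked example

```python
from crownedge import (SceneSpec, make_scene, sample_points, train_svm_grbf,
                       predict_probability_stack, filter_stack, JbfParams,
                       fuse_max_probability, evaluate)

labels, cube, guidance = make_scene(SceneSpec(height=120, width=120,
                                              n_bands=20, seed=42))
samples = sample_points(labels, n_per_class=300, seed=42)
model = train_svm_grbf(cube, samples, C=20, gamma=0.5, seed=42)
stack = predict_probability_stack(model, cube)

raw = evaluate(fuse_max_probability(stack), samples, "damaged_pine")
filtered = filter_stack(stack, guidance, "jbf", JbfParams(1, 0.1))
opt = evaluate(fuse_max_probability(filtered), samples, "damaged_pine")
print(f"raw SVM: OA {raw.oa:.4f}  CADP {raw.cadp:.4f}")
print(f"JBF-optimized: OA {opt.oa:.4f}  CADP {opt.cadp:.4f}")
```

prints

```
raw SVM: OA 0.8900  CADP 0.9467
JBF-optimized: OA 0.9200  CADP 0.9467
```

i.e. filtering the probability maps with a 1-px joint bilateral kernel lifts
overall accuracy by three points on this scene by repairing mixed-boundary
and shading errors, without touching the classifier. The scripts in
`examples/` walk through each capability (scene generation, classification,
both filters and their parameter response, the full pipeline, defoliation
scoring); each prints the numbers it computes and says what they mean.

The same flow from the shell:

```bash
crownedge synth --out-dir run --seed 42
crownedge classify --cube run/cube.tif --samples run/samples.csv --out-stack run/stack.npz
crownedge filter --stack run/stack.npz --guidance run/guidance.tif --method jbf --sigma-d 1 --sigma-r 0.1 --out run/stack_jbf.npz
crownedge fuse --stack run/stack_jbf.npz --out run/labels.tif
crownedge evaluate --pred run/labels.tif --samples run/samples.csv
```

or in one step: `crownedge run --synth --out-dir run --seed 42`.

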