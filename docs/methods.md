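# Methods

## The model

`crownedge` treats damaged-crown mapping as spectral–spatial classification:
a pixel-wise probabilistic classifier followed by guidance-driven
regularization of the probability maps and a maximum-probability decision.
The underlying assumptions are (i) each land-cover class has a
characteristic reflectance spectrum, so a kernel SVM on the raw band vector
separates classes away from boundaries; (ii) classification errors
concentrate where the spectral assumption breaks — mixed pixels at object
boundaries and within-crown shading — and these places are exactly where a
sharper co-registered image (RGB or a PCA false-color composite) carries
reliable edge information; (iii) smoothing each class-probability map with
an edge-preserving filter whose weights come from that guidance transfers
the guidance's spatial structure into the decision without corrupting the
spectral evidence elsewhere.

### Classifier

One-vs-one soft-margin SVM with the Gaussian radial-basis kernel
K(x_i, x) = exp(−‖x−x_i‖²/γ²). The width convention follows the kernel as
written: larger γ = wider kernel; internally this is scikit-learn's
`gamma = 1/γ²`. Features are standardized per band using training-pixel
statistics — without this, a single γ cannot suit bands of different
dynamic range. Class probabilities come from Platt sigmoid calibration of
the binary subproblems with pairwise coupling (LibSVM's scheme). Because
coupled probabilities can disagree with the one-vs-one vote near ties, the
pipeline *defines* the hard label as the argmax of the probability stack:
the fusion stage consumes only the stack, so vote/probability discrepancies
cannot produce inconsistent maps.

Grid search scores every (C, γ) pair on the verification split by OA,
Kappa or CADP. Ties break toward smaller C, then larger γ (cheaper,
smoother models). Wall-clock fit time is recorded per row for reference but
deliberately excluded from the ranking so that identical searches are
bit-identical.

### Edge-preserving filters

Both filters use reflect (symmetric) border padding and are defined
operationally by brute-force oracles in the test suite; the shipped
implementations are accelerations, not re-definitions.

**Joint bilateral filter.** Weights are the product of a spatial kernel
exp(−‖i−j‖/σ_d²) and a range kernel exp(−|I_i−I_j|²/σ_r²) evaluated on the
guidance, normalized per pixel; the output is therefore a convex
combination of input values. Two deliberate choices: the spatial kernel's
*unsquared* distance numerator is kept as the package's primary form (a
`spatial_squared` switch provides the conventional Gaussian; both forms are
oracle-tested); and for 3-channel guidance the range distance is the
squared Euclidean norm over channels — the minimal extension of the scalar
form. Weights are truncated to a square window of half-width ceil(3·σ_d).

**Guided filter.** Per window ω_k of size (2r+1)², minimize
Σ_{i∈ω_k} ((a_k I_i + b_k − P_i)² + ε a_k²), giving
a_k = cov(I,P)/(var(I)+ε), b_k = mean(P) − a_k·mean(I); the output averages
a_k I_i + b_k over all windows containing i. Window statistics use O(1)
separable box means. The printed filter is scalar-guided, so 3-channel
guidance is reduced to Rec.601 luminance first; multi-channel guided
filtering is out of scope. ε = 0 is admitted only for the self-guidance
identity case (where a zero-variance window falls back to a_k = 0,
b_k = mean(P), which is exact there).

**Stack filtering** applies the chosen filter to each of the K maps
independently with the same guidance and parameters, clips to [0, 1] and
does *not* renormalize: the fusion argmax is invariant to per-pixel
positive rescaling, and renormalizing would distort the individual maps
users inspect. Filtered stacks carry `normalized=False`.

### Fusion, metrics, crowns, defoliation

Fusion is the per-pixel argmax with ties to the lowest class index
(deterministic). Accuracy uses the confusion matrix over verification
pixels only: OA = trace/total; κ = (p_o − p_e)/(1 − p_e) with p_e from the
marginals; CADP is the producer accuracy (recall) of the damaged-pine
class — the standard reading of "extraction accuracy" for one class.
Crown masks are `map == damaged_class`; components use 8-connectivity, so
diagonally touching crowns merge (matching how clustered crowns behave in
imagery); outlines are 0.5-level contours exported as GeoJSON in pixel
coordinates. The defoliation rate of a sampled tree is the needle-count-
weighted mean of the 0/25/50/75/100 % loss levels per branch layer,
averaged over the upper/middle/lower layers; every layer must have a
positive needle count.

### MSSIM and the edge-preservation score

`mssim` follows the standard SSIM protocol: 11×11 Gaussian windows
(σ = 1.5), population statistics, c1 = (0.01·L)², c2 = (0.03·L)², L = 1 for
[0,1] images; 3-channel inputs are reduced to luminance. The package's
*edge-preservation score* for a filter setting is MSSIM between the initial
and the filtered probability map: 1 means the filter left the map's
structure untouched, and the score falls monotonically as kernel size
(σ_d or r) or ambiguity (σ_r or ε) grows. We score against the initial map
rather than against the guidance deliberately. An SVM probability map is a
near-binary indicator; its structural similarity to a continuous guidance
image is dominated by the mean mismatch in background regions and by the
contrast imbalance at edges, and under that comparison *stronger* smoothing
can raise the similarity (noise removal shrinks the map's local contrast
toward the guidance's) — making the number useless as a measure of how much
edge structure a setting sacrifices. The initial-map comparison measures
exactly the intended quantity, and its response to the parameter grids is
monotone, which is what the parameter-selection procedure needs.
`mssim` itself is generic and accepts any two same-shaped images, so the
guidance comparison remains available.

## The synthetic scene

The generator emulates a severely defoliated pine stand seen by a
low-spatial-resolution hyperspectral sensor plus a sharper RGB camera:

| parameter | default | meaning |
|---|---|---|
| height × width | 200 × 200 px | scene size |
| n_classes | 4 | bare land, understory vegetation, shadow, damaged pine |
| n_bands | 40 | 450–950 nm, evenly sampled |
| class_separation | 0.3 | spread of class mean reflectance levels |
| noise_sigma | 0.05 | per-pixel reflectance noise (band-correlated, width 2 bands) |
| sigma_mix | 1.5 px | spatial blur of the cube → mixed boundary pixels |
| shade_amp / shade_scale | 0.6 / 2 px | within-region shading blotches toward the shadow signature |
| guidance_blur | 0.5 px | guidance edge softness (strictly < sigma_mix) |
| guidance_shift | (0, 0) | optional sub-pixel misregistration |
| region_smoothness | 6 px | random-field scale → crown-cluster-sized regions |

Class regions are quantile thresholds of a smoothed Gaussian random field
(contiguous, irregular, roughly equal-area). Class spectra are low-order
Fourier curves around offsets spread by `class_separation`; the default
separation puts the raw pixel-wise SVM near 89 % OA on verification
samples, so that boundary mixing and shading — not white noise — dominate
its errors. The shading field (positive part of a smoothed Gaussian field)
darkens both the cube spectra and the guidance colors toward the shadow
signature, emulating within-crown branch shadows and two-sided crown
illumination; because the guidance sees the same blotches, the
edge-preserving filters can both respect genuine dark structure and repair
the classifier's over-reaction to it. All randomness flows from one seed
through per-stage independent streams.

What the scene does **not** emulate: radiative transfer, 3-D canopy
structure and cast shadows (the shadow class is just a spectral class),
sensor PSF/pan-sharpening correlations, georeferencing error beyond a
rigid sub-pixel shift, and within-class spectral gradients. Green results
here demonstrate the machinery and the *direction* of the filtering
benefit at realistic error rates; they are not field-accuracy claims.

## Numerical choices

- Coordinates are 0-based (row, col), row 0 at top, half-open bounds;
  integer rasters are rescaled to [0, 1] by their dtype maximum at load,
  because σ_r and ε only make sense on normalized intensities.
- Filter oracle agreement is asserted at max|Δ| < 1e-10 on 16×16 instances;
  the guided filter's ε→∞ limit is the twice-iterated box mean (a_k → 0,
  b_k → window mean, then the window-average), asserted at 1e-6.
- Argmax ties (fusion, grid search) break deterministically as documented
  above; all stochastic steps take explicit seeds and the pipeline report
  is byte-identical across reruns with equal config and seed.
- Probability stacks assert per-pixel sums of 1 ± 1e-6 before filtering
  only.
- Degenerate inputs fail loudly: single-class training sets, non-positive
  C/γ/σ/ε, shape mismatches, zero-variance cubes for PCA, zero-count
  needle layers, NaN in stacks.

## Problem sizes

The default test and acceptance runs use 200×200 scenes with 40 bands and
5 000 samples (3:1 split) across five seeds — large enough that the SVM
operates at realistic accuracy and the filters see thousands of boundary
pixels, small enough that the whole acceptance study runs in about a
minute on one CPU. The 16×16 oracle instances are sized for exact
brute-force comparison.

## Known limitations

- The guided filter is scalar-guided (luminance); a color guided filter
  would preserve iso-luminant chroma edges that the current GF cannot see
  (the JBF does use full RGB distances).
- Platt-calibrated SVM probabilities are saturated near 0/1 on separable
  scenes; consumers needing soft uncertainty should not over-interpret the
  absolute probability values.
- Merged crown clusters are extracted as single components; individual-tree
  separation within clusters is out of scope.
- Fast-bilateral approximations are not implemented; the JBF cost grows
  with σ_d² and becomes the runtime bottleneck for σ_d ≳ 8.
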