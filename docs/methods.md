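# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `orgscape`. It is written for users who need to know what
the pipeline actually computes, what the synthetic data does and does not
emulate, and which design decisions were genuinely open.

## Spectral model and unmixing

A lambda scan acquires one image per narrow emission window. The default
geometry has 52 windows in four detector blocks — 13 windows spanning
411–481 nm (405-nm excitation), 11 spanning 494–554 nm (488 nm), 12
spanning 569–634 nm (561 nm) and 16 spanning 646–731 nm (640 nm), each with
a 10-nm bandwidth. Window centers are spaced evenly between each block's
endpoints (≈5.7–6.1 nm apart); the endpoints and window counts are the
fixed quantities, and the whole layout is configurable. The four blocks are
appended into a single 52-window series and enter one design matrix; no
per-laser weighting is applied.

Reference spectra are estimated from single-fluorophore stacks as the mean
spectrum of the brightest 1% of pixels (ranked by total counts) minus the
median spectrum of the dimmest 50% (a background estimate), clipped at zero
and normalized to unit sum. These two fractions are exposed as parameters;
they are a robust, parameter-light reading of what instrument unmixing
software does internally, not a reconstruction of any particular vendor
implementation. Whether background subtraction precedes unmixing inside
such software is unknowable from the outside; here it is an explicit,
documented step.

Unmixing is per-pixel linear least squares, unconstrained by default (the
conventional "normal unmixing" behavior), with an optional non-negativity
constraint solved by NNLS. The unconstrained solver is a single batched
`lstsq` over all pixels; a per-pixel residual-norm map is returned. A
rank-deficient reference matrix is rejected with the collinear fluorophore
pair named.

## Particle extraction

Per channel, pixel intensities are modeled as a 1-D Gaussian mixture with
unequal variances. EM is initialized at quantile-spaced means with uniform
weights, run to a mean-log-likelihood tolerance of 1e-8 (at most 500
iterations, variance floor 1e-6); the component count K is selected over
candidates {1..6} by the standard BIC (`k ln n − 2 ln L̂`, minimized). A
candidate K whose EM does not converge — typical when over-fitting a
simpler distribution — is dropped from model selection with a warning; if
no candidate converges, fitting fails loudly. Above 2×10⁵ pixels the fit
uses a seeded subsample (EM is O(n) per sweep); assignment and thresholding
remain exact for all pixels.

Pixels are assigned to the highest-responsibility component. *Crossing
points* are the intensities at which that argmax component switches; they
are computed analytically as the real roots of the pairwise log-density
equalities (each a quadratic), validated against a dense grid scan, with
ties broken toward the higher intensity. Because two Gaussians of unequal
variance cross twice, the argmax can flip again far outside the data; only
switches inside the observed intensity range are kept. The
foreground/background threshold of a channel is the **highest** crossing
point. If BIC selects K = 1 the channel has no separable foreground: it
contributes nothing to the mask (threshold +∞, logged) but is still
measured over every particle.

The particle mask is the union of the per-channel binaries, minus any
explicitly excluded channels (e.g. a marker whose foci are so numerous
they would dominate segmentation, as with RAB11 in endocytosis
experiments). Connected components use 8-connectivity (2-D), matching
common particle-analysis defaults; border-touching particles are kept by
default with a flag to drop them. Per-particle intensities are sums of
pre-binary pixel values over the particle's pixels, for **all** channels
including excluded ones; area is the pixel count. Unconstrained unmixing
can leave slightly negative abundances in dim channels; per-particle sums
are floored at zero to keep the table contract (intensities ≥ 0).

## Landscape construction

Marker sums are normalized by per-particle size factors
`s_i = total_i / geomean(totals)` (geometric mean of the factors is exactly
1 by construction), divided out and `log1p`-transformed. Particles with
all-zero markers have no defined factor and are dropped with a warning.
Note the transform is intentionally *not* invariant to a global intensity
rescaling — size factors are relative quantities and absorb per-particle
size, not acquisition gain; gain differences between replicates are handled
by the batch aligner downstream.

PCA keeps all components (the marker panels are 4–8 dimensional), then
each replicate batch's mean is subtracted in PC space. This mean-centering
is the transparent, testable core of what packaged batch aligners do; a
mutual-nearest-neighbor corrector was considered and left out because the
simulated batch effects (multiplicative gains ≤ 2×, which become additive
offsets after the log transform) are exactly the affine shifts centering
removes. UMAP embeds the aligned PCs in 2-D with n_neighbors = 15,
min_dist = 0.1, Euclidean metric and a fixed seed (single-threaded for
determinism).

Clustering is Leiden community detection (RBConfiguration quality) on the
k-nearest-neighbor graph built in the 2-D embedding, k = 60 for the
organelle landscape and k = 20 for the contact-site and endosome analyses.
The resolution parameter was chosen once so that the package's two
class-recovery simulations (seven organelle classes on 8 markers; seven
endosome states on 4 markers) are recovered as exactly seven communities,
and then frozen at 0.05; both simulations tolerate at least a factor of
two in either direction around this value. Labels are relabeled 1..P by
decreasing size. Manual cluster merging (`merge_clusters`) replaces listed
labels by group labels and leaves the rest untouched, supporting the
workflow in which several clusters dominated by one marker are grouped by
hand.

Query datasets are mapped onto a trained reference landscape by: size-factor
normalization with the query's **own** factors, projection through the
reference PCA, per-batch mean-centering of the query batches onto the
reference PC origin, and the trained UMAP transform. Cluster labels
transfer by majority vote among the 10 nearest reference particles in
embedding space (ties fall to the single nearest neighbor); the distance to
the nearest reference particle is reported so that populations absent from
the reference can be flagged (e.g. against the 99th percentile of the
reference's own nearest-neighbor distances).

## Cargo analysis

Positivity thresholds for EGF and transferrin come from particles of
untreated control cells: the threshold is the empirical 99th percentile
(linear interpolation between order statistics, the "type 7" convention —
values 1..100 give 99.01), computed per cargo channel and, in multi-batch
work, per replicate. By construction ~1% of pure background exceeds the
threshold. Positivity is evaluated on the per-particle **mean** intensity
(sum / area) by default, with a sum-based mode available; the two
conventions differ for large particles and both are explicit because the
source workflow is ambiguous between them — use the mode the control
sample was thresholded on. Particles with a zero value in any required
endosomal marker (RAB5, RAB7, RAB11) are removed regardless of cargo
signal. Filtering is idempotent. Per-cluster proportions are tallied per
(condition, timepoint, cargo); a group with zero positives is reported
with counts 0 and NaN proportions rather than dropped. Display scaling is
`sqrt(100·v/max v)` with all-zero input mapping to zero.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
optics. Particles are hard disks (radius 2–5 px) of uniform interior
intensity — the simplest shape with analytically known area and summed
intensity — placed on a jittered grid so disks can never touch. Class
profiles are log-normal: class c has mean log-abundance `base + sep·σ` on
its defining markers and `base` elsewhere (defaults base = 3.0, σ = 0.5,
sep = 4 for the 8-marker panel). Heavy-tailed positive intensities match
what particle intensity distributions look like in practice, and the
moments are closed-form. Contact-site particles carry the sum of the two
parent profiles with the minor partner scaled by an asymmetry factor
(default 0.2 — an ER fragment is much smaller than the mitochondrion it
rides on). Rendering is exactly linear in abundance: pixel spectrum =
background + Σ (abundance/area)·reference row, with optional Poisson shot
noise followed by Gaussian read noise. The direct feature-matrix path
multiplies true abundances by log-normal noise and per-batch gains with
round-robin replicate assignment, emulating pooling of three independent
experiments.

Study conditions frozen in the presets: the organelle landscape uses seven
equal-weight classes on 8 markers, n = 7,000, 4 log-sd separation, three
batches with gains up to 2×; the endosome landscape uses seven maturation
states as distinct on/off combinations of RAB5/RAB11/RAB7/LAMP1,
n = 17,000, with a higher per-marker contrast (6 log-sd) because four
markers must encode seven states and size-factor normalization removes one
effective dimension. The cargo pulse-chase advances cargo-positive
particles one route step per ~12 min — degradative cargo along early →
converting → late → lysosome, recycling cargo along early → recycling
states — on the time grid 0/5/10/15/20/30/40 min.

What the simulator does **not** model: point-spread blur, chromatic
aberration, autofluorescence, 3-D structure, touching or overlapping
particles, spatial background gradients, and fluorophore cross-excitation
outside the Gaussian emission shape. Passing the recovery tests therefore
shows the pipeline is correct on data satisfying its own assumptions; it
does not certify segmentation of confluent or blurred real images.

## Verification problem sizes and numerical notes

The test suite runs the full landscape recovery at n = 7,000 (organelles,
k = 60) and n = 6,000 (endosomes, k = 20), a ten-seed stability check at
n = 2,800, query projection against an n = 4,000 reference, and
end-to-end imaging recovery with 40 particles on a 160×160 frame across
all 52 windows; the acceptance script runs the two landscape conditions at
their full preset sizes (7,000 and 17,000). Noiseless imaging recovery is
exact to ≤1e-6 relative because every stage of the forward model is linear
and disk sums are conserved; under Poisson noise, recovered per-particle
sums are compared against the delta-method variance
`area · Σ_w B²_jw λ_w` of the linear unmixing estimator. Degenerate
inputs are handled explicitly: empty ground truth renders a flat
background; constant channels refuse GMM fitting; K = 1 channels
contribute no mask; all-zero particles drop out of normalization; all-zero
cargo vectors scale to zero.

## Known limitations

- Leiden clustering quality degrades gracefully but the *number* of
  clusters is sensitive to the kNN graph when distinct classes land
  adjacent in the 2-D layout at small n; the frozen resolution trades off
  the two preset conditions and is not a universal constant.
- The UMAP transform of query data is approximate for points far outside
  the reference manifold; such points are flagged by nearest-reference
  distance, not placed meaningfully.
- NNLS unmixing loops per pixel and is ~100× slower than the batched
  unconstrained path; use it for small fields or final quantification.
- Thresholds from the GMM depend on the fitted mixture being a reasonable
  description of the intensity histogram; heavily multi-modal signal
  populations can push the highest crossing point above dim true signal
  (this is inherent to the highest-crossing rule, not an implementation
  artifact).
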