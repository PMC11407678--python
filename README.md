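# orgscape

Multiparametric particle-based analysis of organelle landscapes.

Gentle sonication of cells releases membranous **organelle particles** that
retain the marker composition of their source compartment (ER, mitochondria,
peroxisomes, endosomes, ...). Imaging thousands of such particles with
8-color spectral (lambda-scan) microscopy and profiling each particle's
marker content turns organelle biology into a single-particle "omics"
problem: every particle is a point in marker space, and the 2-D embedding of
those points — the *organelle landscape* — separates organelle classes,
reveals rare dual-marker populations such as ER–mitochondria contact sites,
and tracks endosome maturation as cargo moves through the endocytic
pathway.

`orgscape` implements the full computational pipeline:

1. **Spectral unmixing** (`orgscape.unmixing`) — per-pixel least squares.
   A pixel's measured spectrum over the 52 emission windows is modeled as
   `y = Aᵀx`, with `A` the matrix of unit-sum fluorophore reference spectra
   (estimated from single-color stacks) and `x ≥ 0` the per-fluorophore
   abundances; `x̂ = argmin ‖y − Aᵀx‖²`, optionally non-negative.
2. **Particle extraction** (`orgscape.particles`) — per channel, pixel
   intensities are fit with 1-D Gaussian mixtures (`K` chosen by BIC,
   `BIC = k ln n − 2 ln L̂`, minimized); the threshold is the *highest
   crossing point*, i.e. the largest intensity at which the
   maximum-responsibility component switches. Channel binaries are merged
   by union (channels may be excluded), connected components are labeled
   (8-connectivity), and each particle's per-marker intensity is the sum of
   pre-binary pixel values over its pixels.
3. **Landscape** (`orgscape.landscape`) — per-particle size factors
   `s_i = total_i / geomean(totals)`, `log1p` transform, PCA, per-batch
   mean-centering of PC coordinates, 2-D UMAP, and Leiden clustering of the
   k-nearest-neighbor graph in embedding space. Query datasets are
   projected through the trained reference transforms and annotated by
   10-NN majority vote ("metric learning").
4. **Cargo kinetics** (`orgscape.cargo`) — EGF/transferrin positivity
   thresholds at the 99th percentile of untreated-control background,
   required-marker filters, per-cluster cargo proportions over the
   endocytic time course, and `sqrt(% max)` display scaling.
5. **Synthetic data** (`orgscape.simgen`) — ground-truth particles with
   class-specific log-normal marker profiles, contact-site (dual-marker)
   particles, disk rendering onto 52-window lambda stacks with Poisson and
   read noise, direct feature matrices with batch gains, and a programmed
   endocytic cargo pulse-chase. Every downstream stage is testable without
   any microscope data.

## Worked example

Simulate a 7-class organelle experiment, build the landscape, and cluster:

```python
import numpy as np
from orgscape import simgen
from orgscape.landscape import fit_landscape

cfg = simgen.seven_organelle_config(n_particles=7000, seed=0)
gt = simgen.sample_particles(cfg)
table = simgen.make_feature_matrix(
    gt, noise_sd=0.1, n_batches=3, batch_gains=np.array([1.0, 1.5, 2.0]), seed=0
)
model = fit_landscape(table, k=60, seed=0)
print("clusters:", len(np.unique(model.cluster_labels)))
```

```
clusters: 7
```

The seven communities of the embedding kNN graph correspond one-to-one to
the seven generative organelle classes (adjusted Rand index ≈ 0.97 against
the ground-truth labels): the landscape recovers the class structure from
marker profiles alone, with particles from all three simulated replicates
mixed in every cluster.

The same pipeline runs from the shell:

```sh
orgscape simulate --preset organelles --n-particles 7000 --seed 0 --out particles.csv
orgscape landscape --particles particles.csv --k 60 --seed 0 --out run/
```

which writes `particles_annotated.csv` carrying the marker intensities plus
`PCA1/PCA2`, `UMAP1/UMAP2` and `cluster` columns, one row per particle.

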