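# namdclust

Unsupervised analysis of nonadiabatic molecular-dynamics (NAMD) trajectory
ensembles.

Surface-hopping simulations of photoactive molecules produce hundreds of
trajectories, each a time series of molecular geometries annotated with
electronic properties (state energies, energy gaps ΔE, state populations,
and 0/1 flags marking the frames where a trajectory *hops* between
electronic surfaces). Buried in that high-dimensional data are a handful of
mechanistically distinct conformational families — e.g. bond-stretched
geometries funneling through a conical intersection versus rarely visited
rotated structures. `namdclust` extracts them with a pipeline of

1. **Ingestion** — discover `TRAJ<k>` directories, parse multi-frame XYZ
   geometry series and per-frame property tables, and merge them into one
   ensemble indexed by `(trajectory, time)`;
2. **Invariant descriptors** — map each geometry to a fixed-length vector
   unaffected by global rotation/translation:
   * **R2**: the strict lower triangle of the interatomic distance matrix
     D (for n atoms, n(n−1)/2 features), with variants 1/R<sub>ij</sub>,
     R<sub>ij</sub>(t) − R<sub>ij</sub>(ref), and R<sub>ij</sub>(ref)/R<sub>ij</sub>(t);
   * **Z-matrix**: internal coordinates (n−1 bonds in Å, n−2 angles and
     n−3 dihedrals in degrees, 3n−6 features), plus a delta variant
     against a reference with optional tanh/sigmoid squashing;
   * **Cremer–Pople** ring puckering: out-of-plane displacements z_j
     relative to the mean ring plane, Fourier amplitudes q_m and phases
     φ_m, total amplitude Q = √(Σ z_j²), and for six-membered rings the
     (Q, θ, φ) triple;
   * **SOAP**: the rotationally invariant power spectrum
     p(Z₁,Z₂,n,n′,l) ∝ Σ_m c^{Z₁}_{nlm} c^{Z₂}_{n′lm} of a Gaussian-smeared
     per-species neighbor density expanded in radial basis functions and
     spherical harmonics;
3. **Preprocessing** — z-score or min–max scaling (never applied to SOAP
   by default), temporal resampling by stride, and seeded random
   subsampling;
4. **Dimensionality reduction** — PCA, ISOMAP (k-NN graph → Dijkstra
   geodesics → classical MDS), and t-SNE;
5. **Clustering** — K-means, Gaussian mixtures, hierarchical agglomerative
   and spectral clustering, with an automatic choice of the cluster count
   that ranks candidate k by both the silhouette score and the
   Calinski–Harabasz index and picks the lowest summed rank;
6. **Postprocessing** — Kabsch-superposed RMSD against a reference
   geometry, hop/non-hop frame partitioning, and per-cluster
   mean/median/std summaries of any property.

A synthetic-ensemble generator (`namdclust.synthetic`) writes the same
on-disk layout from closed-form kinematic trajectories with planted
conformer classes, hop events at bond-stretch maxima, and a gap model
linear in the stretch — so the whole pipeline is testable end-to-end with
exact ground truth and no external download.

## Worked example

```python
from namdclust import (SynthConfig, simulate_ensemble, load_ensemble,
                       descriptor_dataset, resample_by_stride, kmeans,
                       cluster_statistics)
from namdclust.synthetic import ground_truth, frame_class_labels
from sklearn.metrics import adjusted_rand_score

cfg = SynthConfig.well_separated(seed=11)      # 3 planted conformer classes
root = simulate_ensemble(cfg, "ensemble")
ens = load_ensemble(root)
feats = resample_by_stride(descriptor_dataset(ens, "tanh_zmat"), 0.5)
res = kmeans(feats, 3, seed=1)
truth = ground_truth(root)
labels = frame_class_labels(feats.index, truth["class_of_traj"])
print(adjusted_rand_score(labels, res.labels))
summary = cluster_statistics(ens.properties.loc[res.keys], res.labels,
                             ["DE21", "Hops_S21", "Hops_S12"])
```

This prints (numbers from an actual run):

```
loaded 1215 frames from 15 trajectories
descriptor table: 255 frames x 30 features
k-means cluster sizes: [136, 34, 85]
silhouette = 0.748
ARI vs planted classes = 1.000
 label property     mean   median      std  count
     0     DE21 3.630072 3.627751 0.164831    136
     1     DE21 3.539684 3.511463 0.183770     34
     2     DE21 0.947898 0.934047 0.158644     85
     2 Hops_S12 0.011765 0.000000 0.107825     85
```

Reading: after resampling to a 0.5 fs stride the tanh-squashed
delta-Z-matrix descriptor separates the three planted conformer classes
perfectly (adjusted Rand index 1.0 against the generator's ground truth),
and the bond-stretched cluster (label 2) carries a mean S₀–S₁ gap of
≈0.95 eV — far below the ≈3.6 eV of the compact clusters — exactly the
small-gap, hop-rich signature expected of geometries near an intersection
seam.

The same pipeline is available from the shell:

```
namdclust simulate --out ensemble --n-trajs 15 --n-steps 80 --seed 11
namdclust run --config pipeline.cfg        # flat key = value config file
```

`namdclust --help` lists the subcommands (`ingest`, `describe`, `reduce`,
`cluster`, `stats`, `simulate`, `run`) and every config key.

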