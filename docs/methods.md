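# Methods

This note records the models, conventions and numerical choices behind
`namdclust`, and what the synthetic test data does and does not establish
about real trajectory ensembles.

## Data model

An ensemble is a set of surface-hopping trajectories, each a time series of
molecular geometries (element labels + Cartesian coordinates in Å) with a
per-frame property record: current electronic state, total energy, state
energies (passed through in their input units, typically hartree), energy
gaps in eV, 0/1 hop flags (`Hops_S21` for the excited→ground hop,
`Hops_S12` for the back hop), state populations in [0, 1], and optional
oscillator strengths. Frames are keyed by `(trajectory id, time fs)`;
geometry and property records are merged by an inner join with a 1e-6 fs
time tolerance, dropping (and counting) frames present on only one side.
All frames of an ensemble must share one atom-label sequence.

The on-disk layout is one documented plain-text convention per trajectory
directory: a concatenated XYZ series (`dyn.xyz`, comment line
`time = <float> fs`) and a `properties.csv` with canonical headers
(`traj,time,State,Total_Energy,S1,S2,…,DE21,Hops_S21,Hops_S12,Pop1,Pop2`).
Exported tables print floats with 6 decimals, so a CSV write/read round
trip is the identity to 1e-6.

## Descriptors

All descriptors are exactly invariant under global rotation and
translation; this is verified in tests to ≤1e-8 under random rigid motions.

**R2 family.** The strict lower triangle of the distance matrix, flattened
row-major ((1,0), (2,0), (2,1), …), names `R_i_j` with i > j 0-based.
Variants: `inv_r2` = 1/R, `delta_r2` = R(t) − R(ref), `re` = R(ref)/R(t).
Inverse and RE require strictly positive distances.

**Z-matrix.** Default connectivity is the sequential input-order chain
(atom i references i−1 for the bond, i−2 for the angle, i−3 for the
dihedral); a user connectivity referencing only earlier atoms is accepted.
Bonds in Å, angles/dihedrals in degrees; dihedrals use the right-handed
convention φ = atan2((n₁×n₂)·b̂₂, n₁·n₂). A NeRF-style rebuild to
Cartesians exists and round-trips to 1e-8, which is the tested definition
of consistency. Delta Z-matrices wrap angular differences to the smallest
signed value in (−180°, 180°] — without wrapping, the subsequent transforms
would be discontinuous at ±180°. The `tanh` and `sig` (logistic
1/(1+e⁻ˣ)) transforms act elementwise on the deltas with bonds in Å and
angular deltas converted to radians first, so a ±180° swing maps to ±π
rather than saturating the nonlinearity; this per-feature scaling is a
declared convention, not a fitted constant.

**Cremer–Pople.** The ring is translated to its geometric center; the mean
plane normal is n̂ = (R′×R″)/|R′×R″| with R′ = Σ rⱼ sin(2πj/N),
R″ = Σ rⱼ cos(2πj/N); out-of-plane displacements zⱼ = rⱼ·n̂ satisfy
Σzⱼ = 0 to 1e-10. Amplitudes/phases come from the discrete Fourier sums
(√(2/N) weighting for 2 ≤ m < N/2, the signed √(1/N) alternating sum for
m = N/2 when N is even); Q² = Σzⱼ². Atom 0 of the supplied ring ordering
fixes the phase origin; for even N the polar angle θ is measured from the
q_{N/2} pole (cos θ = q_{N/2}/Q). A planar ring has Q = 0 and θ, φ are then
reported as 0 (they are undefined at the pole; a constant keeps feature
tables NaN-free). For N = 6 the descriptor row is the (Q, θ, φ) triple —
the N − 3 = 3 independent coordinates.

**SOAP.** Per atomic center and chemical species, the neighbor density is
a sum of Gaussians of width σ (default 0.5 Å) over atoms within r_cut
(default 6 Å), the center itself included in its species channel. The
radial basis is the polynomial set (r_cut − r)^(n+2), n = 1…n_max
(default 8), Löwdin-orthonormalized through the analytic overlap matrix;
angular expansion uses real spherical harmonics to l_max (default 6). The
angular integral of a displaced Gaussian is evaluated analytically via the
modified-spherical-Bessel expansion, leaving one radial integral per
(n, l, neighbor) computed by 128-point Gauss–Legendre quadrature; a
brute-force 3-D quadrature oracle in the tests confirms the coefficients
to ~1e-6. The power spectrum uses the prefactor π√(8/(2l+1)) and keeps
n ≤ n′ for same-species pairs. Frame-level tables average the per-center
vectors (`aggregation="averaged"`); per-atom concatenation is retained as
an option. Note the spectrum depends on r_cut through the basis itself
(as in any cutoff-supported radial basis), so the tested locality property
is: atoms beyond r_cut leave the per-center spectrum unchanged exactly.

## Preprocessing

Z-score scaling uses the population standard deviation (ddof 0); constant
columns map to 0 (z-score) or the range midpoint (min–max) with a logged
warning, and fitted scaler parameters persist for re-application and exact
inverse transforms. SOAP tables are never scaled feature-wise by default —
the relative magnitudes across the spectral series are the signal — and
requesting it raises unless explicitly forced. Stride resampling keeps
frames whose time is an integer multiple of the stride within 1e-6 fs
(0.5 fs on 0.1 fs data keeps every fifth frame, reducing temporal
correlation); a stride below the native step returns the table unchanged
with a warning. Subsampling is uniform without replacement behind a single
required seed and preserves row order.

## Dimensionality reduction

PCA (full SVD) orders components by decreasing explained variance and
fixes each component's sign so its largest-magnitude loading is positive,
making outputs bit-stable across runs. ISOMAP builds a k-NN graph
(default 30 neighbors), symmetrizes it by union with Euclidean edge
weights, checks connectivity (a disconnected graph is an error naming the
component sizes), computes Dijkstra shortest paths, and applies classical
MDS to the double-centered squared geodesic matrix; negative eigenvalues
are clamped at zero and their total magnitude reported as a residual. With
n_neighbors = n−1 this reduces exactly to classical MDS, and on curved
1-D manifolds the embedding reproduces arc lengths within 1% (both
tested, with scikit-learn's implementation as an independent cross-check).
t-SNE is defined by contract — seeded determinism and planted-structure
recovery — delegating optimizer internals to scikit-learn; the perplexity
guard perplexity < n/3 is enforced.

## Clustering and model selection

K-means: k-means++ seeding, 10 restarts keeping lowest inertia, tolerance
1e-4, max 300 iterations. GMM: EM with full covariances, covariance
regularization 1e-6, k-means initialization; hard labels are argmax
responsibilities and the responsibility matrix is retained. Hierarchical:
scipy linkage (default Ward/Euclidean) cut at k, fully deterministic.
Spectral: RBF affinity with γ = 1/n_features, symmetric normalized
Laplacian, bottom-k eigenvectors row-normalized, K-means in the spectral
embedding; an all-zero affinity row is a numerical error. Diagnostic
traces expose the monotone objectives (Lloyd inertia non-increasing, EM
log-likelihood non-decreasing), asserted on every test fixture.

The silhouette score delegates to scikit-learn (a direct-formula oracle
covers it in tests); the Calinski–Harabasz index is computed directly as
(SSB/SSW)·(n−k)/(k−1) so that zero within-cluster dispersion can be
guarded with SSW = 1e-12 instead of returning infinity (scikit-learn is
the cross-check on generic data). The `"best"` cluster count ranks each
candidate k separately under both metrics (higher better) and returns the
k with the smallest summed rank, ties going to the smallest k — a simple,
scale-free combination chosen because the two metrics live on
incommensurable scales.

## Postprocessing

RMSD aligns by default: both geometries are centered and superposed by the
optimal proper rotation (SVD with determinant correction; reflections
disallowed), all atoms weighted equally. Aligned RMSD never exceeds
unaligned RMSD and both modes are exposed. A frame is "hopping" when
either direction flag is set; the forward/back subsets are separately
accessible. Per-cluster statistics use the population standard deviation
for consistency with the scaler, and count-weighted cluster means
reproduce the global mean to 1e-9.

## Synthetic ensembles

The generator emulates a walkthrough-scale surface-hopping set of a
fulvene-like 12-atom chromophore (a planar five-membered ring with an
exocyclic CH₂): by default 50 trajectories of 60 fs at a 0.1 fs step.
Trajectories are kinematic — closed-form harmonic modes rather than
integrated dynamics — so ground truth is exact and drift-free: a bond
stretch moves the CH₂ group along the bond axis, a torsion rotates it
about that axis, latent conformer classes add static bond/torsion offsets
per trajectory, Gaussian jitter (σ = 0.02 Å) models thermal spread, hop
flags are set where the oscillatory stretch is within δ = 0.005 Å of its
per-cycle maximum (alternating forward/back across cycles), and the gap
model gap = 3.8 eV − 4.5 eV/Å · stretch + N(0, 0.1² eV²) gives the
stretched class a distinctly small gap (≈1.0–1.6 eV depending on the
offset) against ≈3.6 eV for compact geometries — mirroring the small-gap,
hop-rich signature of intersection-seam regions.

`SynthConfig.well_separated()` is the planted-recovery condition: three
classes (compact / +0.6 Å stretched / 90° rotated, proportions
0.4/0.4/0.2) whose signatures exceed the within-class spread by far more
than five standard deviations. Under it, all four clustering algorithms
recover the classes with ARI = 1.0 and the best-k selector returns 3.

What passing these tests does **not** show: the generator has no forces,
no surface-hopping probabilities, no anharmonicity or mode coupling, and
its classes are trajectory-constant — real ensembles interconvert within a
trajectory, carry correlated noise, and rarely present 5σ-separated
families. Results on synthetic data validate the machinery (parsing,
invariances, algorithm wiring, statistics), not the chemistry of any
specific system.

## Problem sizes

Tests and the acceptance script run at reduced scale, chosen to keep exact
ground truth while exercising every code path: 5–15 trajectories of 50–150
steps (≈250–1200 frames; 255 frames after 0.5 fs resampling in the
recovery checks), SOAP at n_max = 3, l_max = 2 for the invariance sweeps,
1000 random quadruples for the internal-coordinate oracle, and 100 rigid
motions per geometry for the invariance suite.

## Known limitations

* The native upstream dynamics output dialects (binary/HDF5) are not
  parsed; the documented plain-text layout is the interface, and gradient
  tables enter through the same CSV convention.
* The six-atom "bending angle" coordinate sometimes used for large
  out-of-plane motions has no standard closed-form definition and is not
  implemented; users can augment Z-matrix tables with their own columns.
* FCHL and MBTR descriptors and DBSCAN clustering are out of scope.
* ISOMAP stores the full geodesic matrix (O(n²) memory); subsample large
  ensembles first, as the pipeline's `n_samples` key does.
* SOAP feature count grows as O(S² n_max² l_max) with S species; the
  averaged aggregation keeps frame tables manageable.
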