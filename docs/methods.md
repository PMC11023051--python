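# Methods

This note documents the models, numerical choices and limitations behind
`surfmap`. It covers the descriptor engine, the four missing-data PCA
algorithms, the map and screen-design operations, and the synthetic-data
generator used by the test suite.

## Descriptor engine

A surfactant is represented by two SMILES fragments — hydrophilic head and
hydrophobic tail. The split itself is **required input**: published maps show
exemplar splits but no general fragmentation algorithm exists, and inventing
one would silently change every downstream descriptor. Charge class
(cationic/anionic/zwitterionic/neutral) is row metadata, never computed;
charge enters the numeric table continuously through the Hirshfeld minimum
charge of the head group, which avoids artificially clustering the classes.

Computed descriptors and their definitions:

| descriptor | definition |
|---|---|
| rotatable bonds | acyclic single bonds whose two heavy atoms both have heavy-degree ≥ 2, excluding amide C–N |
| longest chain | atom count of the longest simple path in the heavy-atom graph (exhaustive DFS) |
| OH groups | oxygen atoms with ≥ 1 hydrogen after valence resolution (carboxylic O–H included) |
| C=C bonds | carbon–carbon double bonds; the cis variant counts only explicit Z stereo bonds |
| volume | van der Waals volume of the union of atomic spheres, Bondi radii, grid integration at 0.2 Å |
| surface area | solvent-accessible surface area, probe 1.4 Å, Shrake–Rupley sampling with a 960-point deterministic golden-spiral lattice per atom |

3D descriptors use a single ETKDG conformer embedded with a fixed seed
(default 1789), hydrogens included; given the seed they are exactly
reproducible. The grid and lattice resolutions keep both measures within
~1–2% of fine-resolution references at molecular sizes; both are
configurable. Semi-empirical quantum geometry optimization is deliberately
out of scope — HOMO/LUMO energies (eV), fragment dipoles (Debye), head-group
solvation free energy (kcal/mol) and Hirshfeld charges are consumed from a
CSV, and any engine that maps a fragment SMILES to a `QuantumRecord` can
supply them.

Range-valued literature descriptors (aggregation number, micelle size) are
encoded as a single midpoint column; contact angles enter as two columns
(left and right). Assembly never invents values: a computed descriptor
without fragments (or a quantum descriptor without a record) is marked
missing with a logged warning.

## Autoscaling and the variance-captured metric

Descriptors mix units (mM, mV, eV, Å³, counts), so every fit operates on the
autoscaled matrix: each column z-scored by the mean and sample standard
deviation (ddof = 1) of its *observed* entries. Zero-variance columns are
rejected by name. All methods report

R²(k) = 1 − Σ_obs (x − x̂ₖ)² / Σ_obs x²

summed over observed cells of the autoscaled matrix, cumulative in k. This
is the one metric that is comparable across all four algorithms, linear or
not. New tables are validated at load/fit time: every column needs ≥ 2
observed values and every row ≥ 1 (freshly assembled tables may be sparser;
fitting them is refused with a clear message rather than silently dropping
rows).

## The four missing-data PCA algorithms

**NIPALS.** Sequential rank-1 extraction. Each component alternates
least-squares score/loading updates with all sums restricted to observed
cells, normalizes the loading, iterates until the relative score change is
below 1e-9 (max 5000 iterations per component), then deflates observed cells
by t·pᵀ. There is no randomness anywhere, so repeated runs are bit-identical
— the property that makes NIPALS the method of choice for the final map. On
complete data it reproduces SVD-based PCA to numerical precision. Components
emerge in decreasing order of explained variance by construction.

**PPCA.** Gaussian factor model x = Wz + ε, z ~ N(0, I), ε ~ N(0, σ²I),
fitted by EM. In the E-step each row's posterior latent moments use only its
observed coordinates; the M-step solves per-feature normal equations over
the rows observing that feature. The mean vector is fixed at zero because
fits always run on the autoscaled matrix (observed-cell column means are
exactly zero); this keeps the scores·loadingsᵀ reconstruction contract
exact. Initialization is the SVD of the zero-imputed matrix — deterministic,
and on complete data already spanning the principal subspace, so the EM
refinement stays in it. Convergence: relative observed-data log-likelihood
improvement < 1e-8; a likelihood *decrease* beyond numerical slack raises an
error (EM guarantees monotonicity — a violation means a bug). With strict
tolerance on a 100 × 25 table EM may use its full iteration budget (default
1000); the model is then returned with `converged=False` and a warning,
which in practice changes the reported quantities by less than the printed
precision. Scores/loadings are reported in canonical form: SVD-rotated so
loadings are orthonormal, ordered by singular value, largest-|element|
positive.

**BPCA.** The same latent model with automatic-relevance-determination
priors: each loading column w_l has precision α_l, re-estimated as
α_l = p/‖w_l‖² each sweep, which adds σ²·diag(α) to the per-feature normal
equations and shrinks irrelevant components toward zero. Missing cells are
re-estimated from the current reconstruction every iteration; convergence is
declared when the largest imputed-cell change falls below 1e-7 (on complete
data, when the relative likelihood change does), with a 500-iteration cap.
Because the updates maximize a *penalized* objective, the raw observed-data
likelihood may dip slightly between sweeps; only gross degradation or
non-finite values raise an error. Deterministic.

**NLPCA.** Inverse-model autoassociative network: free latent scores Z
(n × k) feed one tanh hidden layer (default max(2k+2, 8) units) that
reconstructs all p descriptors; the squared error is summed over observed
cells only, and Z, weights and biases are trained jointly by full-batch
gradient descent (3000 epochs, step 0.01, halved whenever a step would
increase the loss; the step is applied to raw gradients — un-normalized —
which trains reliably at these problem sizes). Initialization draws from the
user seed, and different seeds give materially different components: the
fixture reproduces the qualitative behaviour that motivates preferring
NIPALS for a stable map even when NLPCA captures more variance at small k.
Score columns are ordered greedily by incremental linear R²; loadings are
the best least-squares linear map from the ordered scores to the data
(fitted over observed cells). `r2_cumulative[k'-1]` for k' < k uses that
linear map; the final entry uses the network reconstruction itself — the
honest figure of merit for a nonlinear method. In the rare case the trained
network underperforms its own linear map, the linear value is reported and
the network is dropped from the model so truncated reconstructions stay
nested.

**Imputation** back-transforms the model reconstruction through the stored
scaling parameters and copies observed cells from the input bit-exactly.

**Drop rule.** Rows missing strictly more than 5 cells among experimental
(literature + measured) columns are removed before the final map; a row
missing exactly 5 is retained. The rule is idempotent and reports the
removed ids.

## Map and screens

`build_map` exports the first three score columns with metadata; it is a
pure transformation. `loadings_report` ranks descriptors per PC by absolute
loading (values copied bit-exactly). Outliers are flagged when their
distance from the coordinate centroid exceeds 3 × the median distance — a
documented, rotation/translation-invariant default for what published maps
identify visually. Coordinate and loading exports use 6 significant digits,
locale-independent; descriptor-table CSVs use full precision so round trips
are bit-exact. The 3D map export is a static matplotlib scatter (PNG), as
are the three 2D projections.

*screen1* operationalizes "randomize while maximizing coverage" as greedy
maximin: starting from the origin, each step ranks unselected candidates by
their minimum Euclidean distance (unweighted, in PC1–3) to the selected set
and draws uniformly among the top-q (default 3; q = 1 is deterministic
farthest-point sampling). Distance ties break lexicographically by id, so
plans are reproducible from the seed. *screen2* returns the m (default 5)
nearest neighbours of the best hit, excluding already-screened compounds.
An R²-weighted distance variant was considered and left out of the default
path: the displayed map is unweighted, and screens should match what the
user sees.

## Synthetic data generator

The generator emulates the *structure* of the real table, not its chemistry:
values = (class-shifted latent factors) · orthonormal loadingsᵀ + Gaussian
noise. Defaults mirror the published table's shape: 100 rows × 25 columns,
rank 3, noise sd 0.1, four charge classes, 9 sparse rows missing 6
experimental cells each, and an MCAR rate chosen so exactly 263 of 2500
cells are missing (10.5%). The first 6 columns are tagged experimental
(3 literature + 3 measured) to mirror the real table's block structure for
drop-rule tests. Latent axes have distinct strengths (the class centroids,
spaced `class_shift` = 4 apart on the first axis with unit within-class
spread, then scales 2 and 1) so the planted subspace and the class clusters
are identifiable. MCAR masking blanks an exact cell count drawn without
replacement; masks are redrawn (≤ 100 attempts) if a column would drop below
2 observations, a row below 1, or a non-sparse row would reach the sparse
rows' experimental missing count — the last constraint keeps the planted
sparse-row set exactly identifiable by the drop rule.

What passing tests on this fixture do *not* show: real descriptor tables are
not exactly low-rank, their missingness is not completely at random (it
concentrates in hard-to-measure experimental properties), and class
structure in real maps emerges from the descriptors rather than being
planted. Quantities tied to a specific deposited dataset — per-method R² on
the real 100-surfactant table, the identity of specific screen-2 neighbours
— require that dataset as input; the pipeline reproduces them via
`read_descriptor_table` → `drop_sparse_rows` → `fit_table` → `build_map` →
`select_screen2` when the user supplies it.

## Problem sizes and determinism

Tests and the acceptance script run at the fixture's native 100 × 25 scale;
oracle comparisons use complete matrices up to 50 × 20, and screen-coverage
baselines use 200 maps of 60 points against 1000 random subsets each.
NIPALS, PPCA and BPCA are run-to-run deterministic; NLPCA and top-q
randomized screens are deterministic given their seed. All seeds are
explicit parameters.

## Known limitations

- No automatic fragment splitting, no quantum chemistry, no HLB estimation
  from structure (HLB is curated input).
- NLPCA runs are not averaged (averaging smears the map), and no
  cross-validated choice of k is provided.
- The outlier rule and the maximin operationalization of "coverage" are
  documented defaults, not fitted to any reference output.
- `drop_sparse_rows` assumes column provenance (literature/measured/
  computed) is available; CSVs written by this package carry it in a
  companion `.columns.json`, and foreign tables fall back to name matching
  against the default descriptor specs.
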