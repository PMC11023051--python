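# surfmap

Principal-component **surfactant maps** from incomplete descriptor tables.

Surfactant-enabled organic reactions in water are a cornerstone of green
chemistry, but picking the right surfactant from hundreds of commercial
candidates is mostly trial and error. `surfmap` implements a data-driven
alternative: represent every surfactant by a vector of physicochemical
descriptors, embed all of them in a low-dimensional principal-component
space, and screen the compounds that *cover* that space instead of screening
blindly. Its intended users are synthetic and process chemists optimizing
micellar/emulsion reactions, and cheminformaticians building similar
chemical-space maps.

The pipeline has four stages:

1. **Descriptor table.** Each surfactant is split into a hydrophilic and a
   hydrophobic fragment (SMILES). Computed descriptors — rotatable bonds,
   longest heavy-atom chain, OH count, cis C=C count, van der Waals volume,
   solvent-accessible surface area — are derived per fragment; quantum
   descriptors (HOMO/LUMO, dipoles, ΔG_solv, the most negative Hirshfeld
   charge of the head group) are consumed from an external CSV; curated
   micellar properties (CMC, aggregation number, micelle size) and measured
   emulsion properties (contact angles, zeta potential, HLB) complete the
   table. Experimental columns carry missing values.
2. **Missing-data PCA.** Four algorithms share one contract on the
   autoscaled matrix **X** (column z-scores over observed cells):
   *NIPALS* (regressions skip missing cells; deterministic), *PPCA*
   (x = Wz + ε, EM with missing coordinates integrated out), *BPCA*
   (PPCA with automatic-relevance priors on loading columns) and *NLPCA*
   (autoassociative network with free latent scores; seed-dependent).
   Fits report cumulative variance captured
   R²(k) = 1 − Σ_obs(x − x̂ₖ)² / Σ_obs x², and models impute missing cells.
   Surfactants missing more than 5 experimental descriptors are dropped
   before the final map (the published table goes 100 → 91 rows this way).
3. **Map.** The first three PCs place every surfactant in 3D; loadings
   rankings explain each axis; distance-based outlier flagging and 2D/3D
   plots are included.
4. **Screens.** *screen1* picks n ≈ 8–10 surfactants by greedy maximin
   (farthest-point) selection from an origin compound, optionally randomized
   among the top-q candidates per step; *screen2* returns the m ≈ 5 nearest
   neighbours of the best stage-1 hit.

## Worked example

A synthetic table with the published table's shape (100 surfactants × 25
descriptors, 10.5% missing, 9 rows with concentrated experimental
missingness) exercises the whole pipeline:

```console
$ surfmap simulate --seed 11 --out-table table.csv
wrote 100×25 table (10.52% missing) to table.csv

$ surfmap fit --table table.csv --method nipals -k 3 --drop-sparse 5 --out-model model.json
nipals k=3: cumulative R² [0.5183, 0.8284, 0.9572] -> model.json

$ surfmap map --model model.json --table table.csv --drop-sparse 5 \
    --out-coords coords.csv --out-loadings loadings.csv
wrote coordinates for 91 surfactants

$ surfmap screen1 --coords coords.csv --n 8 --origin S001 --seed 11 --out screen1.csv
screen1 (8 surfactants from S001): S001, S044, S032, S010, S027, S061, S028, S099

$ surfmap screen2 --coords coords.csv --best S014 --m 5 --out screen2.csv
screen2 around S014: S054, S058, S070, S006, S042
```

Reading the output: the drop rule removed the 9 sparse rows (91 remain); the
three NIPALS components capture 52%, 83% and 96% of the observed variance —
consistent with the planted rank-3 structure; `screen1` lists eight
surfactants spread across the map starting from the origin `S001`, and
`screen2` lists the five compounds closest to the hypothetical best hit
`S014`. `loadings.csv` ranks descriptors per PC by absolute loading, which is
how the map's axes are interpreted (on real data, e.g. a charge-dominated
PC3 ranks zeta potential, ΔG_solv and the Hirshfeld minimum charge on top).

The same operations are available as library functions
(`surfmap.generate_table`, `surfmap.fit_table`, `surfmap.build_map`,
`surfmap.select_screen1`, …). To map a real dataset, supply the fragment,
curated and quantum CSVs to `surfmap build-table` (see
`docs/methods.md` for formats), or load a deposited descriptor table
directly with `surfmap.read_descriptor_table` (a `--rename-map` /
`rename_map` option aligns foreign column headers).

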