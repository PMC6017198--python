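# Methods

## The model

`rigiddg` predicts the change in a protein's free energy of unfolding
(ΔΔG, kcal/mol) caused by one or two point mutations, using only structural
features — no energy terms. The core assumption is that a mutation's
thermodynamic effect correlates with how it reshapes the protein's *rigidity*:
a mutation that erodes the largest rigid cluster is more destabilizing than
one that only rearranges small clusters.

### Mutation model

A mutation to glycine is generated by side-chain truncation: all atoms of
the residue other than N, CA, C, O (and backbone hydrogens, which are kept)
are deleted and the residue is renamed GLY. This removes exactly the
stabilizing interactions the side chain participated in. Truncation is
idempotent and leaves the input structure untouched. Non-glycine targets
need rotamer placement, which is out of scope; a shell-command hook
(`mutate(..., external_cmd=...)`) lets users plug in an external placement
and minimization tool. Alternate locations keep the highest-occupancy
conformer; multi-model files default to the first model.

### Rigidity analysis

The molecule is a body-bar framework: each atom is a 6-degree-of-freedom
rigid body, and each interaction a bundle of bars, every bar removing one
relative degree of freedom:

| interaction | bars | detection |
|---|---|---|
| rotatable covalent bond | 5 | residue topology tables + nearest-heavy-atom H attachment |
| resonant / partial-double bond (peptide C–N, carbonyl, carboxylate, amide, guanidinium, aromatic rings) | 6 | topology tables |
| disulfide | 5 | SG–SG ≤ 2.5 Å |
| hydrogen bond | 5 | donor–acceptor ≤ 3.6 Å and donor–H–acceptor angle ≥ 100° |
| hydrophobic tether | 2 | side-chain C/S pairs of hydrophobic/aromatic residues within vdW sum + 0.25 Å |

All thresholds and bar counts live in `RigidityParams` and are overridable;
the defaults are the conventional values for molecular body-bar frameworks,
not measurements. Hydrogen-bond detection requires an explicit donor
hydrogen by default (the angle criterion needs it); for heavy-atom-only
structures `hbond_require_hydrogen=False` falls back to a distance-only
rule.

Rigid clusters come from the (6,6) pebble game: every body holds 6 pebbles;
a bar is independent iff 7 pebbles can be gathered on its endpoints, in
which case it pins one. After all bars are played, two adjacent bodies are
mutually rigid iff a further bar between them would be redundant (no 7
pebbles can be gathered); clusters are the transitive closure of that
relation, and cluster *size* is counted in atoms. Pebble searches use
lowest-index-first DFS, so the decomposition is deterministic, and because
independence is a matroid property it is invariant to edge order.

`rigidity_rank_oracle` is a test-scale cross-check: it builds the generic
body-bar rigidity matrix from random bar placements, takes the null space,
and calls two bodies mutually rigid when every null motion assigns them
identical rigid-body velocities. The suite verifies pebble game ≡ oracle on
30 random graphs plus crafted cases (6-bar fusion, 5-bar hinge, hinge
rings). The oracle retries with fresh placements until two independent
draws agree, guarding against degenerate randomness.

### Rigidity Distance

RD(WT, Mut) = Σᵢ i · w(i) · (WTᵢ − Mutᵢ), summed to the wild-type LRC
(extended to the mutant LRC when the mutant grew, which is logged).
Weightings:

- `dm` — w ≡ 1. Implemented for completeness; not used as a default
  feature.
- `lm` — w(i) = (i − s_min)/(s_max − s_min) with s_min/s_max the wild
  type's smallest/largest cluster sizes (w ≡ 1 when degenerate). For a wild
  type with clusters {4, 4, 22} the ramp has rise 1 and run 18.
- `sm` — w(i) = 1/(1 + e^{−k(i−x₀)}); weights below 10⁻³ are truncated to
  exactly 0 so that sub-threshold clusters contribute nothing. Presets:
  `sm1` (k = 20, x₀ = 10.5) is a near-step that zeroes clusters of ≤ 10
  atoms and weights ≥ 11 atoms by ≈ 1 — k = 20 is the package's choice to
  realize that step sharply (weight 4.5·10⁻⁵ at size 10, under the
  truncation; a shallower slope such as k = 10 would leave 6.7·10⁻³ at size
  10 and break the step). `sm2` is (k = 0.025, x₀ = 300): sizes ≤ 200 get
  near-zero weight, 200–300 get 0.1–0.8, 300+ get ≥ 0.8. `sm3`–`sm5`
  (k = 0.05; x₀ = 50, 100, 200) are package placeholder defaults — there is
  no published parameterization for them — and are expected to be overridden
  from config when calibrated values exist.

Properties (tested): zero on identical histograms, antisymmetry under
wild-type/mutant swap for `dm`/`sm`, linearity in counts, invariance of
`lm` to adding equal counts at s_min, invariance of `sm1` to redistribution
below the step.

### Features

80 fixed-order entries: per site (mut1, mut2) — absolute SASA (Å²),
relative SASA (%), a 4-way secondary-structure one-hot, and two 4-way
residue-category one-hots (wild-type and target residue; categories:
charged D/E/K/R, polar N/Q/S/T, aromatic F/H/W/Y, hydrophobic
A/C/G/I/L/M/P/V); then temperature, pH, the RD score, 24 cluster-fraction
bins each for wild type and mutant (sizes 2…20 singly, then 21–30, 31–50,
51–100, 101–1000, 1001+; size-1 clusters count toward no bin), and a
single/double flag. Single mutants have every mut2 entry exactly 0.
Categorical features are one-hot rather than integer-coded — the 8/16
per-record category counts are consistent with one-hot per slot. SASA and
secondary structure are computed on the *wild-type* structure for both the
wild-type and target slots, because the truncated mutant side chain would
distort them. Temperature stays in the unit recorded upstream.

SASA is Shrake–Rupley with probe 1.4 Å and 3840 Fibonacci-spiral points per
atom. 960 points would be ~4× faster but leaves rotational variation of
~2.3% in residue-level areas; 3840 brings it to ~0.2%, inside the package's
0.5% invariance contract. Relative SASA divides by the Tien et al.
theoretical residue maxima and clips to [0, 100]. Secondary structure uses
HELIX/SHEET/TURN header records when present, else a φ/ψ-window classifier
(helix: φ ∈ [−100, −30], ψ ∈ [−80, −5]; sheet: φ ∈ [−180, −90],
ψ ∈ [90, 180]; else coil; chain termini are coil).

### Split, models, tuning

`grouped_split` shuffles groups (keyed by structure id + sorted mutation
specs) with a seeded RNG and assigns each greedily to the set with the
largest remaining record deficit; defaults 70/15/15. Every replicate of a
mutation combination stays in one set.

- SVR: scikit-learn, behind a training-statistics standardizer; defaults
  RBF kernel, γ = 0.015, ε = 0.1, C = 1 (C is the package default; no
  calibrated value exists).
- RF: scikit-learn RandomForestRegressor, 500 trees, 22 candidate variables
  per split (clipped to the feature count when ablation shrinks it),
  bootstrap samples the size of the training set.
- DNN: implemented in numpy so the contract is fully specified — L ∈ [1,4]
  hidden layers of 10–100 units, tanh or ReLU, weights and biases drawn
  U(−ε, ε), minibatch SGD or Adam on mean squared error, features
  standardized internally. Training length is controlled by early stopping
  on dev RMSE with patience 20 (best weights restored); without a dev set
  it runs `max_epochs` (default 200). Fixed seeds give bit-identical
  models. `DNNEnsemble` averages 5 restarts differing only in seed;
  diverged restarts are dropped and counted.

`tune` minimizes mean cross-validated RMSE (folds respect group keys) or
dev-set RMSE when a dev set is supplied (the DNN protocol); grid or seeded
random search; ties go to the first-listed config; the full trace is
returned. `ablate` removes one named feature group at a time (one-hot
blocks and the SASA pair move as units), refits on the training rows and
ranks groups by the drop in test R.

### Voting

Given m ≥ 2 aligned prediction sets with dev-set metrics cᵢ (Pearson R) and
rᵢ (RMSE): `uwa` is the plain mean; `c-wa`, `rmse-wa` and `combined-wa`
replace each hᵢ(x) by hᵢ(x) + (h*(x) − hᵢ(x))·f, with f = 1 − cᵢ/c*,
1 − r*/rᵢ, or 1 − γᵢ/γ* (γᵢ = cᵢ/rᵢ) and h* the best model by that metric,
then average. Every adjusted term lies between hᵢ(x) and h*(x), so votes
never extrapolate beyond the models' own predictions. Negative cᵢ make the
correlation weights meaningless and raise an error rather than being
silently clipped.

Outlier handling: a record is an outlier when its loss (absolute error by
default; squared behind a flag) divided by the model's RMSE exceeds τ;
mode `exclude` drops such records from the metric computation, mode `scale`
shrinks their residuals by α ∈ (0, 1] before re-evaluating. Adjusted
metrics feed both the weights and the identity of h*. Reference metrics are
computed on the dev set and frozen before test-set voting, so no test
labels leak into the weights. `tune_voting` picks, per scheme, the config
maximizing dev R (ties: lower RMSE, then first listed); the default grid is
τ ∈ {1.5, 2, 2.5, 3, ∞} with α ∈ {0.25, 0.5, 1}.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage is testable without downloads.

- `gen_toy_structure` builds ideal-geometry polyalanine backbones (N, CA,
  C, O, CB; bond lengths/angles from standard peptide geometry, φ/ψ =
  −57°/−47° for the helix, −139°/135° for the strand) by chained internal
  coordinates. They exercise PDB I/O, truncation, SASA, secondary structure
  and the constraint graph, but they are tiny, single-chain,
  hydrogen-free backbones — not folded proteins.
- `gen_histogram_pair` emulates the one-giant-cluster regime of folded
  proteins: one LRC holding `lrc_fraction` (default 0.4) of `n_atoms`
  (default 1500) over a truncated power law (exponent 2.5, sizes ≤ 50) of
  small clusters. The mutant moves `perturbation`·LRC/2 atoms (default
  strength 0.3) out of the giant cluster into small ones, so LRC_mut ≤
  LRC_wt by construction and atom count is conserved.
- `gen_feature_dataset` draws structural features once per group
  (mutation combination) and varies temperature/pH per record, with
  ΔΔG = Σ wⱼ·xⱼ + N(0, σ). Defaults: 300 records in 60 groups, σ = 0.5
  kcal/mol, planted weights on relative SASA (−0.03/%), temperature
  (+0.02/°), pH (−0.1), RD (+0.004) and the double flag (+0.5), chosen once
  to give a ΔΔG spread of roughly ±2 kcal/mol, comparable to experimental
  mutant panels.

Passing the recovery tests therefore shows that the pipeline's plumbing,
split hygiene, learners and voting algebra behave correctly on data *whose
generative law is linear and known*. It does not show that rigidity
features predict real ΔΔG — that claim needs experimental labels and real
structures, which this package deliberately does not bundle.

## Numerical choices and degenerate inputs

- Sigmoid weights below 10⁻³ truncate to 0; `linear_weight` clips
  out-of-range sizes into [s_min, s_max] with a warning; a degenerate
  single-size histogram gives lm weight 1.
- `evaluate` refuses constant labels (R undefined) rather than returning 0;
  a constant *predictor* reports R = 0 explicitly.
- The rank oracle uses |null-space entry| ≤ 10⁻⁷ (relative) as "zero
  motion" and caps at 80 bodies.
- Pebble-game DFS visits neighbours in ascending index order; tuning and
  voting ties resolve to the first-listed candidate — all outputs are
  reproducible from seeds.
- The DNN raises on non-finite loss instead of returning garbage; the
  ensemble excludes such restarts.

## Known limitations

- Only glycine targets are generated natively; everything else requires an
  external placement tool.
- Hydrogen atoms are read if present but never placed, so hydrogen-bond
  detection on heavy-atom-only crystal structures needs the distance-only
  fallback; backbone hydrogens are kept on truncation.
- The per-atom body-bar abstraction leaves terminal atoms with a spin
  degree of freedom; clusters are meaningful relative to this model, which
  is validated against its own rank oracle, not against any external
  rigidity server.
- `sm3`–`sm5` defaults are uncalibrated placeholders.
- Test-suite problem sizes (300–500 synthetic records, ≤ 10-residue toy
  structures, ≤ 8-body oracle graphs) are the package's chosen desk-scale
  conditions; conclusions at protein scale require real inputs.
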