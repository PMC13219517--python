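# Methods

## Model

`soluboost` regresses the natural log of mole-fraction solubility, ln x, of a
pharmaceutical solute in an organic solvent at temperature T. Working on the
log scale is essential because equilibrium solubilities of drug-like solutes
span many orders of magnitude between systems; a squared-error objective on
x itself would be dominated by the most soluble pairs.

The regressor is a gradient-boosted ensemble of regression trees fitted by
second-order (Newton) boosting. With squared error, round m has gradients
g_i = ŷ_i − y_i and unit hessians, so each tree is a regularized fit to the
current residuals. Leaf weights are

    w = −softthreshold(G, α) / (H + λ),

with G, H the gradient/hessian sums in the leaf and (α, λ) the L1/L2
penalties, and the split criterion is the standard second-order gain

    gain = ½·[G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ)] − γ.

Split search is exact greedy: every boundary between adjacent distinct
sorted values of every available column is evaluated, with the threshold at
the midpoint. No histogram approximation is used — the corpora this model
targets are a few hundred rows, where exactness is cheap and makes the
implementation directly checkable against brute-force enumeration (and it is,
in the tests).

### Temperature monotonicity

Solubility of API-type solutes in organic solvents rises with temperature,
and a model used for crystallization design must respect that. The
temperature column carries a +1 monotonic constraint enforced in two steps:

1. a candidate split on T is rejected unless its left-child weight is ≤ its
   right-child weight (weights evaluated under the node's current bounds);
2. the children of an accepted T-split inherit weight intervals cut at the
   midpoint (w_L + w_R)/2 — the left subtree may never emit a leaf above the
   midpoint, the right never below.

Step 2 is what turns a per-split rule into a global guarantee: any path
through one tree is nondecreasing in T, and a sum of such trees plus a
constant base score stays nondecreasing. This is property-tested on
randomized ensembles.

### Features

Columns, in order: one 0/1 indicator per training solute and per solvent
(lexicographic, no reference level dropped), then T, ΔH_fus (kJ/mol), T_m
(K), q (J K⁻¹ mol⁻¹), r (J K⁻² mol⁻¹), Hansen parameter (MPa^0.5), solvent
dielectric constant, solvent boiling point (K). Continuous columns are
standardized with population statistics from the fit rows; indicators are
not. Standardization with positive spread preserves ordering, so the
monotone constraint on scaled T is equivalent to one on raw T.

The two heat-capacity parameters enter as static solute descriptors.
A derived ΔC_p(T) = q + r·(T − T_m) column is available
(`SolubilityFeaturizer(include_delta_cp=True)`) but off by default,
deliberately: with a second temperature-dependent column the booster's
response to the unconstrained ΔC_p channel can (and in practice does) dent
the monotonicity of predicted solubility curves, which defeats the purpose
of the constraint. Keeping T the sole temperature carrier preserves the
global guarantee.

The all-zero indicator convention is load-bearing: a solute absent from
training activates no solute indicator, so its prediction flows entirely
through the numeric descriptors. This is what makes external
(new-compound) prediction possible at all.

### Hyperparameters

Defaults (`PUBLISHED_PARAMS`) are the published optimum for this problem:
300 rounds, depth 4, learning rate 0.05, 70% row subsampling and 70% column
sampling per tree, γ = 0, α = 0, λ = 1, min_child_weight = 1, seed 42.
The search grid shipped with `grid_search` brackets these values
(n_estimators {100, 300, 500}, depth {3, 4, 6}, rate {0.05, 0.1},
subsample/colsample {0.7, 1.0}) and scores candidates by 5-fold
cross-validated RMSLE (lower is better).

Two conventions are under-determined by the published description and fixed
here for reproducibility: the base score is the training-target mean (ln x
targets live far from any fixed constant), and row/column sampling draws
without replacement from a fresh deterministic substream seeded by
(seed, round). Both are recorded in the model file; two fits with the same
inputs and seed are bit-identical.

## Validation protocols

* **Stratified 80/20 hold-out** (in-distribution default): per solvent
  stratum, records are ordered by temperature (ties broken by a seeded
  shuffle — a deterministic secondary sort would let the systematic-sampling
  period lock onto the solute cycle and silently hold out whole systems) and
  test rows are drawn by systematic sampling, keeping solvent and
  temperature distributions consistent across the sides.
* **Leave-one-group-out** by solute, solvent or pair. Leave-one-solute-out
  is the external-validation protocol: the held compound contributes no
  records and no indicator column.
* **k-fold** seeded partitions for grid search.

## Metrics

Two RMSLE normalisations are reported side by side: the "paper" form
√(Σ d²)/N used by the comparison literature (N outside the root) and the
conventional √(Σ d²/N); they differ by exactly √N, an identity the tests
assert. Which form produced any given literature table is often ambiguous —
reporting both makes either comparison possible. MAPD,
100·mean(|x_calc − x_exp|/x_exp), is computed on the linear scale, where it
is directly comparable to the relative scatter of experimental solubility
measurements; R² is computed on ln x, matching log-scale parity plots.
Per-system reports average each solute's systems arithmetically and then
average over solutes, so every compound counts equally.

## Synthetic corpus generator

The generator emulates the structure of the experimental corpus the model
family targets: 30 tabulated solute–solvent systems over five solutes
(butyl paraben, fenoxycarb, fenofibrate, risperidone, butamben) and nine
solvents, 8 evenly spaced temperatures in 278–323 K per pair, mole fractions
spanning several orders of magnitude, monotone increasing in T.

    ln x = ln x_id(solute, T) − ln γ(solute, solvent, T) + ε

* ln x_id is the heat-capacity-corrected ideal solubility from melting
  properties (closed form of the thermodynamic integral with
  ΔC_p = q + r·(T − T_m); 0 at T_m; van't Hoff when q = r → 0). The closed
  form is verified against numerical quadrature to 1e−8.
* ln γ = κ·m·(T_m/T) ≥ 0 is a deliberately simple activity penalty.
  The mismatch m ∈ [0, ~1] is a normalized distance between the solvent's
  (dielectric, boiling point) and per-solute anchor values drawn once from
  the seeded stream. Nonnegativity keeps x ≤ x_id ≤ 1 without aggressive
  clamping (sub-ideal solubility, the typical regime for these systems);
  the T_m/T factor makes −ln γ increase with T, so noise-free curves are
  strictly increasing.
* ε ~ N(0, σ²) on ln x: experimental solubility scatter is relative.

Defaults: κ = 4 (chosen once so that the corpus spans roughly 3–4 orders of
magnitude in x, mirroring the heterogeneity of the real systems — butyl
paraben reaching x ≈ 0.7, risperidone orders of magnitude lower), σ = 0.1
(a typical relative uncertainty for solubility measurements), seed 0.

What the generator does **not** emulate: polymorphism and solvate formation,
mixed solvents, correlated measurement errors within a lab/series, and any
solute–solvent chemistry beyond the two-descriptor mismatch. Passing tests
therefore demonstrate that the pipeline recovers a known monotone,
descriptor-driven solubility surface from noisy data — not that it attains
any particular accuracy on real measurements.

### Butamben descriptor row

The published descriptor table's butamben row is typographically corrupted;
only T_m = 330 K is reliably readable. The packaged fixture fills the
remaining fields with provisional values (ΔH_fus = 24.1 kJ/mol, q = 130
J K⁻¹ mol⁻¹ chosen within the range of the other solutes; r = 0.862,
Hansen = 20.63 read from the tail of the corrupted digit run). They are
placeholders for the generator and tests, overridable by any user
descriptor file, and should not be cited as data.

## Numerical choices and degenerate inputs

* Gain ties break toward the lowest column index, then the lowest
  threshold; rows with a feature value below the threshold go left.
* Splits require strictly positive gain and ≥ min_child_weight hessian mass
  per child; a node with no admissible split becomes a leaf.
* Constant continuous columns standardize to zeros; a constant target gives
  a base-score-only model whose trees are single zero-weight leaves.
* Duplicate (solute, solvent, T) records are rejected, not averaged — no
  aggregation rule is defensible without knowing the measurement protocol.
* A solvent stratum with a single record goes to the training side with a
  warning.
* RMSLE/MAPD require strictly positive mole fractions; R² requires nonzero
  variance. Violations raise, they are never silently patched.

## Known limitations

* Equal-gain splits make tree topology sensitive to tie-breaking; two
  correct implementations of the same algorithm can differ on held-out
  points (they agree on training points) by a few hundredths in ln x. The
  xgboost cross-check in the tests pins this envelope.
* The booster implements squared error only, with no sparsity handling,
  approximate split finding or early stopping — outside the target problem
  size these would matter.
* Descriptors are supplied as tables; no structure-based computation
  (SMILES parsing etc.) is attempted.
* External-solute accuracy hinges on the numeric descriptors spanning the
  new compound; a solute far outside the training descriptor range falls
  back to uninformative indicator-free predictions.
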