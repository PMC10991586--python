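# Methods

## The model

Given a phenotype matrix **X** (n samples × m attributes), multi-attribute
subset selection (MASS) chooses, for a budget p, a set of predictor
attributes and regression coefficients so that every remaining (response)
attribute is expressed as a linear combination of the predictors:

    X = X B + B0 + E

with B the m×m coefficient matrix (B[k, j] is the weight of regressor k in
the regression for attribute j), B0 the intercepts, and E the residual.
Which attributes serve as predictors is itself a decision variable: a
binary indicator z_j per attribute, with Σ z_j ≤ p. The joint problem is a
mixed-integer linear program:

* objective: (1/n) Σ_ij w_ij + λ Σ_j ‖β_j‖₁, where w_ij is the per-cell
  loss slack and the ℓ1 term (linearized by the standard sign split
  B = B⁺ − B⁻) encourages sparse coefficient columns;
* indicator coupling: −M z_k ≤ B[k, j] ≤ M z_k for all j, k, so only
  predictors may carry nonzero coefficients;
* loss switching: for the **absolute loss** (real-valued data) an auxiliary
  t_ij is pinned to X_ij when j is a response (−M z_j ≤ t_ij − X_ij ≤ M z_j)
  and the two-sided constraints t_ij − x_i'β_j − β0_j ≤ w_ij force
  w_ij ≥ |X_ij − x_i'β_j − β0_j|; when j is a predictor, t floats and w
  drops to 0. For the **hinge loss** (±1 data)
  X_ij (x_i'β_j + β0_j) ≥ 1 − w_ij − M z_j, so responses pay margin
  violations while predictor rows are switched off by the M z_j slack;
* group equality: all one-hot dummies of one categorical attribute must be
  predictors or responses together. This package realizes the constraint
  structurally with one binary per attribute group, which also makes the
  default budget semantics "one unit per attribute" (`per_group`); the
  literal per-feature count is available as `group_budget="per_feature"`.

Because responses are coupled only through z, the optimum for a fixed
predictor set decomposes into independent per-response LPs. That is the
basis of the brute-force oracle (`enumerate_subsets`), which certifies the
MILP on instances with at most 12 budget units.

## Parameters

| parameter | default | meaning |
|---|---|---|
| p | required | predictor budget (inequality: fewer predictors may win when λ > 0) |
| λ (`sparsity_weight`) | 1e-3 | ℓ1 weight; 0 disables. The default nudges ties toward sparse B without visibly moving the loss |
| M (`big_m`) | 10 | coefficient box and indicator constant. ±1 data needs margin-1 separators whose coefficients are a few units at most; too small an M cuts off optima, too large an M weakens the LP relaxation |
| `group_budget` | per_group | whether p counts attributes or encoded features |
| `bound_intercept` | False | intercepts are free by default; they can be boxed to ±M for fragile backends |
| `mip_gap` | 1e-6 | relative MIP gap; loosen to ~1e-4 for production-size instances |

## Solver backend

Models are materialized as sparse constraint systems and solved with HiGHS
through `scipy.optimize.milp`; LP subproblems use `scipy.optimize.linprog`.
With one thread and a fixed model, HiGHS is deterministic: identical inputs
yield identical objective values (predictor identity may differ between
exactly tied optima, so tests assert objectives, not z identity, whenever
ties are possible). `solve()` accepts a warm start; this backend does not
consume MIP starts, so the start is used as a safety incumbent — if the
main solve fails or (under a time limit) returns something worse, the
fixed-z restriction of the start is solved and returned instead. On the
instance sizes this package targets, solves run to optimality and the
incumbent path is not exercised.

## Descending sweep heuristics

Solving at large p is fast (few active loss rows); small p is the hard
regime. The sweep solves the unconstrained problem at p_max (default: one
less than the number of budget units, so at least one response exists) and
descends, at each p adding one of two constraints relative to the support
z_prev found at p+1:

* greedy1: z_prev' z ≥ p (all predictors inherited);
* greedy2: z_prev' z ≥ p − 1 (one outside swap allowed), warm-started with
  greedy1's solution.

greedy2's support seeds the next step. By construction
objective(greedy1) ≥ objective(greedy2) ≥ objective(exact) whenever the
restricted problems are solved to optimality; the package reports how often
greedy2 attains the exact optimum.

## Preprocessing

* `discretize_growth`: continuous growth values become 1 if above a
  threshold (default 0, i.e. any nonzero growth counts) else 0. The
  threshold is configurable because "significant growth" is assay-specific.
* `encode_for_mass`: binary {0,1} maps to {−1,+1}; k-level categorical
  attributes are one-hot encoded with a declared reference level dropped
  (three growth levels → two dummies per attribute), zeros cast to −1 as
  the hinge loss requires.
* `spearman_filter`: pairs of attributes with |Spearman ρ| above a
  threshold (default 0.74) are redundant; pairs are scanned in column order
  and the later column is dropped, which is deterministic and auditable.
  A constant column has undefined ρ and is treated as ρ = 0 with a logged
  warning, so unbalanced columns survive to be judged by the selection
  itself.
* `drop_incomplete_samples` removes rows with any missing entry; missing
  symbols must be declared explicitly at parse time — no silent coercion.

## Validation harness

A predictor selection of any provenance (MASS, entropy ranking, random) is
scored by supervised learning: an unstratified 50/50 sample split (odd n:
the training half gets the extra sample), one random-forest classifier per
response attribute trained on the selected predictors (raw categorical
codes), hyperparameters tuned by k-fold CV on the training half over a
small grid (candidate features per split, maximum depth), and metrics
pooled over the concatenated test predictions of all responses (a single
confusion per selection and p). Metrics: MCC, accuracy, balanced accuracy,
Cohen's κ, weighted F1, and the macro-averaged Jaccard similarity score
(the output is labelled as a similarity). A response with a single training
class is served by a constant predictor and flagged.

The 300-draw random baseline is evaluated exactly but economically: with a
fixed split and classifier seed, a subset's score is deterministic, so
repeated draws of the same subset are computed once and weighted by
multiplicity.

## Synthetic data

`generate_planted` draws p_true predictor columns independently with
configurable marginal frequencies and computes each response from the
predictors by one of three rules — `linear_threshold` (a random ±1-weighted
threshold function whose offset parity guarantees margin ≥ 1, so the rule is
exactly representable by the hinge model), `majority`, or `copy_with_noise`
— then corrupts response entries at rate ε (< 0.5 for identifiability):
binary entries flip, three-level entries resample uniformly among the other
two levels. Skewed marginals produce the rare/ubiquitous columns seen in
real fermentation data. `generate_unbalanced_suite` fixes three such
matrices (a rare planted predictor, a rare column among balanced copies,
and an all-balanced control built from copies so that every column stays
near 50/50).

What the generator does not emulate: phylogenetic correlation between
samples, systematic missingness, measurement batch effects, and nonlinear
trait dependencies. Passing tests therefore demonstrate correctness of the
optimization and the harness, not field performance on any particular
organism panel.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale instances chosen so that exhaustive
enumeration remains a valid certificate: random ±1 instances with
n ≤ 30, m ≤ 8, p ≤ 4 for oracle equivalence (checked at λ = 0 and 1e-3);
n = 500, m = 8 planted instances for recovery; n = 120, m = 8 with ε = 0.1
for the baseline-ordering study (random forests with 30 trees and a
two-point depth grid, 5-fold CV). The enumeration guard refuses more than
12 budget units. Oracle-equivalence comparisons use 1e-6 on objectives;
solution invariants allow 1e-7·M on coefficients of non-predictors.
Degenerate planted draws (an alternative subset exactly tied at the
optimum) are detected by enumeration and excluded from recovery rates.

## Known limitations

* No MIP warm-start injection (backend limitation; see above) — the sweep
  still benefits from the restricted feasible regions, which is where most
  of the speedup lies.
* The absolute-loss model assumes |X_ij| well inside M; data should be
  scaled accordingly.
* Entropy is computed on raw categorical columns, not on dummies, so the
  entropy baseline is independent of the encoding choices.
* `per_feature` budget mode can select "half" an attribute only in the
  sense of spending budget on both dummies; the group equality constraint
  always holds.
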