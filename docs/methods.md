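# Methods

## Setting and model

A cohort of N labelled subjects is split column-wise into observed
features `X_o` (dimension d_o, known for everyone) and elicitable
features `X_u` (dimension d_u, known only for the fully observed pool
`E_o`; acquirable on demand for the partially observed pool `E_u`).
Labels are known for all subjects — the scarce commodity is features,
not labels, which distinguishes this from ordinary pool-based active
learning.

Two probabilistic classifiers drive acquisition:

- `M_u = P(Y | X_o)`, fitted once on the observed features of all N
  subjects and frozen for the entire run. It summarises what the cheap
  features say about each candidate.
- `M_o = P(Y | X_o, X_u)`, fitted on the full features of the current
  `E_o` and refitted from scratch after every acquisition batch
  (no warm starting, so results do not depend on fit history).

A candidate i ∈ E_u is scored by the mean divergence of its
cheap-feature posterior from the full-feature posteriors of the
observed pool:

    MD_i = (1/|E_o|) Σ_{j∈E_o} Div( M_u(i) ‖ M_o(j) ).

The direction is part of the method: the candidate's posterior is
always the first (numerator-weight) argument. For asymmetric
divergences, swapping the arguments changes the selected set, and the
test suite guards against silently symmetrising. The top-n candidates
by MD are queried; ties are broken by ascending row index so runs are
fully deterministic given a seed.

The intuition: subjects whose cheap-feature posterior looks unlike
anything in the fully measured pool are the ones the full-feature model
knows least about, so measuring them adds the most information per unit
of acquisition cost. Multi-class cohorts are supported natively — all
divergences operate on length-K posteriors with a class order fixed by
first appearance in the label column and shared by both models.

## Divergences

Four instances of the Csiszár f-divergence
`D_f(p‖q) = Σ q_i f(p_i/q_i)` are provided in closed form, with the
generic form kept as an executable oracle:

| name            | f(x)          | closed form              | symmetric |
|-----------------|---------------|--------------------------|-----------|
| kl              | x log x       | Σ p log(p/q)             | no        |
| hellinger       | (√x − 1)²     | ½ Σ (√p − √q)²           | yes       |
| total_variation | ½\|x − 1\|    | ½ ‖p − q‖₁               | yes       |
| neyman_chi2     | (x − 1)²      | Σ (p − q)²/q             | no        |

Numerical choices:

- **Hellinger constant.** The generator (√x−1)² integrates to
  Σ(√p−√q)², twice the ½-normalised form implemented here. The ½ keeps
  the value in [0, 1]; candidate ranking is unaffected by any positive
  constant, so the choice is cosmetic and is documented rather than
  hidden (the oracle test compares after halving the generator).
- **Zero-probability handling.** KL and χ² are undefined at q_i = 0,
  which confident classifiers produce routinely. The denominator
  distribution is floored at `clamp_eps = 1e-10` and renormalised —
  but only when some entry is actually below the floor, so identical
  arguments give exactly zero. p-side zeros use the 0·log 0 = 0
  convention. The χ² denominator convention implemented is the printed
  Σ(p−q)²/q form.
- **Natural logarithms** throughout (nats), matching the log-likelihood
  convergence scale.
- Scoring is vectorised over the |E_u| × |E_o| grid on cached
  posteriors (one batched predict per model per iteration); the scalar
  per-pair functions remain the reference path the tests compare
  against.

## Classifiers and calibration

Two families sit behind one probabilistic-classifier contract:

- **Gradient boosting** (100 stages, depth 3, learning rate 0.1 —
  conventional defaults, overridable in `ClassifierSpec.params`). Its
  class probabilities are used directly.
- **Linear-kernel SVM** (C = 1). Margins are mapped to probabilities by
  Platt scaling, `P(y=1|s) = 1/(1+exp(A s+B))`, fitted by unpenalised
  logistic maximum likelihood on the model's own training scores (an
  optional cross-validated variant exists behind
  `calibration_cv`; it is off by default). Multi-class margins are
  calibrated one-vs-rest and renormalised.

One `ClassifierSpec` instance is shared by every strategy in an
experiment, so method comparisons never confound selection policy with
classifier settings.

## Stopping rules

The loop stops on the first of: change in `M_o`'s *train mean
log-likelihood* (per example, on the current `E_o`) falling below
`epsilon`; the acquisition `budget` (counted in subjects — each
acquisition elicits all d_u features); `max_iterations`; or pool
exhaustion (a final short batch is taken when |E_u| < n). The
per-example mean makes `epsilon` invariant to the growing pool size;
the default is 1e-3.

Two caveats are deliberate design positions:

- **`epsilon=None` disables the likelihood stop.** Boosted trees
  expressive enough to interpolate their training set saturate the
  train likelihood after the first refit (often to bitwise-identical
  values), which would end every run after two batches. The experiment
  harness therefore runs a fixed iteration budget by default and treats
  the likelihood criterion as an opt-in, which matches protocols that
  report fixed numbers of acquisition rounds. The likelihood criterion
  remains meaningful for the calibrated SVM.
- **Batch schedule.** The default schedule is `fixed`: n stays constant
  (batches of 5) until a stopping rule fires. A `literal` schedule
  applying the shrinking update n ← n/(n+Δ) is retained for fidelity;
  under it n drops below 1 after a single iteration for any Δ ≥ 0, so
  it terminates after one batch.

## Baseline strategies

All selectors plug into the identical acquisition/retraining loop:

- `rnd` — uniform random batches. Draws come from a stream derived from
  (run seed, iteration), so baseline randomness never perturbs the
  classifier seeds.
- `us_obs` — uncertainty sampling: top-n posterior entropy under the
  frozen `M_u`.
- `us_all` — uncertainty sampling on the full feature set: each E_u
  row's missing elicitable block is filled with the per-column mode of
  the current `E_o` (recomputed each iteration as `E_o` grows), and
  entropy is taken under the current `M_o`. The mode of a continuous
  column is computed after rounding to 6 significant digits (a mode is
  only well defined for discrete values); ties go to the smallest
  value. The scoring model is the loop's `M_o`, not a separate refit on
  imputed data.

## Evaluation

Metrics are recall (clinical sensitivity), F1, and the geometric mean
of sensitivity and specificity — all robust under class imbalance;
AUROC is deliberately not offered. Degenerate 0/0 cases return 0 for
every metric, a conservative convention applied uniformly to all
strategies. The declared positive class defaults to the minority class.

Experiments run each (strategy × classifier × divergence) combination
for `n_runs` seeded repetitions against one fixed test set; run r of
every combination shares the same initial `E_o` draw and classifier
seed, so strategies differ only in which subjects they pick.
Aggregation reports per-iteration mean ± sample SD; traces of unequal
length are truncated to the common prefix with a logged warning.

Method comparison uses average ranks across datasets with a relative
tie band: per dataset, methods are sorted best-first and a method joins
the current tie group when its value is within 3% (relative to the
group leader's value) of the leader; every member shares the group's
best rank, and a zero tolerance recovers standard competition ranking.
The tie-rank value (group minimum) and the relative reading of the 3%
are documented choices, both configurable.

## Synthetic cohorts

The generator draws Bernoulli(π) labels and class-conditional Gaussian
features: class-1 means are shifted by `effect_obs` (observed columns)
and `effect_elic` (elicitable columns) in units of the noise SD. The
defaults describe the regime the method targets — 500 subjects, π =
0.25, four observed columns with a weak 0.3 SD shift, four elicitable
columns with a strong 2.0 SD shift, ten initially fully observed
subjects, and a 20% held-out test set (sizes and the 4+4 column split
mirror a PIMA-style diabetes cohort). The Gaussian form was chosen for
analytic transparency: Bayes-optimal posteriors are available in closed
form for stub-model tests.

Determinism is layered: the cohort and its test split depend only on
the data seed (one fixed test set across runs), while `init_seed`
varies only which train rows start fully observed — the per-run source
of sampling variation. The initial `E_o` is drawn stratified by class
(an all-one-class pool makes `M_o` unfittable); `stratify_initial:
false` restores pure random initialisation.

What the generator does *not* emulate: correlated or mixed-type
features, missingness beyond the observed/elicitable split, label
noise, and covariate shift between pools. Passing tests on these
cohorts demonstrate the mechanics and the qualitative value of
divergence-guided acquisition when the elicitable block carries the
signal; they do not certify performance on any real clinical cohort.

## Problem sizes used in the checked experiments

The automated checks run the full protocol at desk scale: selection
oracles on instances with |E_u| ≤ 30 and |E_o| ≤ 15; loop accounting on
200-subject cohorts; the divergence-vs-random comparison on the default
500-subject cohort over 10 seeds (10 iterations of 5 acquisitions,
gradient boosting + KL); and an end-to-end two-classifier protocol run
on a 700-subject cohort (80/20 split, 10 runs, batches of 5, capped at
10 iterations — 50 acquisitions — rather than running the 550-subject
pool to exhaustion). These sizes are the package's reference
configuration for reproducible checks; all of them scale up by changing
the spec objects.

## Known limitations

- Scoring is O(|E_u|·|E_o|) per iteration; for very large pools a
  subsampled `E_o` mean would be the natural refinement.
- Mode imputation is crude by design (it is the published baseline);
  better imputers would likely narrow the gap to `us_all`.
- The divergence score ignores acquisition cost heterogeneity: every
  subject is assumed equally expensive to elicit.
- Per-subject feature-subset acquisition (eliciting only some columns)
  is out of scope; an acquisition always fills the whole elicitable
  block.
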