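# afe — active feature elicitation for partially observed cohorts

Clinical prediction studies routinely have two tiers of data: cheap
*observed* features (demographics, a single screening score) known for
every subject, and expensive *elicitable* features (labs, imaging,
questionnaires) collected only for a small fully observed pool. Labels
are known for everyone. The recruitment question is: **which subjects
should we pay to measure next?**

This package implements divergence-guided active feature elicitation.
Let `E_o` be the fully observed pool and `E_u` the partially observed
pool. Two classifiers are maintained: `M_u = P(Y | X_o)` trained once on
the observed features of *all* subjects (and then frozen), and
`M_o = P(Y | X_o, X_u)` retrained on the full features of the current
`E_o`. Each candidate i ∈ E_u is scored by its mean divergence from the
fully observed pool,

    MD_i = (1/|E_o|) · Σ_{j ∈ E_o}  Div( P(Y_i | X_o^i)  ‖  P(Y_j | X_o^j, X_u^j) ),

the `n` most divergent subjects are queried for their elicitable
features, moved into `E_o`, `M_o` is retrained, and the loop repeats
until the training log-likelihood stabilises or the acquisition budget
is exhausted. `Div` is any f-divergence `D_f(p‖q) = Σ q_i f(p_i/q_i)`
(convex `f`, `f(1)=0`); KL, squared Hellinger, total variation and the
χ²-divergence are built in, and the generic form is exposed as an
internal correctness oracle.

Also included:

- classifier plug-ins: gradient boosting, and a linear-kernel SVM whose
  margins are converted to probabilities by Platt scaling;
- the three standard comparison strategies: random selection (`rnd`),
  uncertainty sampling on observed features (`us_obs`), and uncertainty
  sampling on mode-imputed full features (`us_all`);
- imbalance-aware evaluation (recall, F1, gmean), multi-run
  aggregation against a fixed test set, and average-rank method
  comparison with a 3% tie band;
- a seeded synthetic-cohort generator and a CSV loader for PIMA-style
  tables, so everything runs without any external data.

## Worked example

```python
import afe

spec = afe.SyntheticSpec(seed=2)          # 500 subjects, 25% positives,
dataset, oracle, test = afe.generate(spec)  # weak observed / strong elicitable signal

config = afe.AFEConfig(
    batch_size=5, max_iterations=10, epsilon=None,
    divergence=afe.DivergenceSpec("kl"),
    classifier=afe.ClassifierSpec("gradient_boosting"),
    seed=2,
)
results = afe.ActiveFeatureElicitation(dataset, oracle, config=config,
                                       test_set=test).fit()
print(results.summary())
```

```
Active Feature Elicitation Results
============================================
strategy                afe
classifier              gradient_boosting
divergence              kl
batch size              5
iterations run          10
examples acquired       50
|E_o| initial -> final  10 -> 60
final train LL/ex       -0.0000
test recall             0.9615
test F1                 0.7692
test gmean              0.8830
```

Starting from only 10 fully observed subjects, ten batches of 5
divergence-selected acquisitions grow the pool to 60 and lift held-out
recall of the rare class to 0.96. `results.trace.to_frame()` gives the
per-iteration log (selected indices, pool size, train log-likelihood,
test recall/F1/gmean) used by the plotting and aggregation helpers.

The same loop is available from a shell:

```bash
afe simulate --spec spec.yaml --out cohort.csv
afe run --config cfg.yaml --data cohort.csv --out trace.csv --seed 1
afe experiment --config experiment.yaml --out results/
afe rank --summaries results/ --tolerance 0.03
```

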