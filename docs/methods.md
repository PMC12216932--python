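# Methods

## The population model and its exact solution

A group of `N` members faces a binary decision with one correct option.
For every decision problem the group is composed afresh: each member is
independent with probability `p` (correct on its own with probability
`r_L`, i.i.d. across members and problems) or dependent (all dependents
follow one cue drawn once per problem, correct with probability `r_H`).
Votes are aggregated by strict majority; an exact tie — possible only for
even `N` — is broken by a fair coin.

The simulator (`population.simulate_decisions`) draws, per problem, the
number of independents `k ~ Binomial(N, p)`, the number of correct
independent votes `j ~ Binomial(k, r_L)` and the cue outcome, and scores
the verdict. The exact oracle (`population.exact_accuracy`) evaluates the
same quantity in closed form by conditioning on `k` and the cue:

    acc = Σ_k C(N,k) p^k (1−p)^(N−k) ·
          [ r_H · W(k, r_L, N/2 − (N−k)) + (1−r_H) · W(k, r_L, N/2) ],

where `W(k, r, t) = P(j > t) + P(j = t)/2` for `j ~ Binomial(k, r)`. The
two implementations share every convention exactly (verified in tests by
exhaustive enumeration for `N ≤ 5` and by Monte-Carlo agreement at larger
`N`), so the oracle can stand in for simulation wherever exactness or speed
matters.

Degenerate limits anchor the model: `p = 1` reduces to the Condorcet jury
formula under the coin-tie convention, `p = 0` makes the group a single
effective voter with accuracy `r_H`, and `N = 1` gives the mixture
`p·r_L + (1−p)·r_H`.

### Conventions chosen where the procedure left room

* **Tie rule.** A fair coin in both simulator and oracle (exact ties
  contribute one half in closed form). This keeps even-`N` values equal to
  their `N−1` odd neighbours in the pure-jury limit (the classical jury
  identity) rather than penalising even groups, and the same rule is used
  verbatim in the classifier committees. The jury module additionally
  exposes the literal strict-majority convention (ties incorrect), which is
  its default since that is what the printed formula counts.
* **Composition sampling.** The number of independents is
  `Binomial(N, p)` — a per-member coin — not a fixed `⌊pN⌋`; the group is
  recomposed for every decision problem.
* **Optimal group size.** `optimal_group_size` scans `N = 1..N_max`
  (default `N_max = 100`) of the exact oracle; accuracies within `1e−10`
  are treated as tied and the smallest `N` wins. The tolerance matters
  because odd/even neighbours are analytically equal in the `p = 1` limit
  and differ only by floating-point noise.
* **Canonical parameter range.** Reliabilities below 0.5 are accepted with
  a `UserWarning` rather than rejected: the studied parameter space is
  `[0.5, 1]` but nothing in the mathematics breaks below it.

Jury probabilities are evaluated through the regularized-incomplete-beta
tail of `scipy.stats.binom`, which is stable far beyond `N = 10,001`; no
explicit factorials are formed.

## Classifier committees

`ensemble.train_judge_pool` fits two rosters to one training partition:

* `L` independent judges, each on a private **balanced bootstrap** draw of
  `n_L` observations (with replacement; class 0 receives `⌊n/2⌋` samples
  and class 1 `⌈n/2⌉`; the feature set is identical for all judges);
* `H` dependent judges, each on the union of one pool-wide shared balanced
  draw of `round(alpha·n_H)` observations (round half up) and a per-judge
  balanced draw of the remainder. `alpha = 1` (default) is full
  correlation; `alpha = 0` makes the dependent arm statistically identical
  to the independent one.

Residual stochasticity among same-data judges is real for decision trees
(tie-breaking among equal-quality splits), so per-judge training seeds are
distinct by default; `train_seed_policy="fixed"` forces exact clones, which
several tests rely on. Model families are scikit-learn's
`DecisionTreeClassifier` (impurity splitting, no depth cap) and `SVC` with
an RBF kernel at library defaults; the committee effects under study come
from training-set size and overlap, not from tuned hyperparameters, and the
resolved settings are recorded in the pool's provenance.

Each test sample is one hearing: the seat composition is
`Binomial(N, p)` independents, seated without replacement within each
roster. Rosters are trained once per experiment; only seating and voting
are repeated. When `N` exceeds one roster (legitimate at desk scale, where
`H` may be 50 while committees up to 100 are probed), a drawn composition
that roster cannot seat is redrawn — the conditional distribution — and an
error is raised only when no feasible composition exists at all (e.g.
`p = 0` with `N > H`). For trained pools, per-judge predictions over the
whole test matrix are computed once and cached, so a hearing costs a seat
draw and a vote count; probabilistic stub judges (see below) take the
per-hearing path instead.

`accuracy_vs_group_size` repeats the full set of hearings `runs` times with
fresh seatings and reports mean and standard deviation per group size.
`ensemble_phase_map` retrains pools per `(n_L, p)` cell and records the
accuracy-maximising group size (smallest-`N` tie-break at `1e−12`); a cell
is labelled wisdom-of-crowds when the optimum is the largest size searched
(`N_max`, with `N_max − 1` admitted as an odd/even tie), breakdown
otherwise. `decorrelation_experiment` shares the pool and hearing seeds
across its `alpha` values, so `alpha = 1` reproduces the base experiment
bit-for-bit. `boundary_vs_nH` reports the breakdown-region cell count as
the dependent training-set size grows.

### The stub bridge

`make_stub_pool` builds rosters of Bernoulli judges: independents correct
i.i.d. with probability `r_L`, dependents all following one per-hearing
Bernoulli(`r_H`) draw. Run through the *same* hearing machinery, this
realises the population model exactly, and the tests require agreement
with `exact_accuracy` to Monte-Carlo precision. This separates validation
of the voting/seating code from any property of trained classifiers.

## Synthetic data

`datasets.make_circles_clusters` places `⌈n/2⌉` points on the unit circle
(class 0) and `⌊n/2⌋` on a circle of radius `factor` (class 1, default
0.85), then displaces every point by isotropic Gaussian noise. The default
`noise_sd = 0.1` is a deliberate, load-bearing choice: with radii 1.0 and
0.85 it overlaps the rings enough that a judge trained on tens of samples
sits in the 0.55–0.65 accuracy band and the learning curve climbs slowly
and plateaus well below 1.0 — the data-scarce regime in which committee
effects are visible at all. Markedly smaller noise makes small-sample
judges too strong (curves saturate, the breakdown region collapses);
markedly larger noise pins everything at chance.

What the generator emulates: a balanced, low-dimensional, noisy,
slowly-learnable binary problem with rotational symmetry. What it does
not: class imbalance, feature heterogeneity or missingness, label noise,
and high-dimensional structure of real tabular data. Passing tests
therefore demonstrate the collective-decision mechanisms, not robustness
of those mechanisms across real-world data pathologies; the tabular loader
(`load_and_preprocess_tabular`) exists so the same experiments can be run
on external CSV data (z-scored numeric features, binary label mapping,
constant columns dropped with a warning — full-table standardisation by
default, matching a pre-processed-dataset workflow, not a leakage-audited
pipeline).

The train/test split takes `⌊0.3·n⌋` training samples — the floor rule is
the only rounding consistent with test sizes of 3,500 from 5,000 and
37,825 from 54,035 records. Splitting is unstratified by default with a
stratified switch. Learning curves use repeated random balanced
subsampling (not fixed folds: curve points at many sizes are incompatible
with a fold partition), reporting mean and standard deviation over
`repeats` draws.

## Problem sizes and reproducibility

The package's own experiment defaults are desk-scale choices that preserve
the phenomena: rosters `L = 200`, `H = 50`, `M = 500` hearings, 20 runs,
and a 12-point group-size grid up to 100. The published-protocol sizes
(`L = 1000`, `H = 100`, 100–1000 runs, all `N = 1..100`, full test sets)
are available behind the `--preset paper` flag of every CLI subcommand;
phase maps checkpoint per-cell results to `cells.csv` as they complete so
long jobs are inspectable midway. At desk scale the finite-optimal-committee
effect on the circles dataset is reproducible across arbitrary root seeds
(the suite checks one fixed seed; an eight-seed sweep during development
showed interior optima between N = 15 and N = 81 in every case).

All randomness flows from one integer root seed through
`numpy.random.SeedSequence` with a fixed counter scheme
(`seeding.derive_seeds`); identical configurations and seeds give
byte-identical output files, and hearing records are bit-reproducible.

## Known limitations

* The exact oracle is quadratic in `N` per evaluation (a Binomial scan per
  composition count); it is instant at `N ≤ 200` but not intended for
  `N` in the tens of thousands — use the jury module's closed form for the
  pure-independent limit there.
* Committee accuracy of trained judges is *not* predicted by plugging the
  measured single-judge accuracy into the population oracle: real judges
  share per-sample difficulty, so their errors correlate even when their
  training draws are independent. The oracle is an upper bound, and the
  tests treat it as such.
* Only binary decisions and unweighted majority votes are modelled; no
  heterogeneous competences, multi-option choices, or diversity-regularised
  training.
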