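# Methods

This note documents the models, defaults and numerical choices behind
`sepsisbn`, and what the synthetic-data tests do and do not demonstrate.

## Study design encoding

The design crosses CLP (cecal ligation and puncture; binary) with three
aspirate severities (saline < acid < acid + particles) and, when CLP is
present, three CLP-to-aspirate intervals (0, 12, 48 h), giving 12 groups
of ~10 animals.  `InjuryInterval` is the time between CLP and the
aspirate; it is undefined for the no-CLP arm and encoded as a fourth
state "none" there.  (The variable's name invites the reading "no lung
insult was given", but every in-study animal received an aspirate; the
state marks the absence of CLP, and therefore of an interval.)  The
encodings carry fixed cardinalities into the scoring stage — CLP 2,
LungInsult 4 (state 0 "no injury" is part of the encoding though unused
in-study), InjuryInterval 4, and `type` (compartment) 3 — independent of
which states a particular data set happens to exercise.

Because interval "none" occurs exactly when CLP = 0, the two condition
variables are deterministically related and every learned network links
them; this adjacency is expected and is not evidence of anything
biological.

## Synthetic cohorts

No measurement data accompany the study design, so all validation runs on
synthetic cohorts drawn from configurable ground-truth causal models.
Each mediator X is conditionally log-normal given its parents:

    X = exp(N(mu, sigma^2)),
    mu = ln m(pa_cond) − sigma²/2 + Σ_p c_p (ln x_p − ln x̄_p),

where m(pa_cond) is a target conditional mean looked up by the states of
the discrete condition parents, and the sum adds log-linear effects of
continuous mediator parents.  With no mediator parents E[X] equals
m(pa_cond) exactly, which the calibration relies on.  The log-normal
family guarantees positivity and the right skew typical of cytokine
panels.  Cell counts are kept continuous in ×10³ cells/µl (rounding to
integers in these units would distort the sub-1.0 blood-neutrophil means
that anchor the calibration).

The `paper-like` preset encodes the qualitative dependency structure the
analysis is meant to recover:

* BAL NE ← {CLP, LungInsult} (the collider): severity-graded recruitment
  (means 40/180/550 ×10³ for saline/acid/particles without CLP),
  suppressed ×0.3 by concurrent CLP;
* BAL EO ← NE and BAL albumin ← NE (log-linear coefficients 0.8, 0.6),
  completing the "Y" and the vascular-leak tail;
* BAL chemokines KC, MIP-2α, LIX, MCP-1 ← LungInsult only
  (150/900/2600 pg/ml scaled per chemokine);
* peritoneal and blood IL-6, TNF-α, IL-1β ← {CLP, InjuryInterval}, low
  without CLP, peaking at 12 h, partly resolved at 48 h;
* peritoneal NE ← CLP (0.4 vs 3.5 ×10³/µl);
* blood NE ← {CLP, InjuryInterval} with means anchored at the reported
  post-CLP group values 1.9 (0 h) and 0.8 (12 h) ×10³ neutrophils/µl
  (σ = 0.35 on the log scale; 48 h set to 1.3 as a partial rebound).

All other effect sizes are free preset parameters chosen once to be
plausible for murine cytokine panels; they are defined in
`sepsisbn/generate.py` and were not fitted to any data.  The `strong`
preset widens all conditional-mean gaps ×1.6 in log space and shrinks
noise ×0.7 (used for small structure-learning checks); `null` removes all
dependencies while keeping the marginal baselines.

What the generator does *not* emulate: temporal dynamics beyond the four
interval states, mechanistic couplings (e.g. neutrophil redistribution
between compartments), measurement floors/ceilings of immunoassays,
missing data, and between-batch variation.  Passing recovery tests
therefore show that the pipeline recovers the encoded statistical
structure at the study's sample size — not that it would recover the
biology of real cohorts with those complications.

## Discretization

Default: equal-frequency tertiles.  Cut points are the empirical 1/3 and
2/3 quantiles snapped to the midpoint between the adjacent distinct order
statistics, making the mapping unambiguous under ties; intervals are
closed on the right (a value exactly at a cut maps to the lower state).
Columns with fewer than 3 distinct values collapse to fewer states and
are recorded as degenerate rather than raising.  A `manual` policy loads
expert cut points from JSON, emulating expert binning; since no published
expert thresholds exist, results that would depend on them are treated as
property-based only.

## Scoring

BDeu with ESS = 1.0 by default (the conventional default of the scoring
family; the hyperparameter is exposed because small-sample behaviour is
sensitive to it).  The maximum parent count defaults to 5 to bound the
parent-configuration blowup q_i at n ≈ 120.  Log-gamma terms use
`scipy.special.gammaln`; zero-count cells contribute exactly zero and are
vectorized over occupied parent configurations.  The empty data set
scores 0.  Scores are exactly decomposable, row-order invariant, and
score-equivalent across Markov-equivalent DAGs (verified exhaustively on
three-node graphs and against an independent sequential-predictive
(Pólya-urn) oracle in the tests).

## Search

Restarted simulated annealing from the empty DAG.  Proposals pick an
ordered node pair uniformly; an absent edge proposes an addition, an
existing edge proposes deletion or reversal with equal probability.
Cycle-creating or parent-limit-violating proposals are rejected and
consume a step, which makes the kernel uniform over candidate moves
without enumerating the legal-move set each step.  Acceptance is
Metropolis on the score difference; cooling is geometric
(factor 0.95 every `max(1, proposals/1000)` steps) from an initial
temperature of 10, i.e. on the scale of typical single-edge score
deltas.  Much hotter starts were tried and rejected: they let the early
random walk fill every node to the parent cap with junk edges, and BDeu
at small ESS then strands the cooled search on plateaus where no single
deletion improves the score.

Desk-scale defaults are 20 restarts × 1e5 proposals — enough for the
30-variable, 120-row compartment tables to recover the planted collider
in 20/20 seeded replicates while keeping a full four-table run in the
low minutes on one CPU.  The original analysis effort (100 restarts ×
5×10⁷ per compartment; 50 × 1×10⁸ combined) remains reachable via
configuration (`--paper-scale`), with a runtime warning.  Per-restart
best networks, including exact score ties (tolerance 1e-9, capped at 32
per restart), are pooled across restarts before consensus.

## Consensus and motifs

"Sharing the top log posterior" is interpreted with a numeric tolerance
of 1e-9 (floating-point equality is unreliable); it is configurable.  Top
networks are pooled across all restarts before filtering.  Adjacencies
absent from any kept network are excluded from the consensus graph but
logged with their support counts.  In consensus graphs, collider
detection uses directed edges only, while the non-adjacency condition
also counts undirected edges.

## Baseline statistics

Group summaries are mean ± SEM (SEM undefined and reported as missing
with a warning for single-animal groups).  Two-level factors use the
pooled-variance Student's t test (Welch behind a flag); multi-level
factors use one-way ANOVA with post hoc Tukey HSD at α = 0.05.  No
two-way interaction model is provided.  Note that on raw concentrations
the Tukey comparison loses power when variance grows with the mean (the
pooled MSE is dominated by the highest group); the test suite's power
check therefore runs on log-transformed counts, the standard treatment
for right-skewed mediator data.

## Sizes used in validation

Structure-recovery and search-oracle checks run at the study's own scale
(120 rows per compartment, n = 10/group) or at n ≈ 200 for 4-variable
oracle comparisons; calibration checks use 2000 simulated animals per
group; the ANOVA type-I-error simulation uses 1000 replicates.

## Known limitations

* Exact numeric reproduction of the original networks is impossible: the
  underlying animal data, the expert bin thresholds, and the original
  backend's ESS/parent-limit/annealing settings are all unpublished.
  The pipeline reproduces the method, encodings and printed design
  numbers, and validates against its own generator's ground truth.
* Whether top networks were originally pooled across replicate
  simulations or taken per simulation is unstated; pooling is assumed.
* BDeu conclusions depend on ESS at these sample sizes; only ESS = 1 is
  exercised by default.
* The generator has no sham-surgery arm (unstated in the design) and
  drops albumin from the combined run, since it exists only in BAL.
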