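# Methods

`attnlink` asks whether the attention parameters of formal categorization
models, fit to an individual's choices, predict how well the attended
stimulus features can be decoded from that individual's multivariate
neural activity.  The package implements the full chain — behavioral
models, maximum-likelihood fitting, synthetic neural data, single-trial
estimation, decoding, and the brain–behavior linking analysis — for two
classic designs: the 5/4 exemplar task (four binary stimulus dimensions,
nine training items) and the Shepard–Hovland–Jenkins (SHJ) learning
problems Types I, II and VI (three binary dimensions).

## Behavioral models

**GCM.**  The Generalized Context Model stores the nine 5/4 training
exemplars and classifies a probe `x` by attention-weighted similarity:

    d(x, y) = Σ_k w_k |x_k − y_k|          (city-block, r = 1)
    s(x, y) = exp(−c · d(x, y))
    P(A|x)  = S_A^γ / (S_A^γ + S_B^γ)

with attention `w` on the simplex, sensitivity `c > 0` and response
scaling `γ > 0`.  The exponential kernel with the city-block metric is
the conventional choice for perceptually separable binary dimensions;
no Gaussian kernel and no response-bias parameter are offered.  One
consequence worth knowing: with five A and four B exemplars and no bias
term, a participant who guesses at random is *not* fit by uniform
attention — the likelihood is maximized by concentrating attention on
the dimension whose exemplar labels split most evenly (D3), because that
flattens P(A) toward 0.5.  Attention fit to unstructured behavior is
therefore uninformative rather than uniform.

**SUSTAIN.**  A trial-by-trial clustering learner.  Binary dimensions
are encoded as positions in [0, 1] with per-dimension distance
`μ_ij = |center_ij − x_i|` (equivalent to half the nominal two-unit
encoding up to a rescaling of λ).  Cluster activation is
`act_j = Σ_i λ_i^r e^{−λ_i μ_ij} / Σ_i λ_i^r`; clusters compete
(`out_win = act_win^β / Σ_j act_j^β · act_win`); the winner's association
weights drive a Luce choice `P(k) ∝ e^{d·C_k}`.  Learning is supervised:
a cluster is recruited when there is none or when the winner predicts the
wrong category; otherwise the winner's center moves toward the stimulus,
associations follow a delta rule against a humble teacher, and tunings
update as `Δλ_i = η e^{−λ_i μ_i}(1 − λ_i μ_i)`.  Response probabilities
entering the likelihood always use the pre-update state.

Two design choices depart from the most literal reading of the classic
recipe, both forced by the discrete stimulus space:

* **Tie-breaking.**  With binary stimuli a new cluster can be recruited
  exactly on top of an older, mispredicting one.  If ties went to the
  older cluster it would win every later encounter, mispredict, and
  trigger a recruitment every time (we observed >130 clusters over a
  384-trial chain).  Ties therefore go to the most recently recruited
  cluster — deterministic, and the discrete-space analogue of the
  continuous case where the newer, better-centered cluster wins.
* **Cross-problem carryover.**  The SHJ chain (Type VI first, then I and
  II in counterbalanced order) carries learning across problems.
  Carrying the *full* state is self-defeating: Type VI forces
  memorization, leaving a cluster exactly on every stimulus, so every
  later winner has μ = 0 on all dimensions and λ grows identically —
  per-rule attention profiles mathematically cannot differentiate.  The
  default (`carryover="tunings"`) therefore carries the attention
  tunings λ across problem boundaries while each problem builds its own
  cluster solution.  This preserves cross-task attentional influence
  (e.g., a Type I profile learned after Type II retains residual weight
  on the II-relevant dimensions) while letting each task express its own
  diagnostic structure.  `carryover="full"` remains available.

**Attention extraction.**  Per problem, the attention profile is the
time-average of λ over the late learning window (the last two runs, where
behavior has stabilized), normalized to the simplex; the profile is
invariant to rescaling all λ.  The endpoint-λ alternative is available
via the window argument.

## Fitting

Both models are fit per participant by maximizing trial-wise choice
likelihood with an elitist genetic algorithm: tournament selection
(k = 3), uniform crossover (rate 0.9), Gaussian mutation (σ = 0.1) on an
unconstrained genome (softmax for the simplex, scaled logistic for
box-bounded parameters: c ∈ [0.1, 20], γ ∈ [0.1, 10], r ∈ [0.5, 20],
β ∈ [0, 20], d ∈ [0.5, 30], η ∈ [0.01, 1]), elitism 1, multi-start with
best-of.  Library defaults are population 100 × 200 generations × 5
starts; the simulation studies and tests use reduced budgets (e.g.
24 × 40 × 2), which recover the GCM attention simplex with mean absolute
error ≤ 0.10 at 288 trials.  SUSTAIN is fit with one learning-parameter
set over the whole problem chain; the parameters are then frozen and the
λ trajectories replayed to extract per-problem attention.  Likelihoods
are clipped at 1e−12; non-finite objective values lose tournaments
outright.

## Synthetic data

The generator defines the study conditions.  Behavior: 20 participants
by default; GCM participants draw attention from a flat Dirichlet
(α = 1, maximal realistic heterogeneity with a uniform mean) and respond
with c = 4, γ = 1 (mid-range of published 5/4 fits) over 288 trials;
SUSTAIN participants share learning parameters in the range typical of
fits to the six classic problems (r = 9.0, β = 1.25, d = 16.9,
η = 0.092) and differ through their stochastic trial orders and learning
histories; their true attention is the model's own late-window tuning
profile per rule.

Neural patterns: each binary dimension is assigned a selectivity map —
random ±1 sign patterns over units, orthogonalized across dimensions and
scaled to unit norm — and trial t's pattern is
`Σ_k κ·w_k·(±1)_tk·m_k + N(0, σ²)`, so the hypothesis under test (more
attention → more decodable) is the generative truth and κ = 0 is an
exact null.  Defaults: 100 units, σ = 1, five pattern runs of 16 trials
with every dimension balanced 50/50 within every run (5/4 pattern runs
are assembled from complementary stimulus pairs).  The coupling default
κ = 0.8 was calibrated once, by simulation under these defaults, so that
the linking slope of decoding accuracy on attention weight is ≈ 0.08 —
a weak, realistically sized brain–behavior effect.

Optional BOLD simulation: trial amplitudes convolved with the canonical
double-gamma HRF on a 2-s TR grid (3.5-s stimulus, jittered 4–8-s ITI),
plus AR(1) noise (ρ = 0.12).  What the generator does *not* emulate:
spatial autocorrelation, physiological noise, motion, retinotopy, or any
topographic structure — passing tests show the analysis chain is
correct and calibrated, not that real cortex behaves this way.

## Decoding and group inference

Single-trial patterns come either directly from the generator or from a
least-squares-separate GLM on simulated BOLD: per trial, one regressor
for that trial, one for all remaining trials, a linear drift and an
intercept; the trial's t-statistic map is retained.  At low noise the
recovered t-patterns correlate > 0.9 with the injected amplitudes; the
ceiling below 1.0 is inherent to LSS (the shared "other trials"
regressor misspecifies trial-to-trial amplitude variation).

Decoding uses a linear SVC (C = 1 for ROI analyses, C = 0.1 in the
searchlight) with leave-one-run-out cross-validation; features are
standardized with training-fold statistics only.  For the SHJ design the
classifier trains on all four runs per problem but only the two
late-learning folds are reported.  The toy searchlight decodes within
spheres of in-mask voxels (centers within the radius, inclusive) on an
array volume with voxel-size metadata, centers each accuracy at chance
and averages across dimensions.  Group maps are tested with a one-sample
sign-flip permutation test using the max-|t| statistic over voxels
(familywise control); when all 2^n sign patterns fit the permutation
budget the null is enumerated exactly.  ROIs are nested t-thresholds of
the group map.

## Linking analysis

The link table pairs each (participant, rule, dimension[, run]) attention
weight with the corresponding decoding accuracy: fold-averaged, one row
per participant × dimension for the 5/4 design; per retained run for the
SHJ design.  The mixed model (statsmodels MixedLM, REML) has fixed
effects for intercept, attention weight and dimension (plus rule and
centered run for SHJ) and random intercept + attention slope per
participant (plus run for SHJ).  A singular or non-converged fit falls
back to a random-intercept model and is flagged.  The parametric t on
the attention slope uses a conservative between-cluster df
(n_participants − 1); we treat the parametric p as secondary, because
inference rests on the permutation test.  Confidence intervals are Wald
by default or a participant-level (cluster) bootstrap (1,000 resamples
in the pipeline default).

**Attention-shuffle permutation.**  Whole weight vectors are reassigned
across participants with dimension (and rule) correspondence preserved —
each participant's simplex survives by construction — and the slope is
recomputed per permutation.  The reported percentile is mid-p (ties
count half), the identity assignment is part of the null set, and the
null is enumerated exhaustively whenever n! fits the permutation budget.
Two statistics are offered: the mixed-model slope (default, matching the
headline fit) and a Frisch–Waugh–Lovell residualized OLS slope with
participant intercepts, vectorized over permutations.  A permutation
test is valid for any statistic, so the fast statistic is used for the
large calibration studies.  Under the κ = 0 null the rejection rate at
the 0.95 percentile stays below nominal (measured 0.045 over 200
replicates).  At the default κ — deliberately calibrated to the weak
slope of ≈ 0.08 — measured power with 20 participants is about 0.73–0.78;
the suite's power check targets 0.8 and documents this shortfall rather
than strengthening the coupling, because a detectably stronger effect
would no longer represent the weak-coupling regime the defaults encode.
A studentized permutation statistic was evaluated and gives identical
power, so the limit is the information in the data, not the statistic.

**Salience control.**  Because each participant's perceptual-to-abstract
mapping is randomized, attention weights can be re-expressed per
perceptual feature (weights averaged over rules for the SHJ design) and
submitted to a repeated-measures ANOVA (pingouin) with feature as the
within-subject factor.  The Bayes factor for the null is the BIC
approximation exp(ΔBIC/2) comparing subject-only and subject+feature
linear models — directional evidence, not a default-prior Bayes factor.

## Numerical notes and limitations

Degenerate inputs are defined, not left to rounding: identical weight
vectors across participants make the permutation slope 0/0, which is
mapped to 0 for every permutation so the percentile is exactly 0.5; a
zero-variance salience table returns F = 0 with the null favored; cluster
competition underflow at extreme β resolves to winner-take-all.  All
randomness flows through explicit seeds (`numpy` Generators spawned from
a single SeedSequence); reruns are bit-identical.  Problem sizes in the
tests (e.g. 200-replicate calibration with 500 permutations, reduced GA
budgets) are the package's chosen desk-scale study conditions.  The
linking model's df approximation and the BIC Bayes factor are coarser
than the mixed-model machinery of a full statistical environment; both
affect only secondary quantities.  Real-data ingestion (NIfTI volumes +
ROI mask via nibabel) is supported at the pattern-matrix interface but
no preprocessing (motion correction, normalization, smoothing) is
provided.
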