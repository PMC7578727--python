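# Methods

## Problem setting and data model

The package targets two-class transcriptomic classification in the
small-n / large-p regime typified by the classic colon-tumour microarray
design: n = 62 samples (40 tumour, 22 healthy) by ~2000 genes, values
assumed already preprocessed (no raw-format parsing, background
correction or normalization is performed).  Labels use the 1/2 coding
with class 1 = tumour; the tumour class is the positive class for every
confusion-derived quantity.

The synthetic generator draws every gene i.i.d. Gaussian
N(0, noise_sd²) and shifts a chosen set of "planted" informative genes
by `effect_size × noise_sd` in the tumour class only.  Defaults —
62 samples, 2000 genes, 20 informative, class sizes (40, 22),
effect_size 2.0, noise_sd 1.0 — emulate the target study's shape with a
planted effect large enough that the signal is unambiguous at n = 62
(a standardized two-sample shift of 2 is detectable per gene at this
sample size).  What this model deliberately omits: gene–gene
correlation structure, heavy-tailed and heteroscedastic expression
noise, batch effects, and any nonlinearity of the class boundary.
Consequently, passing recovery tests demonstrates that the pipeline's
machinery works as specified — not that it would identify biologically
meaningful genes in real microarray data, where correlated probes and
weaker effects make selection much harder.

## Level 1: MRMR ranking

Mutual information (base-2 logarithm, i.e. bits) is estimated by the
plug-in rule on empirical joint distributions of per-gene discretized
codes.  Discretization is per-gene, equal-frequency, 3 bins by default
(the de-facto MRMR convention); equal-width binning is selectable.
Implementation notes:

- Equal-frequency bin boundaries are the interior quantiles; values
  tied with a boundary stay in the lower bin, which prevents
  heavily-tied genes (e.g. binary-valued ones) from collapsing into a
  single code.  Constant genes map to one code and carry zero MI.
- Set-level redundancy includes the diagonal (self) terms of the double
  sum exactly as defined — many MRMR implementations drop them, so this
  is documented explicitly.  The greedy criterion, by contrast, uses the
  conventional mean redundancy of a candidate against the already
  selected genes (no self term).
- Greedy selection uses the difference rule (MID),
  `score(g) = relevance(g) − meanRedundancy(g, selected)`, with the
  quotient rule (MIQ) available via `combination="quotient"`.  Ties
  break toward the lower gene index, making the ranking deterministic.
- The continuous mode replaces MI by the one-way ANOVA F statistic
  (relevance) and mean absolute Pearson correlation (redundancy).
  A gene with zero within-class variance but distinct class means gets
  relevance +inf (an absorbing maximum); constant genes contribute
  correlation 0 by convention, including their self term.

The pipeline ranks once on the full sample set (the "flat" protocol;
see Protocol below).  `sample_indices` arguments allow ranking on
training folds only for nested designs.

## Level 2: metaheuristic wrapper selection

All six optimizers minimize a black-box fitness over the box [0, 1]^d
with coordinate clipping after every move (bounds are configurable; the
self-test on the 5-dim sphere uses [−1, 1]^5 so the analytic minimum is
interior).  A position over the d-gene pool decodes to the subset of
its k largest coordinates (ties toward lower index), which guarantees
subsets of exactly k genes.  The wrapper fitness of a subset is
`1 − pooled 10-fold CV accuracy fraction` of the configured classifier,
with folds fixed by a seed, so fitness is a deterministic function of
(subset, seed); identical decoded subsets are cached within a run.

Best-so-far tracking lives outside each algorithm's population, so the
reported per-iteration trace is non-increasing for every algorithm even
though beetle antennae search and fruit fly optimization are not
intrinsically monotone.  All algorithms are driven by a single seeded
`numpy` generator: identical seeds reproduce runs bit-identically.

Per-algorithm notes and defaults (chosen so a 5-dim sphere run costs at
most ~5000 evaluations and one selection cell on desk-scale synthetic
data stays around a minute; every value is configurable):

- **IWO** — seeds per weed interpolate linearly between a_max (colony
  best) and a_min (worst), floored to an integer; dispersal s.d. decays
  from sigma_initial to sigma_final under modulation index m; merged
  colony truncated to the best c_max (stable sort, parents before equal
  children).  Defaults: pop 8, c_max 20, seeds 1–4, sigma 0.25 → 1e-3,
  m 3, 60 iterations.
- **TLBO** — teaching factor fixed at 2 (the stated choice of the
  source formulation) or drawn as round(1 + u); the per-learner random
  weight is drawn per dimension.  Greedy acceptance in both phases.
  Defaults: pop 20, 80 generations.
- **LCO** — single round-robin schedule by the circle method; match
  outcomes drawn against the closed-form win probability
  C_j = (f_k − f̂)/(f_j + f_k − 2f̂) with reference point f̂ = 0
  (appropriate for fitnesses in [0, 1]; clamped to the running minimum
  if a lower fitness appears, keeping probabilities in [0, 1]; both
  teams exactly at f̂ resolve 0.5).  The source description gives no
  formation-update equation, so a surrogate is used and clearly labeled
  as such: the loser moves `update_step` of the way toward the winner
  plus Gaussian jitter, accepted only on improvement; jitter decays
  geometrically across seasons so late seasons refine.  Defaults:
  10 teams, 60 seasons, step 0.5, jitter 0.1 → 1e-3.
- **BASO** — antennae probe symmetrically (z_r − z = −(z_l − z)
  exactly; probes are evaluated unclipped so the symmetry survives at
  box edges, and probe evaluations count toward the budget but do not
  update best-so-far).  The movement convention m_dir = −1 (default)
  moves the beetle toward the lower-fitness antenna; +1 selects the
  opposite reading of the ambiguous sign.  Antenna length decays as
  s′ = c1·s + 0.01 (fixed point 0.01/(1 − c1)), step as δ′ = c2·δ.
  Defaults: 3 beetles, 500 iterations, s0 0.2, δ0 0.3, c1 0.95,
  c2 0.98.
- **CSO** — pursuit move Y′ = Y + r·fl·(L_k − Y) when the awareness
  draw r ≥ AP, uniform-random evasion otherwise; memories update only
  on improvement, so per-crow memory fitness is non-increasing.
  Defaults: flock 20, 200 iterations, AP 0.1, fl 2.0.
- **FFO** — the two-coordinate original is generalized to d dimensions:
  candidates scatter uniformly within the current radius around the
  center; the smell-concentration judgement value SC = 1/‖position‖
  (epsilon-guarded at the origin) is computed per candidate, while the
  quantity actually minimized is the wrapper fitness at the candidate;
  the center relocates only when the best candidate beats the
  historical best.  The scatter radius decays geometrically
  (0.3 → 1e-3 by default over 400 iterations): with a fixed radius the
  gated center cannot refine below the scatter resolution, so the decay
  is a deliberate design addition.

## Classification and metrics

Classifier adapters wrap scikit-learn with pinned defaults: random
forest (100 trees), AdaBoost (50 stumps), logistic regression (lbfgs,
max_iter 1000), CART decision tree, QDA.  QDA's class covariances are
singular whenever a class has fewer samples than the subset has genes
(always true here for k ≥ 22); on that failure the adapter refits with
the eigen solver and Ledoit–Wolf shrinkage (`shrinkage="auto"`), which
is the documented regularized fallback.  Stochastic classifiers are
seeded.

Cross-validation is stratified (with 22 minority samples, unstratified
10-fold splits would often produce one-class test sets) and confusion
counts are pooled over folds rather than averaged per fold (per-fold
percentages on 6-sample folds are too unstable to be meaningful).

The metric suite decomposes the pooled table into PC (percent correct),
MC (percent false negatives — missed tumours) and FA (percent false
positives), the only sample-level mapping under which the derived
sensitivity/specificity formulas behave as intended and the three parts
sum to 100.  PI = 100(PC − MC − FA)/PC may be negative and is undefined
at PC = 0 (flagged per cell, not fatal).

**A null-behaviour caveat worth knowing:** because Sensitivity and
Specificity are both built from PC, a classifier that degenerates to
majority-class prediction on the 40/22 design scores Specificity 100
and "Accuracy" (the sensitivity/specificity mean) around 72 *at
chance*.  The proportion-correct percentage PC has the conventional
null (~50, at most the 64.5% majority rate), so chance-level controls
in the tests and the acceptance script are asserted on PC, and Accuracy
values near 70 on permuted labels should not be read as signal.

## Protocol: flat versus nested

The default protocol is *flat*: MRMR ranks on all samples, the wrapper
fitness uses 10-fold CV on all samples, and the reported metrics reuse
the same folds.  This mirrors the apparent protocol of the study the
pipeline reproduces and is intentionally optimistic — the selection
step has seen the evaluation folds, so reported accuracies are biased
upward relative to truly held-out performance.  All selection and
evaluation entry points accept `sample_indices`, which is sufficient to
build a nested (outer-fold) protocol when unbiased estimates matter.

## Identifiability limit of wrapper recovery

A finding from the package's own experiments, documented here because
it bounds what wrapper selection can prove: with 62 samples, an
accuracy-based wrapper fitness stops being informative about the
planted-gene set well before full recovery.  At planted effect 2.5 the
CV error of every supported classifier reaches exactly 0 once ~4 of 10
planted genes are in the subset, so all larger planted fractions are
indistinguishable; at moderate effects (~1.0) the plateau is replaced
by fold-noise overfitting — subsets containing noise genes can beat the
true planted set on the fixed folds.  In both regimes the selected
subsets reliably beat random subsets of equal size and are strongly
enriched for planted genes (~4–6 of 10 at k = 10 over a 50-gene pool),
but full recovery of the planted set is not achievable through this
objective, and the corresponding acceptance check records that fact.

## Numerical and degenerate-input conventions

- MI of empty or mismatched vectors, empty gene sets, fold counts
  exceeding the sample count, duplicate or out-of-range gene indices,
  one-class training folds and non-finite fitness values all raise
  errors naming the violated constraint.
- IWO's seed-count rule returns a_max when all colony fitnesses are
  equal (the interpolation is otherwise undefined).
- Dataset round trips are bit-exact: floats are written with 17
  significant digits and parsed with a correctly-rounded converter.
- Per-cell seeds in the pipeline derive from SHA-256 of
  (master seed, algorithm, classifier, k), so cells are independent and
  individually reproducible from the manifest; every derived seed is
  below 2³¹.

## Scale of the packaged experiments

The self-contained experiments run at desk scale by design: sphere
convergence uses 5 dimensions and ≤ 5000 evaluations per run; recovery
experiments use 62 × 200 (MRMR) and 62 × 50 (wrapper, ~700 evaluations)
fixtures over 10 generator seeds; the end-to-end pipeline demonstration
uses 62 × 2000 with a 200-gene pool, k = 30 and an 800-evaluation
budget.  These sizes exercise every code path of the full-scale
configuration (pool 600, k ∈ {30, 60, 90}, six algorithms × five
classifiers), which is available through the same interfaces and
configuration files.
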