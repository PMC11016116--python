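# Methods

## Model and assumptions

The package implements a population metaheuristic for box-bounded
minimization of black-box objectives, plus a binary wrapper for gene
selection. No gradient, smoothness or unimodality assumptions are made;
the only contract is that the objective returns a real number for any
point in `[lb, ub]^D` (non-finite returns are recorded as +inf and can
never become the incumbent best).

The hybrid maintains up to three groups of NP candidates seeded from one
uniform sample of the box: an investigation group and a pursuit group
evolved by the forensic-investigation rules with greedy acceptance, and
an inspector group evolved by the slime-mould rule with unconditional
replacement (faithful to the original slime-mould formulation, where
selection pressure comes from the fitness-ranked weights rather than
from greedy acceptance; `greedy_inspectors=True` flips this). The groups
interact only through the shared global best position and fitness, which
is refreshed after every single evaluation. Each iteration runs
investigation → pursuit → inspector.

Progress for the adaptive coefficients `a` (vb half-range) and the vc
half-range is defined as `evaluations_used / GEN`, because the stopping
criterion is an evaluation budget, not an iteration count; phases that
would overshoot the budget are truncated mid-phase and the run ends
cleanly. With the budget defined this way the very first inspector
update already has progress > 0; `arctanh(1 − progress)` is additionally
clamped at argument `1 − 1e−12` so a hypothetical progress of exactly 0
stays finite.

## Tunable parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `NP` | 30 (continuous), 20 (gene selection) | members per group | 30 is the published protocol for continuous benchmarks; 20 keeps the wrapper's classifier cost manageable on small-sample data |
| `GEN` | 300,000 (continuous), 2,000 (gene selection) | objective evaluations | 300,000 assessments is the published continuous budget; the gene-selection budget is 100 iteration-equivalents of NP = 20 |
| `z` | 0.03 | restart probability | fixed value of the original slime-mould rule |
| `log_base` | 10 | — | the original slime-mould reference uses log10; natural log is config-switchable |
| `gate_a2` | on | — | step A2 relocates member i only when `Prob_i < u`, `u ~ U[0,1]`: low-quality members relocate more often |
| `vector_draws` | on | — | random multipliers r1–r8 drawn per dimension (the common reading in this literature); scalar-per-member available |
| `alpha` / `beta` | 0.95 / 0.05 | fitness weights | published weighting: classification error dominates the size penalty |
| `folds` | 10 | CV folds | published protocol (stratified) |
| `k` (KNN) | 5 | neighbours | unspecified in the protocol; 5 is the common choice in the wrapper-selection literature, configurable |
| search box for binary runs | `[−4, 4]^d` | transfer units | `T(4) ≈ 0.9993` saturates the transfer; any symmetric box works, this one is fixed for reproducibility |

## Numerical and design choices

- **Boundary repair**: coordinate-wise clipping to `[lb, ub]` after every
  position update. The update rules themselves do not prevent box
  violations (step A2's `X_best + X_d` in particular can double
  magnitudes near the best; it is implemented literally, not averaged).
- **Greedy ties** keep the incumbent, avoiding drift under equal fitness.
- **Peer draws** (k,h / d,e,f / partner r) are uniform without
  replacement, excluding the focal member, re-drawn per member per
  iteration. The slime-mould helpers X_A, X_B are drawn *with*
  replacement and may equal the focal member.
- **RNG**: one `numpy` Generator per run, seeded from the config. Draw
  order is fixed (documented in each phase function), so identical seed
  and config give bit-identical results.
- **Weight matrix**: rows are filled in rank order; the superior half for
  odd NP is the top `ceil(NP/2)` ranks; `bF == wF` yields exact ones.
  `p = tanh|S(i) − DF|` is clamped to the largest double below 1 because
  tanh saturates in floating point beyond gaps of ~19.
- **Selection probabilities** treat +inf fitness markers as probability
  0 (they never gate-in a relocation toward the best).
- **Binarization**: the standard V-transfer rule `bit = [u < |tanh x|]`.
  A literal fixed-0.5-threshold rule that ignores the position is kept
  as `literal_threshold_binarize` for auditability only — it degenerates
  the search to random masks. Empty masks are repaired by setting one
  uniformly chosen bit, keeping the classifier contract total.
- **Wilcoxon signed-rank**: zero differences dropped; exact null for
  n ≤ 25 when |differences| are untied, exact sign-flip enumeration for
  tied magnitudes up to n = 16, normal approximation with tie correction
  otherwise. Friedman ranks are mid-ranked on ties; ARV is the mean rank.
- **Benchmark battery**: a stand-in set spanning the four standard
  categories (unimodal, multimodal, hybrid-like, composite-like). The
  official CEC2017 suite needs distributed shift/rotation data files and
  composition machinery and is not bundled; every base function here is
  re-centred to have its minimum of 0 at the origin so the shift/rotate
  wrapper `f(R(x − s))` places the optimum at `s` with unchanged value.
  External evaluators can be plugged in via `register_function`.

## Gene-selection protocol

The published evaluation protocol partitions samples into training,
validation and test sets "according to a certain ratio" that is not
stated. Two modes are therefore shipped, neither asserted as canonical:

- `holdout` (default): stratified 80/20 outer split; the optimizer's
  fitness is the 10-fold CV error on the 80 % portion and the reported
  error is the held-out 20 % error of the best mask.
- `cv`: fitness and reported error are both the 10-fold CV error on all
  samples.

Within a run the CV split is fixed (seeded), so the objective is
deterministic up to the stochastic binarization, and repeated runs use
consecutive seeds. KNN errors are memoized per mask within a run.

## Synthetic data: what it does and does not emulate

`generate_expression_dataset` produces Gaussian class-conditional
matrices: informative genes get per-class mean offsets spaced
`class_separation` noise-SDs apart (class order permuted per gene),
redundant genes are noisy copies of informative parents at correlation
≈ 0.9, the rest is i.i.d. noise; columns are shuffled and the informative
indices returned as ground truth. A Gaussian model was chosen over
log-normal intensities because it keeps the chance-level and
wide-margin oracles analytic; a `log_intensity` flag offsets values to a
log2-microarray-like scale. Batch effects, missingness, heavy tails and
realistic co-expression networks are *not* modelled, so passing tests
demonstrate correct optimizer/wrapper mechanics, not performance on real
chips.

A property of the fitness worth stating explicitly: with a wide class
separation (e.g. 6 noise-SDs), a *single* informative gene already
achieves zero CV error, so the global optimum of
`0.95·error + 0.05·l/d` is a singleton informative mask. A
well-converging wrapper therefore reports very small subsets and *low*
recall of the full planted set — recovering every informative gene is
not an objective this fitness rewards. Recall of the planted set is
reported as a diagnostic (`informative_recall`), not optimized.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` use scaled-down budgets chosen
as the package's own smoke-test regime: sphere/Rastrigin in D = 10 with
NP = 30 at 30,000 / 60,000 evaluations over 10 paired seeds, and gene
selection on 60 × 200 synthetic matrices with NP = 20 at 2,000
evaluations over 5 seeds. These demonstrate convergence behaviour and
orderings, not the absolute values attainable at the full 300,000
evaluation protocol.

## Known limitations

- Minimization only; no constraints beyond the box; single-objective.
- The inspector phase's unconditional replacement means group members can
  worsen between iterations (the global best never does).
- Wall-clock cost of the wrapper is dominated by KNN cross-validation;
  budgets beyond ~10^4 evaluations on thousands of genes are expensive.
- Low-dimensional large-sample datasets and many-class problems are
  outside the method's sweet spot.
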