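# Methods

## The model

`shoalbayes` implements a two-stage model of individual decisions in animal
groups, exercised throughout on collective binary choices of the kind made
by shoaling fish (two refugia, left/right arms of a Y-maze, and so on).

**Stage 1 — Bayesian estimation.** A focal individual estimates the
probability that option *x* is the better of two options from two sources:

* private (non-social) evidence, summarised by the likelihood ratio
  `a = P(private data | x best) / P(private data | y best)`;
* social evidence: the behaviours currently displayed by the other group
  members.  Under the *independence assumption* (each observed behaviour is
  conditionally independent given which option is best), a behaviour class
  `k` displayed by `n_k` individuals contributes a factor `s_k ** n_k`, where
  `s_k = P(behaviour k | x best) / P(behaviour k | y best)` is the
  behaviour's **reliability**.

The posterior is a logistic function of the log odds:

    P(x best) = 1 / (1 + (a * S)^-1),      S = prod_k s_k ** n_k.

**Stage 2 — probability matching.** The individual chooses *x* with
probability equal to `P(x best)`.  This is the only decision rule
implemented: it adds no parameters, and deterministic threshold rules are
inconsistent with the trial-to-trial variability of the experiments this
family of models was built for.

Specialising the reliabilities gives the named variants:

| variant           | rule for `P(go to x)`                                | parameters |
|-------------------|------------------------------------------------------|------------|
| `symmetric`       | `1/(1 + s^-Δn)`, `Δn = n_x - n_y` (replicas pooled)  | `s` |
| `two-replica`     | `1/(1 + ρ s^-Δn_fish)` (attractive replica at x)     | `s, ρ` |
| `asymmetric`      | `1/(1 + a^-1 s^-Δn)`                                 | `a, s` |
| `asymmetric-full` | `1/(1 + a^-1 s_x^-n_x s_y^{n_y} s_u^-n_u)`           | `a, s_x, s_y, s_u` |
| `fish-replica`    | `1/(1 + a^-1 s_f^-Δn_fish s_rep^-Δn_rep)`            | `a, s_f, s_rep` |
| `multi-option`    | `P_i = w_i s^{c_i} / Σ_j w_j s^{c_j}`                | `s` (+ weights) |

Every richer variant reduces exactly to its parent at the neutral settings
(`ρ = 1`, `a = 1`, `s_u = 1`, `s_f = s_rep`), and the reductions are tested.

In the two-replica rule only the ratio `ρ = s_r / s_R` of the two replicas'
reliabilities is identifiable.  We define `ρ` so that `ρ < 1` pulls the
decision toward the attractive replica's side; the ten bundled attractiveness
ratios for the classic replica pairs are all below 1 under this convention,
which fixes the sign unambiguously.

**Group process.** Group outcomes follow from applying the individual rule
*sequentially*: replicas are forced deciders placed first; each real fish
then decides with the up-to-date counts; the final configuration records the
number of fish (not replicas) at *x*.  "Undecided" individuals are exactly
the fish still waiting their turn; their reliability defaults to 1
(uninformative), because model comparison rejects an indecision-reliability
parameter on this kind of data.  Exact outcome distributions come from
enumerating the decision tree; for count-state (independence) models the
tree collapses into a dynamic programme over `(n_x, n_y)`.

**Dependency model.** The recursive variant drops the independence
assumption: the focal individual evaluates the ordered decision *sequence*,
modelling each earlier decider as a probability-matcher who carried an
assumed private bias `a_dep` toward the best option (its reciprocal under
the rival hypothesis — the reciprocal constraint is what keeps the symmetric
model at a single parameter).  Each observed decision multiplies the social
term by its likelihood ratio under the two hypotheses, so histories with
equal head-counts can carry different evidence.  The model predicts
minority following: after a long one-sided run, conformist choices are
nearly uninformative and a lone dissenter can flip the posterior.  The model
has exactly as many free parameters as the matching independence model.

When a trial starts with replicas already committed, the fish cannot know
the order in which that configuration arose.  We average the social term
over all orderings consistent with the counts, weighting each ordering by
its probability under the hypothesis-symmetric marginal (the mean of its
probabilities under "x best" and "y best").  The weighting is a genuine
design choice — uniform averaging is also plausible and is available via
`weighting="uniform"` — but the probability-weighted form is symmetric and
reduces exactly to the single-path value when the ordering is unique.  Path
enumeration is exact and refuses more than 12 initial deciders rather than
approximating.

## Shape analysis

Final-configuration histograms are classified on the proportion-at-x axis
after aggregation into `B` equal-width bins (`[l, r)`, last bin closed, mass
conserved exactly).  The classifier reduces the bin masses to their monotone
runs with an absolute plateau tolerance of 1e-9 — exact enumeration near
`s = 1` produces exact ties that must read as plateaus — and labels:

* **U** — falls then rises with the valley at the centre bin(s);
* **J** — monotone toward one edge, *or* falls-then-rises with an off-centre
  valley.  The second clause matters: the exact model distribution in a
  biased set-up always keeps a small rise at the minor edge (the J's hook),
  and demanding strict monotonicity would leave precisely the distributions
  the literature calls J-shaped unlabelled;
* **bell** — a single interior maximum;
* **M** — rise/fall/rise/fall with both interior peaks above the centre and
  above both edges;
* **flat** — everything else (ambiguous), including exact uniformity.

Ties break toward the simpler label (U or bell over M).  "Centre" means the
middle bin for odd `B` and the two middle bins jointly for even `B`.

An M shape needs at least five bins to be expressible, and coarse binning
can convert a true M into an apparent U or bell — the binning sensitivity
the phase diagram quantifies via the minimum bin count at which M appears.

**Shape dynamics.** The shape is tracked as deciders accumulate at a fixed
bin count (default 5), evaluating only at stages where the `t + 1` distinct
outcomes divide evenly into the bins (`t + 1` a multiple of `B`).  At other
stages unequal bin occupancy injects spurious peaks that reflect the binning
rather than the process.  Under this protocol the three regimes are cleanly
realized on a scan of `s ∈ [1.05, 10]` with up to 30 deciders: U from the
start (roughly `s ≳ 1.8`), M then U (`s ≈ 1.6–1.75`), and bell, M, U
(`s ≈ 1.3–1.45`).

One deliberate deviation from a tempting summary statistic: the probability
of a *unanimous* outcome is not monotone in group size (it is 0.714, 0.579,
0.555 at `N = 2, 4, 8` for `s = 2.5`).  What grows with `N` is the
steepness of the U — the edge-to-centre probability ratio rises 1.25 →
2.64 → 15.9 over the same sizes — and that is the property the package
asserts.

## Inference

The likelihood of a parameter vector is the product over conditions of the
multinomial probability of the observed count table under the exactly
enumerated outcome distribution.  The multinomial coefficient is included;
it is parameter-free and cannot affect fits or rankings.  Predicted
probabilities are floored at 1e-300 inside logarithms; a fit that touches
the floor is flagged rather than silently accepted.

Fitting is coordinate ascent: each free parameter is maximised separately by
bounded scalar optimisation in log-parameter space (all parameters are
positive ratios), sweeping until the log-likelihood improves by less than
1e-8 or 200 sweeps elapse.  The ascent is monotone by construction and the
trace is kept.  A multi-start wrapper draws log-uniform initial points to
detect local maxima; on this model family the 1- and 2-parameter likelihood
surfaces are smooth and unimodal (verified on a grid in the tests).

**BIC.** Model comparison uses `BIC_i = L_i - (k_i / 2) ln n` (select the
largest).  `n` counts *measurements*: one per repetition, totalled across
conditions (380 for the 19-condition × 20-repetition design) — each
repetition is one recorded final configuration.  A `bic_classic` accessor
returns the common `-2L + k ln n` form; the two orderings are reverses of
each other.  BIC weights are softmax-normalised scores computed in shifted
log domain.  Frozen parameters (the fixed-ratio protocol for replica pairs)
are excluded from `k`.

Confidence bands are parametric-bootstrap quantiles: simulate replicate
experiments at the design's repetition counts from the fitted model and take
per-configuration empirical quantiles.

## Synthetic data

No raw data from the source experiments are deposited anywhere, so the
package generates its own studies under the published designs:

* **symmetric**: group sizes {2, 4, 8} × replica ratios
  {1:1, 2:2, 0:1, 1:2, 0:2, 1:3, 0:3}, 19 of the 21 cells, 20 repetitions
  per condition.  Which two cells were absent from the original experiments
  is not recoverable from the published text; we omit (N=2, 2:2) and
  (N=2, 0:3) as the reconstruction.  The specific choice has no measurable
  effect on recovery or selection results.
* **two-replica**: ten replica pairs × three group sizes, attractive replica
  to x, with the ten bundled attractiveness ratios.
* **predator**: group sizes {2, 4, 8} × 0–3 replicas toward the safe side;
  the threat enters through the non-social term `a` of the fitted model.

Generation is seeded per-study; per-condition streams are spawned from the
study seed, so a study is reproducible from a single integer.  The canonical
generating parameters are `s = 2.5` (the reliability the real data are best
fit by, meaning conspecifics assumed right 2.5 times as often as wrong) and
`a = 3` for asymmetric studies.

What the generator does *not* emulate: within-trial timing, spatial
trajectories, individual heterogeneity, or fish that never commit.  Passing
recovery and selection tests therefore demonstrates the statistical
machinery under the model's own assumptions — that the pipeline is
self-consistent at the experimental sample sizes — not that the model is
true of any particular dataset.

## Numerical choices and problem sizes

* All choice probabilities are computed as `expit` of summed log factors —
  overflow-safe for arbitrarily large counts; parameters are validated
  strictly positive (floor 1e-12) rather than clipped.
* Exact enumeration is capped at N = 20 for count-state models and N = 12
  for sequence-state (dependency) models; beyond that a capacity error is
  raised, never an approximation.
* Expected-count fixtures round `probability × repetitions` with
  largest-remainder correction so every condition keeps its exact total.
* The bundled studies use the experimental scale throughout (19–30
  conditions, 20 repetitions); replicate counts for stochastic checks are
  50 studies for recovery and 50 for selection, sizes at which medians and
  win-rates are stable to the asserted tolerances.

## Limitations

* The shape classifier is an operational reconstruction; near region
  boundaries of the (s, N) plane its labels may differ from any particular
  published rendering of the diagram.
* The dependency model's initial-state path averaging and the BIC `n`
  convention are documented choices among defensible alternatives (both
  alternatives are implemented behind switches/accessors).
* The multi-option rule is the symmetric product form with optional
  per-option weights; per-behaviour, per-option reliability matrices are not
  modelled.
* Only the sequential decision scheme is implemented; simultaneous decisions
  and standing indecision were reported to make no relevant difference and
  are out of scope, as are spatial/continuous-motion extensions.
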