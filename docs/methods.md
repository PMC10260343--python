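# Methods

This note documents the statistical machinery implemented in `shiftcrm`,
the defaults it ships with, the numerical choices made where behaviour was
genuinely open, and what the simulation results do and do not demonstrate.

## Model and conduct

**Grid and orderings.** The trial operates on a 2 x L grid (L = 7 by
default). DLT probabilities are assumed nondecreasing in dose level within
each row and, at a fixed level, at least as high in row 2 (combination
therapy) as in row 1 (monotherapy). The MTD of a row is the level whose DLT
probability is closest to the target θ (default 0.30); when two levels are
exactly equidistant from θ the lower one is chosen, on safety grounds.
Distances to θ are rounded to 10 decimals before comparison so that
decimal-exact ties (e.g. 0.25 vs 0.35 around 0.30) resolve by the tie rule
rather than by floating-point representation noise.

**Skeletons.** A skeleton is calibrated with the indifference-interval
recursion for the empiric power model: q[ν] = θ, and moving upward q[k+1]
solves q[k+1]^{a*} = θ+δ where a* solves q[k]^{a*} = θ−δ (downward with the
two bounds exchanged). Defaults: δ = 0.05, ν = 4, base length L + max|shift|
= 8. With δ = 0 the recursion is the identity. Both δ and ν are exposed in
the design configuration, since different trials calibrate differently.

**Shift-structured working models.** One working model per hypothesized
MTD offset s ∈ {0, −1} (configurable), all cut from the single calibrated
base vector: row 1 takes positions 1..L, row 2 takes 1−s..L−s. This
guarantees column ordering and makes the per-row skeleton argmins differ by
exactly s, so a final recommendation can never reverse the rows. A
consequence worth knowing: the two models share the row-1 skeleton, so data
confined to row 1 produce exactly tied likelihoods and the model is chosen
by the documented uniform tie-break (two fits whose log-likelihoods agree
to within 1e−9 relative are treated as tied).

**Estimation.** The power parameter is written p = q^{exp(a)} so that the
power is positive with a unconstrained; a is bounded to [−10, 10] (powers
between ~4.5e−5 and ~2.2e4), which is far wider than any data-supported
value. The binomial log-likelihood is concave in exp(a), hence unimodal in
a, and is maximized by golden-section search to an interval of 1e−9 (a
numba-compiled kernel, since simulations perform millions of fits).
Likelihood evaluation uses per-cell counts, so its cost does not grow with
the sample size. Estimation requires heterogeneous data (at least one DLT
and one non-DLT); before that the likelihood has no interior maximum and
the design is in its prespecified escalation stage.

**Allocation.** In the modeling stage all working models are refit after
every patient, the model with the largest likelihood is selected (equal
prior model weights by default — pure maximum likelihood; weights are
configurable), the selected fit recommends argmin_j |p̂_rj − θ| in each
row, and the next patient is randomized 1:1 between the two row
recommendations. No dose-skipping restriction is imposed by default (model
recommendations are followed as-is, which is how a never-tried row-2
combination can be assigned directly); a `max_step` option caps per-row
escalation for conservative use.

**Initial stage.** Cohorts of one, starting at (row 1, level 1), escalating
along row 1 then along row 2. Edge cases the design must define: if the
first patients only ever experience DLTs there is no lower dose to retreat
to, so the lowest combination is repeated (in practice the safety rule
stops such trials after three patients); if the whole grid is exhausted
without a DLT the trial parks at the top combination. A trial that ends
with zero DLTs recommends the highest tried level per row; an all-DLT trial
recommends nothing.

**Safety stop.** The trial stops, recommending no MTD in either row, when
at least 3 patients have been treated at the lowest combination and the
exact one-sided lower 90% Clopper–Pearson bound on its DLT rate exceeds θ.
Confidence level and minimum exposure are configurable. This rule is a
documented stand-in: reporting conventions for early stopping exist for all
three designs, but no stopping rule for the shift design is pinned by an
external source.

## Comparators

**3+3.** The classic rule table applied independently per row, cohorts of
three: 0/3 escalate; 1/3 expand to six; ≤1/6 escalate; ≥2 stop with the
next-lower level as MTD (none when stopping at level 1 — counted as a
per-row safety stop); clean escalation through the top level selects the
top level. No de-escalation expansion cohorts — the simplest canonical
variant.

**BOIN.** Independent per row, cohorts of one, n = 20 per row. Boundaries
λ_e, λ_d from the standard closed forms with φ1 = 0.6φ, φ2 = 1.4φ
(λ_e ≈ 0.2364, λ_d ≈ 0.3586 at φ = 0.30). Decisions depend only on the
current level's observed rate. A level with ≥3 patients is eliminated
(together with all higher levels) when the Beta(1+x, 1+n−x) posterior puts
more than 0.95 probability above φ; eliminating level 1 stops the row. MTD
selection isotonically adjusts posterior means over tried, non-eliminated
levels (weights = inverse posterior variance, pool-adjacent-violators via
scikit-learn) and takes the level closest to φ, ties low. The selection
prior is the near-vague Beta(0.05, 0.05) — the interval method's own
selection default — because a uniform prior's shrinkage toward 0.5 badly
distorts estimates at levels tried only once or twice; Beta(1,1) is used
only where the elimination rule specifies it.

**Reversal.** Defined as both rows selecting an MTD with the row-2 level
strictly above the row-1 level; trials missing either selection do not
count. It is identically zero for the shift design by construction, which
the test suite asserts over 10,000 simulated trials.

## Random dose–toxicity curves

The ensemble generator emulates constrained random curve generation whose
defining outputs are: valid ordered 2 x L matrices, row MTDs equal or one
level apart, and a mix of steep and flat shapes. Mechanism: the intended
row-1 MTD location is uniform over levels and the intended shift uniform
over the allowed set (clipped at the grid edge); that pair is drawn once
and held fixed while candidate matrices are rejected, so the realized pair
frequencies follow the stated law exactly (verified by chi-square over
10,000 draws). Each row anchors its MTD probability in θ ± 0.04 and fills
outward with random increments: Gamma(2, 0.04) (mean 0.08) adjacent to the
MTD and heavier-tailed Gamma(1.2, 0.10) elsewhere, damped near the unit
bound going up and allowed to drop steeply toward 0 going down. All
dispersion controls are configurable. Curves are rejected until row
monotonicity, column ordering, the intended MTD locations, and the shift
constraint all hold.

What this emulation does *not* guarantee: agreement with any particular
published ensemble. Ensemble-level operating characteristics (especially
comparator reversal rates, which are sensitive to how flat the curves are
near θ) can differ by several percentage points from numbers obtained with
a different generator even when single-scenario results agree closely.

## Simulation engine

Patient outcomes are Bernoulli draws at the assigned combination's true
probability. Trial t of stream s under base seed B uses
`SeedSequence(entropy=B, spawn_key=(s, t))`, so any single trial is
re-runnable in isolation and streams share no state. Operating
characteristics follow the field's conventions: PCR counts trials selecting
the row's true MTD (safety-stopped trials count as incorrect); PCA is the
per-trial fraction of enrolled patients treated at the row's true MTD, so
the overall PCA is the sum over rows; the average PCR is the unweighted
row mean. Zero-correct and at-least-one-correct percentages partition 100%.

Problem sizes used by the shipped tests and the acceptance script: 1,000
trials for single-scenario operating characteristics, 10,000 trials for the
structural no-reversal check, and a 50-curve ensemble with 200 trials per
curve and design.

## Sample-size calculator

The calculator characterizes a CRM trial by the desired average probability
of correct selection (PCS), θ, the number of test doses K, and an effect
size ψ defined as the odds ratio of DLT rates at neighbouring doses. It
returns the smallest N at which a single-agent two-stage likelihood CRM —
the same design class this package conducts — reaches the PCS goal,
averaged over K scenarios placing the MTD at each dose in turn with
logit-spaced neighbours (logit(θ) ± multiples of log ψ). The skeleton uses
ν at the middle dose and δ equal to a quarter of the ψ-induced probability
gap. Full trajectories are simulated once under a fixed internal seed
(common random numbers), and the PCS-versus-n curve is read off by
truncation, making the result a deterministic, monotone function of the
specification. For the configuration (PCS 0.50, θ 0.30, K 14, ψ 1.78) this
calculator returns N = 30; published calculators implementing closed-form
approximations fit to their own reference simulations can return larger
values for the same inputs (simulation-based and formula-based calculators
agree in ordering and scale but not to the patient), so N should be read as
this package's own estimate of the accuracy/size trade-off, not as a
reproduction of any specific published table.

## Known limitations

- Only 2-row grids are conducted and tested; the working-model construction
  generalizes to more rows but is deliberately not exposed.
- The shift design's early-stopping rule is this package's documented
  choice; trials with a protocol-specified rule should configure or replace
  it.
- Bayesian CRM variants (posterior-mean estimation for conduct),
  time-to-event outcomes, and efficacy-integrated extensions are out of
  scope.
- The random-curve generator reproduces constraint structure, not any
  specific published ensemble (see above).
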