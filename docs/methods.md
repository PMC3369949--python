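# Methods

`sweepint` models a well-mixed population of `N` haploid, obligately sexual
individuals adapting through beneficial mutations that arise at genomic rate
`U` per genome per generation on a continuous linear genetic map of total
length `R` Morgans.  Fitness is multiplicative: an individual carrying
mutations with advantages `s_i` has fitness `prod_i (1 + s_i)`.  Mutations
are never exhausted and there are no deleterious mutations, epistasis,
dominance (the model is haploid), population structure, or changes in `N` —
the model is a deliberate best case for adaptation, built to isolate one
question: how much does linkage between simultaneous selective sweeps
(Hill–Robertson interference) limit the rate of adaptive substitution?

## The individual-based simulator (`sweepint.sim`)

Discrete generations.  Each generation:

1. Relative fitness is computed from segregating mutations only; factors
   from fixed mutations are shared by everyone and cancel.  Optionally each
   individual's log fitness receives non-heritable noise `N(0, v_n)` drawn
   fresh every generation.
2. `N` parent pairs are drawn; each parent is chosen independently with
   probability proportional to fitness (polygamous mating).  Because the two
   draws are independent, self-pairing occurs with probability
   `w_i^2 / (sum w)^2`; excluding it would change the offspring-number
   variance, and nothing in the model motivates exclusion.
3. Each pair produces one offspring by meiosis with a Poisson(`R`) number of
   crossovers at uniform map positions; the offspring takes alternating
   parental segments starting from a fair-coin parent.
4. A Poisson(`N U`) number of new mutations arise at uniform positions
   (infinite sites on a continuum; coinciding positions have probability
   zero and are asserted against rather than handled), each in a uniformly
   chosen newborn, with fixed effect `s` or an exponential effect of mean
   `s_mean`.
5. Copy numbers are updated; mutations at count 0 are recorded as lost and
   mutations at count `N` as fixed — their `log(1+s)` moves to a fixed-
   background accumulator and their column is removed.

The population is stored as an `N x M` boolean presence matrix over the `M`
currently segregating mutations, with per-column position/effect arrays kept
sorted by map position; crossover inheritance is evaluated for all `N`
offspring at once by counting, for every (offspring, locus) pair, the parity
of crossovers to the left of the locus.  This keeps the per-generation cost
at a few vectorized `N x M` array passes and makes runs with `N ~ 10^3–10^4`
and tens of thousands of generations take seconds to minutes on one core.
Runs are bit-reproducible given the seed (a single PCG64 stream).

Simulations start from a purely wild-type population; measurements discard a
burn-in, by default `max(1000, 10/s)` generations, chosen so the cumulative
substitution count is well into its linear (steady-state) regime for the
parameter ranges exercised here.  The burn-in is configurable and recorded
in the run metadata.

A neutral, multi-allelic marker locus can be carried alongside (used by the
painting experiment); it is inherited through the same crossover machinery
and never touches fitness.

### Problem sizes used in the tests

The package's checks run at desk scale: baseline-recovery uses `N = 1000`,
`s = 0.05`, `R = 10` with ~10^4 resolved mutations; the scaling-collapse
comparison uses `(N, U) = (2000, 10^-3)` vs `(4000, 5x10^-4)` at baseline
density 0.2 per Morgan; painting uses `N = 200` with 100 replicates.  These
sizes give binomial/counting errors of a few percent, which is what the
corresponding assertions are calibrated to.

## Observables (`sweepint.observables`)

The density of sweeps `Lambda` is the number of fixations per Morgan per
generation in a post-burn-in window.  Fixation probabilities are estimated
from mutations that *originated* in the window and were resolved by the end
of the run (still-segregating mutations are right-censored: including them
would bias the estimate in either direction depending on the cut), with
exact Clopper–Pearson intervals.  Sojourn times between frequencies use the
last up-crossing of the lower bound, ignoring early stochastic dips, which
is the frequency range in which sweeps actually interfere.

The painting experiment's coalescence time is fitted on the
*replicate-averaged* heterozygosity: the expectation of `H` decays exactly
at the pairwise coalescence rate, whereas the log of a single stochastic
trace decays faster by a Jensen term `Var(dH)/2H^2` of the same order as
the signal itself (fitting replicates individually and averaging the rates
underestimates `T2` by a factor ~2 even for pure drift).  Standard errors
come from bootstrap resampling over replicates; the late-time fit window
starts where a rolling log-linear slope stabilizes to within 5%, which
absorbs the initial drift-only epoch before draft dominates.  Heritable
variance in log fitness excludes the injected non-heritable noise by
construction.

## Interference kernel (`sweepint.kernel`)

The fate of a rare focal allele (advantage `s_f`) near a single sweep
(advantage `s`, deterministic logistic trajectory `x(t)`) is governed by a
two-background branching process.  Writing `p_b`, `p_B` for fixation
probabilities on the ancestral and sweeping backgrounds, the backward
equations in sweep-scaled units (`tau = s t`, `rho = r/s`,
`beta = s_f / s`, `q = p / 2 s_f`) are

    dq_b/dtau = -[ (beta - x) q_b        - beta q_b^2 + rho x (q_B - q_b) ]
    dq_B/dtau = -[ (beta + 1 - x) q_B    - beta q_B^2 + rho (1-x) (q_b - q_B) ]

integrated backwards from the end of the sweep (terminal condition `q_B = 1`
and `q_b` at the frozen stationary root, which tends to 0 at complete
linkage: an allele stranded on the ancestral background is excluded).  The
fractional loss for a mutation born at scaled time `tau` is
`L = 1 - [(1-x) q_b + x q_B]`; the theory guarantees `L >= 0` (variation in
fixation probability across backgrounds can only reduce the average).

Integrated over uniformly distributed sweep times and positions the loss is
scale-free — the Morgan-per-generation measure `dr dt` is invariant under
`(tau, rho)` scaling — and defines the interference constant

    Z = \int_0^inf drho \int dtau L(rho, tau)  ~  1.058,

computed by two-piece Gauss–Legendre quadrature (a `rho = u^2` substitution
absorbs the integrable logarithmic divergence of the time-integrated loss at
`rho -> 0`) with a doubling refinement check (<1% change required; observed
~10^-6).  The kernel is independent of `N` at fixed scaled coordinates, the
numerical statement of the scaling argument that the reduction in fixation
probability depends on the parameters only through the density of sweeps.

Numerical choices: LSODA with `rtol = 1e-9`; the time window spans
`[-45 max(1, 1/beta), 20]` scaled units (the pre-sweep tail of the loss
relaxes at the *focal* allele's rate `beta`); the outer integral is
truncated at `rho = 3000` with the tail bound reported.

The interference coefficient `c(zeta)` (`zeta = s_sweep / s_focal`)
generalizes `Z = c(1)` to unequal effects.  Numerically `c ~ zeta` for weak
sweeps and `c ~ (pi/2) zeta / ln zeta` for strong ones (the prefactor
1.57±0.03 is stable over `10 <= zeta <= 300`); the exposed closed-form
approximation joins these branches at `zeta = e^{pi/2}`.  Both asymptotic
coefficients are fitted once from this package's numerics.

The two-sweep solver generalizes to four backgrounds with deterministic
four-haplotype dynamics (selection plus recombination of the sweep pair),
started either in linkage equilibrium or with both sweeps arising on
distinct wild-type genomes at frequency `1/2N` (complete negative
disequilibrium).  Double crossovers in one generation are second order in
the map distances and dropped.  Combined losses stay within ~5% of the sum
of single-sweep losses across separations, the numerical justification for
the additive approximation.

## Analytic theory (`sweepint.theory`)

* Baseline: `p0 = (1-e^{-2s})/(1-e^{-2Ns})` (diffusion; the weak-selection
  `2s` is selectable and every result records the convention),
  `Lambda0 = N U p0 / R`, `v0 = N U p0 s`.
* Additive approximation: `<p>/p0 = 1 - 2 Z Lambda` gives
  `Lambda = Lambda0 / (1 + 2 Z Lambda0)`, with ceiling `1/(2Z)` — at
  `Z = 1`, half a substitution per Morgan per generation, i.e. one per
  centimorgan per 200 generations.  `Z` defaults to 1 in the rate formulas
  (the 5% refinement is far below the model's own accuracy) and the kernel
  value 1.05 is used where theory is compared against the kernel numerics.
* Unlinked loci: heritable variance `sigma^2` in log fitness multiplies
  fixation probability by `e^{-alpha sigma^2}`.  `alpha = 1` for
  non-inherited variance (the background is redrawn every generation;
  offspring-number variance `e^{sigma^2}`), `alpha = 4` under polygamy and
  `alpha = 8` under monogamy.  The latter two are derived by second-order
  perturbation of the multitype branching process defined by the
  infinitesimal model: the linearized type operator has eigenfunction
  `e^{2z}` (fixation probability proportional to the square of the
  founder's fitness — the cumulative transmission factor is
  `1 + 1/2 + 1/4 + ... = 2`) and left eigenvector `N(0, sigma^2)`, giving
  `<p> = 2s e^{-4 sigma^2}` for polygamy; the shared mate under monogamy
  contributes fully correlated offspring-number and offspring-type noise
  and doubles the exponent.  The branching simulation reproduces both
  values up to higher-order `sigma^2` curvature (measured exponents 4.26 ±
  0.45 and 7.1 ± 0.45 at `sigma^2 <= 0.03`).
* Self-consistent rate: `Lambda = Lambda0 (1 - 2 Z Lambda)
  e^{-alpha Lambda R s}` with the steady-state tie `sigma^2 = Lambda R s`
  (Fisher's theorem: the variance equals the rate of increase of mean log
  fitness).  Solved by bracketed root finding on `[0, min(Lambda0, 1/2Z)]`
  to 10^-12; tight linkage dominates when `alpha R s << 2 Z`.
* Lambert-W rates: `v = v0 e^{-alpha v}` has the closed form
  `v = W(alpha v0)/alpha` — logarithmic growth in the mutation supply.
  `alpha = 1` reproduces the complete-recombination model.
* Neutral diversity: a sweep at map distance `r` coalesces a pair of neutral
  lineages with probability `e^{-2 r ln(2Ns)/s}` (both lineages must stay on
  the sweeping background for the `ln(2Ns)/s` generations the sweep spends
  below high frequency); averaging over a linear map gives a pairwise
  coalescence rate `Lambda s / ln(2Ns)`, so
  `T2 = e^{-alpha sigma^2} / (1/N + Lambda s / ln(2Ns))`.
  This reproduces the characteristic phenomenology: diversity is strongly
  reduced at sweep densities far too low to cause interference, saturates
  once interference caps `Lambda`, and over a mid range of `N` the
  heterozygosity-based effective population size *decreases* with the actual
  size (and can reverse again at very large `N`, where the lengthening sweep
  timescale dilutes each sweep's effect).
* Exponential effects: with the linear coefficient `c = Z zeta` and the
  baseline mean advantage of successful sweeps `s~ = 2 s_mean`, the profile
  is `p(s) = 2 (s - s_c)_+` with `s_c = 4 Z Lambda s_mean` and the overall
  density solves `Lambda = Lambda0 e^{-4 Z Lambda}` (`W(4 Z Lambda0)/4Z`) —
  an interference term exactly twice the fixed-effects value.  Weakly
  selected alleles get the resummed form `p = 2s e^{-2 Z Lambda s~/s}`,
  floored at the neutral `1/N` with an explicit near-neutral flag rather
  than a silent extrapolation.
* Facultative sex at outcrossing rate `psi`: selection per outcrossing cycle
  scales as `s/psi` while per-mutation drift scales identically, so `p0` is
  unchanged and only the interference terms rescale:
  `Lambda = Lambda0 (1 - 2 Z Lambda/psi) e^{-alpha Lambda R s/psi^2}`,
  ceiling `psi/(2Z)`; linked loci dominate when `R s << psi`.
* Sojourn times: for the haploid WF diffusion conditioned on fixation from
  one copy, the mean sojourn density is
  `t*(x) = 2N (1-e^{-ax})(1-e^{-a(1-x)}) / [a x (1-x) (1-e^{-a})]`,
  `a = 2Ns` — symmetric in `x <-> 1-x` (a fixing allele spends as long
  below frequency 1/2 as above it).  Standard deviations come from the
  Green function of the conditioned diffusion
  (`E[T^2] = 2 \iint G(0,x) G(x,y)`), evaluated on a trapezoid grid; both
  moments agree with conditioned Wright–Fisher Monte Carlo at `N = 100`,
  `s = 0.05` to within sampling error.

## Simplified dynamics (`sweepint.auxiliary`)

The complete-recombination ("mass meiosis") engine reuses the mutation
bookkeeping but builds every offspring by sampling each locus independently
at its fitness-weighted parental frequency, so linkage disequilibrium is
identically zero; its measured rate of adaptation is checked against
`v = W(v0)`.

The infinitesimal branching simulation tracks only carriers of the focal
mutation, each tagged with a background log fitness measured relative to the
advancing population mean (which moves by `sigma^2` per generation — this
analytic-normalization choice keeps the process exactly critical at
`s = 0`, verified directly).  Polygamy draws an independent fitness-tilted
mate `N(sigma^2, sigma^2)` per offspring; monogamy one random mate
`N(0, sigma^2)` per carrier per generation shared by all its offspring;
offspring backgrounds are mid-parent plus `N(0, sigma^2/2)` segregation
noise.  A lineage is fixed at `fix_threshold` carriers (default 5000 with a
400-fixed-lineages stopping criterion; tests use smaller thresholds, safe
whenever `threshold >> 1/s`, which the parameter validation enforces).

## What the synthetic data do and do not show

All inputs are generated by the package itself under the model's own
assumptions; tests therefore validate internal consistency (simulator vs
independent branching/diffusion/Markov-chain oracles, numerics vs closed
forms), not realism.  Real genomes have non-uniform maps and mutation
targets, deleterious mutations, epistasis, diploidy and structure, all of
which are out of scope here; conclusions about real populations inherit the
model's best-case character — interference limits computed here are, if
anything, underestimates of what heterogeneous genomes experience locally.

## Known limitations

* The additive approximation underestimates the rate of adaptation at very
  strong interference (`Lambda0 >> 1`), where simulated densities keep
  creeping above the 0.5 ceiling; this is a property of the theory itself,
  visible in the package's own simulations.
* `estimate_T2` fits a single late-time exponential; when drift and draft
  time scales are close the window-stabilization rule can be sensitive to
  its tolerance (both are configurable and logged).
* The desk-scale defaults target `N <= ~10^5`; populations of 10^6-10^7
  individuals are outside the default performance envelope.
* The two-background machinery covers one and two concurrent sweeps; the
  general 2^n-background system is intractable and is represented by the
  additive approximation plus direct simulation instead.
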