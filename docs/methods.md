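# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `reactoracle`, and what the synthetic validation does and
does not establish.

## Generative model

**Latents.** An entity basis (compounds, or fingerprint bits under MACCS /
Morgan schemes) carries a membership matrix `M` (entities × K) with entries
in [0, 1]: the degree to which each entity possesses each of K abstract
properties.  Each modelled reaction arity k ∈ {2, 3, 4} carries a symmetric
order-k reactivity tensor `R_k` over property indices, entries in [0, 1].
Multibit theories add an emission matrix `E` (modes × B), where a *mode* is
an unordered multiset of k property indices and B is the reactivity-vector
width.

**Likelihood.** For an experiment with reagent membership rows m₁…m_k, every
ordered index tuple (I₁…I_k) is an independent potential cause firing with
probability m₁[I₁]⋯m_k[I_k]·R[I₁…I_k]; causes combine by noisy-OR.  Grouping
the ordered tuples of one multiset and OR-ing them is algebraically identical
to taking the product over all ordered tuples, which is what the vectorised
kernel computes; the unit tests check it against explicit multiset
enumeration.  Binary theories stop there (the event *is* reactivity).
Multibit theories compute per-mode components, attenuate them by the
emission weight of each bit, and noisy-OR across modes per bit.  Recorded
bits pass through fixed false-positive/false-negative rates
(`eps_fp = eps_fn = 0.01` by default; both must be < 0.5): the probability of
an observed bit is `eps_fp + (1 − eps_fp − eps_fn)·signal`.  Observations are
conditionally independent Bernoulli bits given the latents.  Probabilities
are clamped to [1e−9, 1 − 1e−9] before logs.

**Fingerprint basis.** A compound's membership row is the per-property
noisy-OR over the bit memberships of its set bits.  This shares statistical
strength across compounds with common motifs; the nine-compound fixture
asserts at build time that the isocyanide carries Morgan bits no other
compound has, so the planted rules are identifiable in that basis.

**Priors.** Independent Beta distributions per block, named configurations:
`conservative-v1` (default) puts Beta(0.5, 2.5) — mean 1/6, mass near zero —
on memberships, unique tensor entries and emission weights; `uniform` is
Beta(1, 1).  Per-block overrides support e.g. a null theory with reactivity
~ Beta(0.5, 50).  K is a fixed truncation (default 8); sparsity comes from
the prior, not from inferring K.  Noise rates are fixed constants, not
sampled.

**Self-combinations.** A compound reacted with itself is a legal arity-2
experiment (one id, `self_pair=True`); default enumeration excludes
self-pairs, fixtures request them explicitly.

## Inference

Sampling runs in the unconstrained logit parameterisation (Beta density plus
Jacobian collapses to `a·logθ + b·log(1−θ)`), using an ensemble MCMC sampler
(differential-evolution moves 80%, stretch moves 20%) with the log posterior
vectorised across walkers.  Walker count is `max(2·ndim+2, 4·chains, 32)`.
`chains × draws` posterior draws are retained by thinning the sampling phase;
walkers are treated as chains for split-R̂ and ESS (a convergence *warning*,
never an error, above R̂ = 1.05).  Identical (theory, log, seed) gives
bit-identical draws.  Coordinates with |z| > 200 are rejected outright, which
keeps the ensemble geometry finite without affecting any realistic posterior
mass.

Monte-Carlo standard errors of derived scalars use the effective sample size
of the per-draw values, so autocorrelation is accounted for.

**Quadrature oracle.** For theories with ≤ 6 free parameters,
`grid_posterior` integrates prior × likelihood on a midpoint grid *in
prior-CDF coordinates* (each axis mapped through its Beta quantile function).
This makes the prior weight exactly uniform and neutralises the integrable
endpoint singularity of Beta(a < 1) densities; plain θ-space quadrature
converges visibly slower on the same toys.  Sampler-vs-oracle agreement is
asserted within 3 combined standard errors (Monte-Carlo SE plus the
grid's own discretisation error, estimated as the shift between resolutions
101 and 201).

**Posterior hedging and the parsimonious readout.** With a single Bernoulli
observation per combination, the likelihood tilt toward any one explanation
is linear in its firing probability, so the full posterior legitimately
hedges: crisp "rule" configurations carry real but not majority mass.  (This
is a property of the inference problem, not of the sampler; the quadrature
oracle shows the same thing on small cases.)  The Occam-style summary —
*how many properties are needed to explain the observations* — is therefore
computed not from posterior draws but by a dedicated extractor:
L1-penalised maximum likelihood (penalty λ·Σθ, λ = 0.5), optimised by
L-BFGS-B from 12 seeded multistarts that mix near-zero entries with a sparse
sprinkling of crisp ones.  The linear penalty zeroes parameters the data
never ask for while leaving data-demanded parameters free to approach 1
(unlike a Beta(·, b>1) log-prior, whose −log(1−θ) penalty forbids crisp
values; λ = 0.5 sits well below the ≈ 4.6-nat likelihood gain of explaining
one observation and well above the vanishing marginal gain of diffuse
micro-contributions).  The reported count is the size of the smallest
property subset under which every reactive observation keeps a
binary-collapsed signal ≥ 0.5 (the declared activity threshold), found by
exhaustive search over the 2^K subsets; per-compound counts use membership
≥ 0.5 within that subset.

On the six-compound cycloaddition space this yields four properties, two on
cyclopentadiene.  Four is provably minimal for that fixture *because all six
self-pairs are observed* (only cyclopentadiene dimerises): without the
acid/base self-pairs a single shared self-reactive property explains the
acid–base pair, and without the anhydride self-pair a single shared "ene"
property explains both cyclopentadiene reactions — the optimiser finds those
three-property shortcuts if the self-pair evidence is removed.  The fixture
therefore observes every self-combination, which is also what a combinatorial
platform naturally does.

## Surprise, disruption, replay

Surprise of an observation is −log of the Monte-Carlo-averaged probability
of its exact outcome vector.  The *a priori* trace uses prior draws (hence is
order-invariant), the *a posteriori* trace the full-log posterior, and the
*online* trace the posterior over observations 0…t−1, refitting every
`refit_every` accepted observations and importance-reweighting in between.
With reweighting only, the online surprises telescope exactly to −log of the
joint predictive likelihood (tested to 1e−6).  The anomaly threshold defaults
to −ln 0.05: an outcome judged less than 5% likely in retrospect is
shortlisted.

Disruption of a candidate experiment is the expected total-variation change
of predictive reactivity over the remaining unexplored experiments, where
the expectation runs over the candidate's binary-collapsed outcome branches
and each branch's predictive comes from importance-reweighting the posterior
draws by that branch's likelihood.  Collapsing multibit candidates to
reactive/unreactive keeps two branches instead of 2^B.  Rankings break ties
by canonical experiment order, so they are deterministic.

Exploration replay iterates choose → observe → update with either uniform
random choice or the top disruption candidate; an observation whose online
surprise exceeds the anomaly threshold is scheduled once more before being
accepted (the repeat-attempt policy), and the event stream records step,
experiment, outcome, online surprise, strategy, refit and repeat flags.

## Theory registry and mixture comparison

Deposited theories get identifiers from the SHA-256 of their canonical JSON
definition (first 16 hex digits): registration is idempotent, refinements
record a parent identifier, and lineage is acyclic by construction.

Rival theories A and B are compared through a per-observation mixture:
each observation's likelihood is `w·p_A + (1−w)·p_B` with w ~ Beta(1, 1) and
both theories' latents sampled jointly.  The weight itself is *marginalised
out of the MCMC* by Gauss–Legendre quadrature (the integrand is a
polynomial of degree n in w, so the node count is chosen exact for the log
length) and reconstructed afterwards by drawing one w from each kept draw's
conditional.  Sampling w directly is sticky: once w reaches a corner the
losing theory's latents decouple from the data and the swap mode mixes very
slowly.  Because a slow label-swap mode remains in the joint latent space,
`compare_theories` runs `chains` fully independent ensembles (sub-seeded
from the config seed) and treats them as chains for ESS, so between-replicate
disagreement inflates the reported standard error honestly.  A count-based
event definition (number of distinct new peaks rather than their location)
is supported by thermometer-recoding outcome vectors, which keeps the
Bernoulli machinery unchanged.

## Synthetic data: what it emulates, what it does not

The fixtures emulate the *logical* structure of combinatorial discovery
campaigns: planted membership-style rules (acid–amine; acid + carbonyl +
isocyanide; coupling partners sharing a catalyst and base), deterministic
outcome sources, optional seeded bit-flip noise, and 8-bit outcome vectors
whose sub-combination behaviour follows the convention that a tabulated
reagent set's *unique* bits appear only for the full set while its remaining
bits are emitted by proper sub-combinations (unioned when a sub-combination
sits inside several tabulated sets; combinations covered by no set are
blank).  The chromatogram converter bins product peaks into eight equal
retention regions (match tolerance 0.1 min) and flags peaks absent from the
reactant references.

They do **not** emulate: real chromatogram shapes (baselines, co-elution,
intensity-dependent detection), condition- or stoichiometry-dependent
reactivity, yields or kinetics, or correlated instrument noise.  Passing
tests therefore demonstrate that the inference and interpretation machinery
behaves correctly on data whose generating rules are known — not that the
model recovers mechanisms from real instrument data.

## Problem sizes and defaults

The shipped analyses use: the 21-observation cycloaddition space with K = 8;
the 120-combination nine-compound space with K = 4 (two properties for the
binary rule, two more for the ternary rule, with shrinkage headroom); a
60-observation exploration of the 550-combination space with a
binary-collapsed K = 3 theory for the anticipation analysis; 3-parameter
toys for the quadrature cross-checks; and MCMC budgets of 4 chains ×
1000–3000 warmup × 600–3000 kept draws, chosen so the full validation runs
in minutes on a single CPU while keeping Monte-Carlo error well inside the
asserted tolerances.  All seeds are explicit; nothing falls back to global
random state.

## Known limitations

- Ensemble MCMC on the larger latent spaces (≥ 80 dimensions) mixes slowly
  across label-switching modes; all shipped summaries are label-invariant
  (predictive probabilities, likelihoods, subset counts), and raw membership
  entries should never be compared across draws.
- The disruption score is a reweighting approximation to one-step lookahead;
  it does not refit per branch and collapses multibit outcomes to binary.
- The emission map is a soft matrix, not a one-to-one mode-to-bit
  assignment; with few observations per bit the two are not distinguishable.
- `eps` noise rates are fixed, not inferred; grossly misspecified rates bias
  surprise levels (though not their a-priori/a-posteriori ordering in the
  shipped fixtures).
- The online surprise trace between refits relies on importance weights,
  whose effective sample size degrades when an observation is very
  surprising; the default refits every observation on small spaces.
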