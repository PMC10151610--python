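# reactoracle

Bayesian interpretation of combinatorial chemical-reactivity data.

Autonomous chemistry platforms can run hundreds of 2–4-reagent combination
experiments and record, for each, whether anything reacted — or, more
informatively, a fixed-width bit vector marking which regions of the product
chromatogram gained new peaks.  What such platforms cannot do by themselves
is *interpret* those outcomes: decide which results are genuinely surprising,
which are explained by rules already learned, which experiment to run next,
and how two rival mechanistic pictures compare on the same data.
`reactoracle` is a library (plus a small CLI) for exactly that, aimed at
computational and automation-minded chemists.

## The model

Each entity — a compound, or a molecular-fingerprint bit in the structural
variant — possesses each of *K* abstract properties to a degree
*M*<sub>eI</sub> ∈ [0, 1].  Property combinations carry a latent mutual
reactivity *R*<sub>IJ</sub> ∈ [0, 1] (a symmetric tensor per reaction arity
*k* ∈ {2, 3, 4}).  For compounds α, β the component matrix

&nbsp;&nbsp;&nbsp;&nbsp;P<sub>αβIJ</sub> = M<sub>αI</sub> · M<sub>βJ</sub> · R<sub>IJ</sub>

is the probability that α and β react *because* α acts through property I and
β through J.  Independent causes aggregate by noisy-OR,

&nbsp;&nbsp;&nbsp;&nbsp;p(react) = 1 − ∏<sub>I,J</sub> (1 − P<sub>αβIJ</sub>),

extended to order-3/4 tensors for three- and four-component reactions.
Multibit outcomes attach an emission matrix linking each reactivity mode
(unordered property multiset) to observable bits, with small false-positive /
false-negative rates.  Priors are independent Beta distributions; the default
`conservative-v1` configuration (Beta(0.5, 2.5), mean 1/6) expects few
properties and little reactivity unless the data insist.

On top of the posterior (ensemble MCMC in a logit parameterisation; a
deterministic quadrature oracle validates it on small models) the package
computes:

- **surprise** — the negative log predictive likelihood of each observation,
  a priori (prior predictive), online (conditioned on earlier observations),
  and a posteriori (final posterior);
- **anomaly shortlists** — observations still surprising in retrospect;
- **disruption rankings** — which unexplored combination would, in
  expectation, most change predicted reactivity over the remaining space
  (importance reweighting over outcome branches);
- **parsimonious explanations** — the minimum set of properties needed to
  explain all reactive observations (seeded multistart L1-penalised maximum
  likelihood);
- **theory registry and mixture comparison** — content-addressed deposits of
  rival theories and a per-observation mixture model whose posterior weight
  reads out their relative support.

Everything runs against synthetic chemical spaces with planted rules (a
cycloaddition space, a nine-compound space hiding acid–amine and
three-component acid + carbonyl + isocyanide rules, and an eleven-compound
space reproducing eight named reactions with 8-bit reactivity vectors), so no
external data are required.

## Worked example

```python
from reactoracle import (MCMCConfig, Theory, anomaly_shortlist,
                         parsimonious_explanation, surprise_trace)
from reactoracle.synthetic import (make_diels_alder_space,
                                   make_passerini_space, simulate_log)

fx = make_diels_alder_space()
log = simulate_log(fx["space"], fx["outcome_source"], experiments=fx["experiments"])
print(len(log), "observations,", int(log.outcome_matrix().sum()), "reactive")

theory = Theory(id="cycloaddition", k=8, arities=(2,))
expl = parsimonious_explanation(theory, log, seed=1)
print("properties needed:", expl.n_properties,
      "| on cyclopentadiene:", expl.compound_properties["cp"])

px = make_passerini_space()
plog = simulate_log(px["space"], px["outcome_source"])
ptheory = Theory(id="passerini", k=4, arities=(2, 3))
config = MCMCConfig(seed=11, chains=4, warmup=2500, draws=1000)
trace = surprise_trace(ptheory, plog, config, online=False)
i = [o.experiment for o in plog].index(px["passerini_experiments"][0])
print("%s surprise: a priori %.2f -> a posteriori %.2f"
      % (plog[i].experiment, trace.a_priori[i], trace.a_posteriori[i]))
print("anomalies at the 5% cutoff:", len(anomaly_shortlist(trace)))
```

Output:

```
21 observations, 3 reactive
properties needed: 4 | on cyclopentadiene: 2
aca+ace+iso surprise: a priori 2.87 -> a posteriori 2.40
anomalies at the 5% cutoff: 0
```

The six-compound cycloaddition space (an acid, a base, two inert fillers,
maleic anhydride and cyclopentadiene) contains three reactive combinations.
The model needs exactly four abstract properties to explain them — two of
which sit on cyclopentadiene, the in-model analogue of discovering the
*diene* and *dienophile* labels.  On the nine-compound space, the
three-component acetic acid + acetone + isocyanide observation is improbable
in prospect (surprise 2.87, predictive probability e<sup>−2.87</sup> ≈ 6%)
but clearly less surprising in retrospect (2.40 ≈ 9%), and after exhaustive
exploration no observation remains anomalous at the 5% cutoff — the
three-component rule has been absorbed as a rule rather than flagged as an
outlier.

A CLI mirrors the library for shell use (`reactoracle simulate / fit /
surprise / suggest / explore / compare / vectorize`); every command writes a
manifest with input hashes and seeds.

## Layout

- `src/reactoracle/space.py` — compounds, experiments, observation logs, fingerprints
- `src/reactoracle/theory.py` — the generative model and likelihood kernels
- `src/reactoracle/inference.py` — ensemble MCMC, quadrature oracle, posterior container
- `src/reactoracle/model.py` — scikit-learn style estimator (`BayesianReactivityModel`)
- `src/reactoracle/oracle.py` — surprise, disruption, anomalies, replay, parsimonious explanations
- `src/reactoracle/delphi.py` — theory registry and mixture comparison
- `src/reactoracle/synthetic.py` — fixture spaces, planted rules, chromatogram vectorizer
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
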