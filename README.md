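# geoadditive

Bayesian geo-additive multinomial logit models for the nutritional status
of reproductive-age women — underweight, normal, or overweight/obese —
observed with categorical household covariates, age, and an
administrative region.  The package is aimed at epidemiologists and
biostatisticians who want to separate three kinds of structure in
survey data like the Bangladesh DHS: linear effects of categorical
covariates, a smooth nonlinear effect of age, and spatially structured
versus unstructured regional variation.

## The model

For woman *i* and non-reference outcome category *r* (reference:
normal weight),

```
P[y_i = r] = exp(η_ir) / (1 + Σ_s exp(η_is)),
M6:  η_ir = u_i'β_r + f_r(z_i) + g_r(S_i) + h_r(S_i)
```

with five nested simplifications M1–M5 (drop the smooth and/or spatial
terms).  `f_r` is a Bayesian P-spline — a cubic B-spline expansion on 20
equidistant knots with a second-order random-walk prior; `g_r` is an
intrinsic CAR (Gaussian Markov random field) effect over the division
adjacency graph; `h_r` is an iid Gaussian region effect; `β_r` gets a
diffuse prior and all variances inverse-gamma(0.001, 0.001) hyperpriors.
Inference is by MCMC (exact Pólya–Gamma augmentation by default, an
IWLS Metropolis–Hastings backend as a cross-check), and the six variants
are compared by DIC = D̄ + pD.  See `docs/methods.md` for the full
account.

Because the underlying DHS microdata are access-controlled, the package
includes a first-class synthetic generator that draws DHS-like samples
from this exact model with known effects (covariate marginals matching
the published 2014 / 2017-18 frequency tables), so the entire pipeline —
classification, descriptive tables, fitting, model comparison, effect
export — is testable end to end.

## A worked example

```python
import geoadditive as ga

sim = ga.simulate_dataset(ga.GeneratorConfig(
    n_records=3000, seed=4,
    true_linear_effects=ga.default_true_linear_effects(),
    true_smooth_functions=ga.default_true_smooth_functions(),
    structured_truth_delta=0.15,
))
data = ga.ModelData(sim.data, graph=sim.graph)

results = []
for variant in ("M1", "M2", "M4"):
    fit = ga.run_mcmc(data, ga.ModelSpec(variant),
                      ga.MCMCConfig(n_iter=2000, burn_in=500, thin=2, seed=9))
    results.append(ga.compute_dic(fit))
print(ga.compare_models(results, reference="M4").round(2))
```

prints

```
  model  mean_deviance     pd      dic  dic_difference  similar_to_best
0    M1        5872.66  34.18  5906.84          164.16            False
1    M2        5729.18  44.00  5773.19           30.51            False
2    M4        5688.42  54.25  5742.67            0.00             True
```

The data were generated with linear, smooth-age and structured spatial
effects, and DIC ranks the variants accordingly: adding the age smooth
(M2) buys ~164 DIC over the purely linear M1, adding the spatial term
(M4) another ~31; `pd` is the effective parameter count each block adds.
The scripts in `examples/` walk through the other capabilities
(simulation, descriptive tables with proportion tests, spatial/age
effect export), each printing a short annotated result.

There is also a thin CLI:

```sh
geoadditive simulate --n-records 4000 --seed 1 --out runs/sim
geoadditive fit runs/sim/survey.csv --graph-edges runs/sim/graph_edges.txt \
    --models M1,M4 --n-iter 4000 --burn-in 1000 --seed 2 --out runs/fit
geoadditive compare runs/fit --out runs/fit/comparison.csv
```

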