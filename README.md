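# microbeta

Directed microbial interaction inference from cross-sectional abundance
tables and environmental gradients.

## The problem

High-throughput surveys give relative taxon abundances across many sites
together with measured environmental parameters, but no time series — each
soil core is destroyed when sampled.  Co-occurrence networks built from
such data are symmetric by construction: the correlation of taxon *A* with
*B* equals that of *B* with *A*, so predation, antagonism and other
one-sided relationships are invisible.  `microbeta` estimates, for every
*ordered* pair of taxa, a directed interaction coefficient from how taxon
abundances change along environmental gradients, for researchers who want
interaction hypotheses (who influences whom, in which direction, how
strongly) out of standard cross-sectional survey tables.

## The model

Assume each abundance `A_i` is a smooth function of the environmental
parameters `Θ_α` and the other taxa.  For sample *k* the chain estimates

* the local slope `p_iαk = ∂A_ik / ∂Θ_αk`, then
* the local interaction `β_ijαk = (∂p_iαk / ∂A_jk) / A_ik`,

via no-intercept Huber regressions on first-order Taylor differences
between sample *k* and every other sample.  By analogy with the
generalized Lotka–Volterra equations (gradient in the role of time), the
coefficient for pair (*i*, *j*) estimates the effective interaction
`r_i B_ij / K_i`, so it is signed and directed: `β_ij` and `β_ji` need not
agree.  The per-sample tensor is condensed per parameter by the median of
the dominant density peak under an 80 % sign-majority rule, and across
parameters by the same majority rule with a twofold magnitude-ratio
fallback, yielding one global `β_ij` per ordered pair with an explicit
determinacy status.  Perturbation and subsampling machinery quantifies how
stable each global value is; a gLV simulator provides ground truth for
validation.  Details and all numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import microbeta as mb

truth = mb.simulate_glv_gradient(mb.predator_prey_params())
result = mb.infer_interactions(truth.abundance, truth.environment)
print(result.global_matrix.to_frame().round(3))
```

prints

```
        taxon1  taxon2
taxon1   0.163   0.187
taxon2  -0.051  -0.055
```

Columns act on rows: the prey (taxon2) exerts a positive influence on the
predator (+0.187), the predator a negative one on the prey (−0.051) — the
simulator's true signs, with opposite off-diagonal directions that no
correlation matrix could express.  The diagonal carries self-interaction
(here: positive while the predator is still growing into its niche,
negative for the self-limited prey).  The `examples/` directory has one
short script per capability (inference, co-occurrence contrast, gradient
profiles, robustness), each printing the numbers it computes and what they
mean.

A thin command-line wrapper exposes the same pipeline
(`microbeta infer|summarize|robustness|simulate|compare`); run
`microbeta --help` for flags.

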