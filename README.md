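# varcallkit

Bayesian classification of missense variants from functional assay data.

Variants of uncertain significance (VUS) are a routine outcome of
clinical sequencing: a missense change is observed, but its association
with disease is unknown. For proteins with a validated functional assay
— the motivating case is the transcriptional-activation (TA) assay for
the C-terminal BRCT region of BRCA1 — the assay readout carries direct
evidence about pathogenicity. `varcallkit` turns that readout into a
per-variant posterior probability of pathogenicity and a five-tier
functional classification, for assay labs and variant-curation groups
who need calibrated, reproducible calls rather than ad-hoc activity
cutoffs.

## The model

Normalized log-activities y (firefly/Renilla ratios, wild-type-centred
per batch) follow a hierarchical two-component mixture:

    y_vbr = x'γ + β_b + η_v + ε_vbr        ε ~ N(0, σ_e²)
    β_b ~ N(0, σ_b²)                        batch random effect
    η_v | Z_v=0 ~ N(μ₀, τ₀²)                neutral component
    η_v | Z_v=1 ~ N(μ₁, τ₁²)                pathogenic component,  μ₁ < μ₀
    Z_v ~ Bernoulli(π)                      for unlabelled variants

Wild-type and loss-of-function controls in every batch (plus any
reference panel of known variants) have Z fixed, anchoring the two
components. **PrDel** = posterior mean of Z_v is the probability that a
variant's effect arises from the low-activity component, mapped to
**fClass** 1–5 at thresholds 0.001 / 0.05 / 0.95 / 0.99. Inference is
a blocked Gibbs sampler (see `docs/methods.md`).

The package also provides leave-one-out cross-validation with exact
Clopper–Pearson bounds on sensitivity/specificity, standardized-residual
QQ plots with simultaneous Monte-Carlo envelopes, concordance tables
against in-silico predictors (SIFT, PolyPhen-2, CADD, MutationTaster2),
alignment-based transfer of functional annotation between BRCT-domain
proteins (BRCA1 → MCPH1/MDC1), and a synthetic-data generator with
known ground truth.

## Worked example

```python
import varcallkit as vk

# simulate a 20-variant assay with a 6-variant labelled panel
dataset, truth, labels = vk.generate(
    vk.GeneratorConfig(n_variants=20, n_labeled=6, seed=11))

fit = vk.fit(dataset, labels,
             vk.ModelSpec(chains=2, iterations=2000, burn_in=1000, seed=5))
print(f"max split-Rhat: {fit.diagnostics['rhat_max']:.3f}")
for s in vk.eta_summary(fit)[:5]:
    print(f"{s.variant:>8}  eta median {s.eta_q50:+.2f}  "
          f"PrDel {s.prdel:.3f}  fClass {vk.fclass(s.prdel)}  "
          f"(true Z={truth.z[s.variant]})")
```

prints

```
max split-Rhat: 1.003
  C1402Y  eta median -0.12  PrDel 0.000  fClass 1  (true Z=0)
  S1458D  eta median -2.12  PrDel 1.000  fClass 5  (true Z=1)
  P1511L  eta median -1.85  PrDel 1.000  fClass 5  (true Z=1)
  F1538K  eta median -0.09  PrDel 0.000  fClass 1  (true Z=0)
  T1540M  eta median -0.50  PrDel 0.000  fClass 1  (true Z=0)
```

Chains mixed (Rhat ≈ 1), variants simulated from the low-activity
component get PrDel ≈ 1 (fClass 5, pathogenic), the rest PrDel ≈ 0
(fClass 1) — including T1540M, whose true effect (−0.5) is an
unusually low draw from the neutral component but is still resolved
correctly.

The same pipeline is scriptable from the shell:

```sh
varcallkit simulate --seed 11 --n-variants 20 --n-labeled 6 --out run/sim
varcallkit fit --assay run/sim/assay.tsv --labels run/sim/labels.json \
    --seed 5 --out run/fit
varcallkit classify --posterior run/fit/posterior_summary.tsv --out run/cls
```

Subcommands `loo`, `metrics`, `concordance` and `map-domains` cover the
validation and annotation-transfer stages; every run writes its
resolved configuration next to its outputs, and identical config + seed
gives byte-identical outputs.

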