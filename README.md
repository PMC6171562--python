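# mrmtrace

Design and analysis toolkit for targeted metabolomics on a triple-quadrupole
LC-MS/MS: multiple-reaction-monitoring (MRM) transition prediction for
central-carbon, amino-acid and nucleotide metabolism, O-benzylhydroxylamine
(OBHA) derivatization mass arithmetic, stable-isotope (¹³C/¹⁵N) isotopologue
transition design with moiety resolution, transparent chromatographic peak
quantitation, mass-isotopomer-distribution analysis with natural-abundance
correction, and label-incorporation kinetics simulation and fitting.

It is written for mass-spectrometry facility users and metabolism labs who
run a single fusion-core reversed-phase column across several pathways and
want to (a) validate and extend their acquisition lists from chemical first
principles and (b) design and interpret simple stable-isotope tracing
experiments without a full ¹³C flux-analysis pipeline.

## What it computes

**Transition prediction.** At unit resolution (integer element masses,
proton = 1), the precursor m/z of an analyte with formula *M* is

    Q1 = nominal(M) ± 1        ([M+H]⁺ positive / [M−H]⁻ negative)

and the product m/z comes from a curated fragment: either a product-ion
formula *F* (Q3 = nominal(F) ± 1, e.g. protonated adenine 136 for AMP) or a
neutral loss *L* (Q3 = Q1 − nominal(L)).  OBHA derivatization of carbonyl /
carboxyl metabolites condenses one OBHA (C₇H₉NO) per site with loss of
water, a net +C₇H₇N = +105 Da per site; the per-analyte site count is
curated (empirical), not inferred from the formula.

**Isotopologue ladders.**  For a tracer element with `n_total` labelable
atoms in the precursor and `n_frag` of them in the product ion, a precursor
with `k` labels and `j` of them in the fragment is feasible iff
`max(0, k − (n_total − n_frag)) ≤ j ≤ min(k, n_frag)`; the channel is
acquired at (Q1 + k, Q3 + j).  Because Q1 and Q3 shift independently, label
is attributed to sub-structures — for AMP monitored by base release, the
five base carbons (fragment) versus the five ribose carbons (remainder).

**MIDs and kinetics.**  Channel areas become mass isotopomer distributions
f₀..fₙ; percent label incorporation is 100·(1 − f₀); mean enrichment is
Σ i·fᵢ / n.  Natural abundance (1.07% ¹³C, 0.364% ¹⁵N) is removed by
non-negative least squares against a lower-triangular binomial convolution
matrix.  Labeling time courses are simulated with first-order pool-turnover
chains, dLᵢ/dt = (F/Pᵢ)(L₍ᵢ₋₁₎ʰ − Lᵢ), and fitted with exponential,
lagged (two-pool) or sigmoidal (Hill-time) models.

## Worked example

Predict the AMP transition and compare with the packaged library:

```
$ mrmtrace predict --analyte AMP
AMP     predicted 348/136       library 348/136
```

Q1 348 is protonated C₁₀H₁₄N₅O₇P (nominal 347); Q3 136 is protonated
adenine, the monitored nitrogen base.  The full ¹³C acquisition list in the
moiety-pure policy (base-filled series, then fully labeled ribose carrying
the overflow):

```
$ mrmtrace ladder --analyte AMP --label 13C --policy moiety-pure
name,k,j,q1,q3,ce,moiety_tag
13C_AMP_0,0,0,348.0,136.0,21.0,unlabeled
13C_AMP_1_frag1,1,1,349.0,137.0,21.0,fragment-labeled
13C_AMP_2_frag2,2,2,350.0,138.0,21.0,fragment-labeled
13C_AMP_3_frag3,3,3,351.0,139.0,21.0,fragment-labeled
13C_AMP_4_frag4,4,4,352.0,140.0,21.0,fragment-labeled
13C_AMP_5_frag0,5,0,353.0,136.0,21.0,remainder-labeled
13C_AMP_5_frag5,5,5,353.0,141.0,21.0,fragment-labeled
13C_AMP_6_frag1,6,1,354.0,137.0,21.0,mixed
13C_AMP_7_frag2,7,2,355.0,138.0,21.0,mixed
13C_AMP_8_frag3,8,3,356.0,139.0,21.0,mixed
13C_AMP_9_frag4,9,4,357.0,140.0,21.0,mixed
13C_AMP_10,10,5,358.0,141.0,21.0,mixed
```

The 353/136 channel is a fully ¹³C-labeled ribose on an unlabeled base —
the channel that reveals the ribose moiety labeling faster than the base
when tracing from ¹³C-glucose.  Finally, the tracer-design calculator for
the conditioning strategy (grow on half-strength unlabeled precursor, then
add the other half labeled):

```
$ mrmtrace design --strategy conditioning --labeled 0.5 --unlabeled-medium 0.5
initial precursor enrichment: 50.0%
```

so downstream metabolites plateau at ~50% labeling at most.  Other
subcommands: `validate` (recompute every library Q1/Q3 from formulas),
`simulate-chrom`, `integrate`, `mid`, `fit`.  The same functionality is
available as a library (`import mrmtrace`).

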