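# Methods

## Mass arithmetic and the two mass modes

All printed MRM parameters in the packaged library are unit-resolution
triple-quadrupole values, so the default mass mode is **nominal**: integer
element masses (C 12, H 1, N 14, O 16, P 31, S 32) and a proton of exactly 1.
This reproduces every printed Q1/Q3 bit-exactly, which a floating-point
monoisotopic computation followed by rounding would obscure.  A
**monoisotopic** mode (exact most-abundant-isotope masses, proton
1.00727646688 Da) is provided for high-resolution use; across the packaged
library the rounded monoisotopic [M±H] always equals the nominal value (a
test asserts this), as expected for CHNOPS molecules under ~620 Da.

Fractional printed product masses (91.2, 84.1, 179.3 …) exceed nominal
precision; the library stores them verbatim for acquisition, and the
validator compares predictions after rounding both sides to the nearest
integer.  No rounding convention is imposed on acquisition values
themselves.

## OBHA derivatization

O-benzylhydroxylamine condenses with a carbonyl (oxime) or an
EDC-activated carboxyl (hydroxamate), releasing water: the net addition per
site is C₇H₇N, +105 Da nominal.  The number of derivatized sites per
analyte is a curated library attribute, never inferred from the formula,
because derivatization efficiency is empirical — glutamate runs
mono-derivatized (Q1 253) despite carrying two carboxyls.  Curated site
counts: pyruvate 2, lactate 1, methylglyoxal 2, citrate 3, 2-ketoglutarate
3, succinate 2, fumarate 2, malate 2, oxaloacetate 3, glyoxalate 2,
2-hydroxyglutarate 2, glycine 1, aspartate 2, glutamate 1, glutamine 1.
Every derivatized Q1 then matches its printed value except glutamine
(printed 251 vs computed 252), which is stored verbatim and flagged
off-by-one by the validator with a curated note (plausibly in-source
ammonia loss, or a typo; deliberately left unresolved).

## The transition library and its validator

One CSV is the single source of truth (abbreviation, name, formula,
polarity, derivatization, site count, fragment spec, printed Q1/Q3/CE/RT,
method tag); the four acquisition methods are distinguished by a
`method_tag` column rather than four files, and HPLC gradients live in a
structured YAML keyed by the same tags.  Printed values are authoritative
for acquisition; predictions exist to validate the curation and to extend
the method to new analytes.  Collision energies and retention times are
empirical and stored, never computed.

Fragment specs are curated only where the chemistry is unambiguous:
protonated nitrogen bases for the nucleotides (and adenine for
S-adenosylhomocysteine), the H₂PO₄⁻ reporter (97) for sugar phosphates,
deprotonated hexose (179) for trehalose, CO₂ loss for negative-mode
aspartate, the benzyl/tropylium reporter (91) for OBHA derivatives, and the
immonium-type H₂O+CO loss (−46) for the nine amino acids whose printed Q3
it reproduces exactly.  Remaining product ions involve further
rearrangements and are left not-predictable rather than curated
speculatively.

Isobaric transitions (lysine/glutamine 147.0/84.1, isoleucine/leucine
132.0/86.0) are resolved chromatographically: nearest library retention
time within a caller-supplied tolerance, with an explicit error on an exact
tie — never a silent choice.

## Isotopologue ladders and channel-selection policies

Feasibility of (k labels in precursor, j in fragment) is the support of the
hypergeometric distribution over placements; the generator enumerates it
directly and a brute-force double loop over all (k, j) serves as the test
oracle up to 20 atoms.  Mass shift per label is exactly 1 in nominal mode
(1.00336 for ¹³C, 0.99703 for ¹⁵N in monoisotopic mode).  Collision energy
is inherited from the unlabeled base transition, the only defensible choice
since labeled channels are chemically identical.

Four selection policies are exposed.  `full-grid` acquires everything;
`q3-tracks-fragment` takes the maximal-j channel per k; `fragment-unlabeled`
takes the j = 0 series; `moiety-pure` takes channels whose remainder moiety
is either fully unlabeled or fully labeled.  `moiety-pure` is the default in
the CLI because it is the practically informative set for a two-moiety
metabolite such as AMP: the base-filled series for k ≤ 5 plus the
fully-labeled-ribose series (353/136 through 358/141) that separates ribose
from base labeling kinetics.  Positional isotopomers within a moiety are
out of scope — MRM cannot distinguish them.

## Peak detection and integration

The detector boxcar-smooths (default window 5 points), takes local maxima,
and walks to the flanking valleys or to baseline return, whichever comes
first; noise is estimated as 1.4826 × the median absolute deviation of the
smoothing residual, and SNR is peak height over that noise floor.
Integration is trapezoidal above a straight baseline drawn between the peak
bounds — deliberately the same simple geometry vendor software applies by
default, rather than exponential-modified-Gaussian fitting, so areas are
auditable.  Defaults (min SNR 3, min width 0.02 min) are package choices;
no instrument-specific thresholds are implied.  Deconvolution of co-eluting
sugar phosphates is a non-goal: the acquisition method itself does not
separate them well.

The simulator writes Gaussian peaks at library retention times on a uniform
grid (default 0.01 min) plus seeded Gaussian baseline noise clipped at
zero.  It emulates well-behaved single-analyte MRM traces; it does not
emulate tailing, baseline drift, detector saturation or co-eluting
interferences, so passing recovery tests bound numerical error of the
integrator, not real-world chromatographic error.

## Isotopologue distributions and natural-abundance correction

Percent label incorporation is defined as 100·(1 − f₀), the fraction of
molecules carrying at least one label; the atom-weighted mean enrichment
Σ i·fᵢ / n is exposed alongside as a companion statistic, since "overall
incorporation" is sometimes read either way.  Both raw and
natural-abundance-corrected fractions are available, and outputs carry a
`corrected` flag so the two are never conflated.

The correction matrix is binomial: column j holds the probability that a
molecule with j tracer labels gains i − j extra mass units from natural
heavy isotopes among its remaining tracer-element atoms.  For derivatized
analytes the unlabeled-atom count includes the derivatization-tag atoms
(7 carbons per OBHA site) — the tag contributes natural abundance even
though it is never biosynthetically labeled.  The system is solved by
non-negative least squares rather than matrix inversion for robustness to
noise; a solution whose unconstrained counterpart goes negative beyond
tolerance is flagged with a warning.  Only the tracer element's +1 isotope
is corrected; ¹⁸O/³⁴S and +2 contributions are negligible at unit
resolution for these analytes and are not modeled.

Moiety-resolved labeling classifies every (k, j) channel: area share with
j ≥ 1 is the fragment-moiety labeled fraction, area share with k − j ≥ 1
the remainder-moiety fraction.  Missing feasible channels lower a coverage
flag rather than raising, since published acquisition subsets rarely cover
the full grid.

## Kinetics

The pathway archetypes (high/low flux, positive/negative cooperativity,
single/multiple inputs, linear/cyclic organization) are qualitative; the
package adopts the simplest quantitative reading that reproduces all of
them: first-order well-mixed pool turnover, dLᵢ/dt = (F/Pᵢ)(donorᵢʰ − Lᵢ),
with the donor of the first pool the external precursor enrichment,
cooperativity an exponent h on the donor fraction, and cyclic topology a
single recycle edge mixing a fraction of the last pool into the first
pool's influx.  These are documented interpretations, not claims about
mechanism.  Time units are the user's (hours by convention for growing
cells) and are never hard-coded.  The ODE solver is LSODA at rtol 1e-8 /
atol 1e-10; a single pool against the closed form A(1 − e^{−(F/P)t}) agrees
to 1e-6.

Multi-input metabolites combine independently labeling moieties: the M+k
distribution is the convolution of per-moiety binomials at each moiety's
enrichment, and the fully labeled species fraction is the product of the
per-moiety fully-labeled fractions.  Independence is an assumption — it
ignores shared upstream pools — and is stated as such.

Curve fitting (via lmfit) offers A(1 − e^{−kt}), the two-pool lagged closed
form, and the Hill-time sigmoid A·tʰ/(t50ʰ + tʰ).  All-zero data returns a
degenerate fit rather than an error.  Moiety comparisons report rate and
half-time ratios; when the underlying points are supplied, a
residual-resampling bootstrap (default 200 refits) gives a 95% percentile
interval on the rate ratio.

The tracer-design calculator is a ratio: initial precursor enrichment =
labeled / (labeled + unlabeled medium + unlabeled internal pool).  The
conditioning design with equal halves and a depleted internal pool gives
0.5 — the ~50% ceiling on downstream incorporation that motivates that
design.  Full ¹³C metabolic flux analysis (EMU/cumomer estimation) is
explicitly out of scope.

## Test problem sizes and numerical choices

The suites favor exactness where it is available (integer m/z, closed
forms, brute-force enumeration oracles) and seeded Monte-Carlo elsewhere:
peak-area recovery uses 200 simulated traces at height/noise = 100, rate
recovery 50 replicates at 5% noise on 12 time points, and the bootstrap
coverage check 25 replicates at 80 resamples — sizes chosen to make the
statistics stable while keeping the whole suite around ten seconds.
Hypothesis property tests are derandomized for reproducibility.  All random
draws go through `numpy.random.default_rng` with explicit seeds.
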