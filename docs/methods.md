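# Methods

## Data model

A study is one case-control comparison at one biallelic site: genotype
counts (common homozygote aa, heterozygote ab, variant homozygote bb) per
arm plus etiology metadata.  Allele counts derive as `a = 2·n_aa + n_ab`,
`b = 2·n_bb + n_ab`.  Where a source table's stated arm size disagrees with
its genotype-row sum, the genotype sum is authoritative (it feeds every
downstream statistic) and the mismatch is logged.  Studies contributing
several disease arms against one shared control series are kept as separate
records with no unit-of-analysis correction, replicating how this
literature pools them.

The three bundled fixtures transcribe the published genotype tables for
TGF-β1 -509C/T (25 rows), codon 10 (18 rows) and codon 25 (20 rows) in
chronic liver disease, including the printed per-arm HWE p-values as
metadata columns used only for verification.  Two transcription notes: the
codon-25 Falleti cirrhosis row sums to 187 cases though the characteristics
table says 188, and the Yousefi AIH row to 43 though 44 is stated; the
genotype sums are carried.  Two CHC cohorts (Sánchez-Parada 2013 and
Maria 2013) print identical arm sizes and near-identical genotypes —
a possible duplicate publication — and are both retained as printed.

## Hardy-Weinberg filter

Pearson's χ² goodness-of-fit of the three genotype classes against
`n·p̂², 2n·p̂q̂, n·q̂²` with 1 df and no continuity correction; this exact
variant reproduces all 126 printed case/control p-values to 3 decimals.
Filtering uses the control arm only, at α = 0.05: control-arm departure
signals genotyping or sampling error, while case-arm departure can be the
association signal itself (several retained studies have case p < 0.01).
A monomorphic arm has nothing to test and maps to χ²=0, p=1, flagged, so
it is never excluded on HWE grounds.  Exact HWE tests (Wigginton-style) and
multi-allelic sites are out of scope.

## Effects and pooling

Per-study odds ratios are Woolf log-normal estimates with z = 1.96
intervals (the convention of the published tables; not the 1.95996
quantile).  Zero-cell studies get 0.5 added to all four cells — both for
the Woolf effect and inside the Mantel-Haenszel sums.  The latter departs
from the textbook "MH tolerates zero cells" advice deliberately: the
dominant meta-analysis software corrects zero-cell studies everywhere, and
only that convention reproduces the published sparse-table subgroup rows
(e.g. codon-25 CHC homozygote 0.44 rather than the raw-count 0.41).  A
study whose exposure class is empty in *both* arms carries no odds-ratio
information and is dropped from that contrast; this reproduces the
published 19 → 14 study drop for the codon-25 homozygote and recessive
models, whereas dropping every zero-cell study would give 15.

Fixed effects: Mantel-Haenszel with Robins-Breslow-Greenland variance
(validated to 1e-10 against an independent implementation and exactly
against the published two-study subgroups 2.33 / 14.73 / 14.69).  Random
effects: DerSimonian-Laird on the Woolf effects, with Q computed on
fixed-effect inverse-variance weights.  Model selection: fixed iff
`P_het > 0.1` and `I² < 50`, strict inequalities, so boundary values pool
under random effects.  REML/Paule-Mandel τ², Hartung-Knapp adjustment and
Peto pooling are out of scope.

Leave-one-out sensitivity analysis defaults to random effects regardless of
the selection rule, matching the published procedure; subgroups estimate
τ² independently per partition.

## Publication bias

Egger's test is the classic unweighted regression of the standard normal
deviate on precision with a t test of the intercept (k−2 df, two-sided);
Begg's test uses Kendall τ-b with tie-corrected variance and continuity
correction on the standardized deviates `vᵢ = (yᵢ − ŷ_FE)/√(varᵢ − var_pool)`.
Both require k ≥ 3.  Our Begg p for the -509 allele contrast matches the
published 0.2661 exactly; the published Egger column matches no standard
formulation we tried (classic, random-effects-weighted, Harbord, Peters) and
is treated as unverifiable — the classic form is kept.  Funnel output is
plot-ready data (points plus pseudo-95% boundary), not rendered graphics.

## Synthetic data generator

Controls draw genotypes from `(1−q)² + fq(1−q), 2q(1−q)(1−f), q² + fq(1−q)`
— Hardy-Weinberg at variant frequency `q` when the inbreeding coefficient
`f` is 0.  Cases reweight the control probabilities by
`(1, or_het·e^δ, or_hom·e^δ)` renormalized, with the study shift
`δ ~ Normal(0, τ²)`.  Genotype-contrast log ORs are therefore exactly
`ln(or) + δ` — the normal random-effects model — while the allele-scale
log OR is an attenuated function of δ (slope² ≈ 0.37 at q = 0.3), so τ²
recovery is assessed on the homozygote contrast and location recovery on
the allele contrast, whose expected value under `or_hom = or_het²` equals
`ln(or_het)` exactly.  Defaults state a realistic null corpus for this
literature: k = 15 studies, 100–400 individuals per arm, q = 0.3, exact
HWE, no effect, no heterogeneity.  Each study has its own substream keyed
by (seed, study index), so growing k never perturbs earlier studies.

The generator emulates count noise, arm-size variation and normal
between-study heterogeneity; it does not emulate linkage disequilibrium,
covariate confounding, genotyping error or publication-selection
mechanisms.  A green calibration test therefore establishes correctness of
the estimators under the stated model, not robustness to those
misspecifications.

## Numerical conventions

Two-sided p-values from the standard normal (pooling Z), χ² (Q, HWE) and
Student t (Egger).  Text rendering floors p at `<0.00001`, prints OR/CI at
2 decimals and I² as an integer percent; JSON output carries 6 significant
digits with fixed key order, so identical inputs give byte-identical files.
Single-study pools carry Q = 0, I² = 0, P_het = 1 by convention and print
"–" for heterogeneity columns.

## Reproduction status

95 of the 100 published pooled rows (overall plus subgroup tables)
reproduce within max(0.02, 1%) on OR and both CI bounds with exact study
counts and model labels.  The five exceptions are defects of the printed
tables, not of the computation: one OR contradicts its own printed CI
(whose geometric mean equals our estimate), one subgroup row was evidently
computed from a study the source's own HWE rule excludes, and three
two-study rows containing a monomorphic case arm use a sparse-data CI
convention that no standard variant reproduces (our ORs still agree within
0.015).
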