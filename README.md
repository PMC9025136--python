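# xopop

Sex-specific crossover rates and crossover interference from a single
outbred F1 cross.

## The problem

In forest trees and other highly heterozygous, long-generation organisms,
the reciprocal backcrosses that classical recombination studies rely on are
impractical. An F1 full-sib family still carries the needed information: a
SNP heterozygous in one parent and homozygous in the other (`ab × aa`
female-informative, `aa × ab` male-informative) segregates 1:1 and behaves
like a backcross marker for that parent — the *pseudo-testcross* design.
A RAD locus that happens to carry one SNP of each type reads out **both**
parents' meioses at the same genomic position, so the two parents'
crossover (CO) landscapes can be compared interval by interval on one
population, with no inbred lines.

The catch is that linkage phase is not fixed in an outbred F1, so every
statistic must infer coupling vs repulsion before it can estimate anything.
`xopop` implements that analysis end to end, together with a forward
simulator that makes every stage verifiable by parameter recovery.

## The statistics

**Two-point rates.** At two same-type SNPs the progeny classes
(het,het), (het,hom), (hom,het), (hom,hom) with counts `n11..n14` are
multinomial with probabilities `((1−r)/2, r/2, r/2, (1−r)/2)` under
coupling. Phase is inferred by maximum likelihood (repulsion relabels
classes 1↔2, 3↔4), after which

    r̂ = (n12 + n13) / n,     r̂ ≤ 1/2.

Equality of the female and male rates over the same interval is tested with
`LR = 2 log [L(r̂_f) L(r̂_m) / L(r̂)²-pooled]`, asymptotically χ²₁.

**Three-point interference.** Across two adjacent intervals with rates
`r1, r2`, the coefficient of coincidence `C` parameterizes the joint
crossover probabilities `p11 = r1·r2·C`, `p01 = r2 − p11`, `p10 = r1 − p11`,
`p00 = 1 − r1 − r2 + p11`. From the 8 genotype classes at three same-type
SNPs (phase-canonicalized by single-marker het/hom flips),

    r̂1 = (n3+n4+n5+n6)/n,  r̂2 = (n2+n3+n6+n7)/n,  Ĉ = (n3+n6) / (n·r̂1·r̂2),

and the LR test of `C = 1` (a G-test of independence of the two intervals'
crossover indicators) classifies pairs as negative (`Ĉ > 1`) or positive
(`Ĉ < 1`) interference. Marker triples are chosen with a minimum interval
length (MIL) ladder, 0.5–5 Mb.

**Interference strength.** Reconstructed crossovers (haplotype switches
along each gamete) are fit with the stationary gamma renewal chiasma model:
inter-chiasma distances ~ Gamma(shape ν, rate 2ν) per Morgan with
independent ½-thinning to the observed chromatid. ν = 1 is no interference
(Poisson), ν > 1 positive, ν < 1 negative; parents are compared by a paired
t test on per-chromosome ν̂.

## Worked example

Simulate a two-chromosome population in which the female map is 1.3× the
male map and the female clusters crossovers more strongly
(ν_f = 0.55 vs ν_m = 0.9), then run the full pipeline:

```python
import numpy as np
from xopop import simdata, genotypes, tagselect, corate, interference, strength

cfg = simdata.SimConfig(
    n_progeny=250,
    chromosomes=[("Chr01", 20_000_000, 3.38, 2.6), ("Chr02", 20_000_000, 3.38, 2.6)],
    nu_female=0.55, nu_male=0.9,
    tag_spacing_bp=150_000, missing_rate=0.20, seed=11,
)
dataset, truth = simdata.simulate_population(cfg)
filtered, report = genotypes.apply_filters(dataset)
tags = tagselect.select_spaced_tags(tagselect.pair_snps_into_tags(filtered))
results = corate.scan_intervals(filtered, tagselect.build_intervals(tags))
summary, paired = corate.chromosome_summary_and_paired_test(results, unit="interval")
fits = strength.fit_all_chromosomes(filtered)
```

which prints (via the obvious `print` calls):

```
markers kept: 287/532
tags: 76, intervals: 74
mean r (female) = 0.0654, mean r (male) = 0.0522
paired Wilcoxon over 74 intervals: p = 3.72e-05
significant intervals at 0.05: 8
parent chrom  nu_hat    se  n_events
female Chr01   1.047 0.078       683
female Chr02   1.023 0.073       733
  male Chr01   1.442 0.124       561
  male Chr02   1.351 0.117       540
```

Reading the output: the 20%-missing filter keeps 287 of 532 SNPs; the
surviving opposite-type SNP pairs form 76 spaced tags (74 intervals). The
female per-interval rate is higher (0.065 vs 0.052, paired rank test
p ≈ 4e-5), as built into the simulation, and the female's ν̂ is lower on
both chromosomes — stronger crossover clustering — matching ν_f < ν_m.
Marker-based ν̂ is biased toward 1 relative to the generative values
because tightly clustered double crossovers between adjacent markers go
undetected (see `docs/methods.md`); the parent ordering is preserved.

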