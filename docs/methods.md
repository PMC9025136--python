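# Methods

## The design being analyzed

An outbred F1 full-sib family of ~250 progeny, genotyped at SNPs on RAD
loci. SNPs heterozygous in exactly one parent segregate 1:1 and carry
backcross-like information for that parent (`ab × aa` female-informative,
`aa × ab` male-informative; the first pair of letters is the female
genotype). A RAD tag holding one SNP of each type (< 1 kb apart) observes
both parents' meioses at one genomic point; tags spaced > 100 kb define the
intervals over which the two parents' crossover rates are compared.

Progeny calls are coded relative to the informative parent: `het` means the
progeny carries the informative parent's alternate allele; `hom` means it
equals the homozygous parent's genotype; everything else is missing.

## Two-point model

At two same-type SNPs, the four progeny classes are multinomial with
probabilities `((1−r)/2, r/2, r/2, (1−r)/2)` under coupling. Phase is not
fixed in an outbred F1, so it is estimated first: the maximum-likelihood
phase is coupling iff the "recombinant" classes are the minority, with ties
(r̂ = 1/2) broken to coupling and flagged unlinked. Repulsion relabels
classes 1↔2 and 3↔4, after which the closed-form MLE is the canonical
recombinant fraction, guaranteed ≤ 1/2.

Rate equality between parents over one interval is tested with the LR
statistic against the pooled-rate null; multinomial constants cancel, so
the statistic needs only the recombinant/parental splits. `0·log 0 := 0`
handles boundary tables (no recombinants). The p-value uses the asymptotic
χ²₁ even at small counts; intervals with fewer than 20 informative progeny
in either parent are flagged `low_n` rather than switched to an exact test.
Missing calls are dropped pairwise per SNP pair. No multiple-testing
correction is applied by default (raw 0.05/0.01 flags are reported);
Benjamini–Hochberg is available as an option.

Runs of ≥ 2 consecutive significant intervals (sharing a boundary tag) are
grouped into significant regions; lone significant intervals are reported
separately. Genome-level comparison uses a two-sided Wilcoxon signed-rank
test, exact for ≤ 25 pairs. The pairing unit is the chromosome mean by
default; interval-level pairing is provided because with few chromosomes
the exact test cannot reach 0.05 (minimum two-sided p is `2/2^k` for k
pairs — 0.0625 at k = 5), so small synthetic genomes are only testable at
the interval level.

## Three-point model

Two adjacent intervals with rates `r1, r2` and coefficient of coincidence
`C` have joint crossover-occurrence probabilities `p11 = r1 r2 C`,
`p01 = r2 − p11`, `p10 = r1 − p11`, `p00 = 1 − r1 − r2 + p11`; validity of
all four constrains `C ≤ min(1/r1, 1/r2)` automatically. The 8 genotype
classes at three same-type SNPs (lexicographic, het before hom) collapse
onto these probabilities in the canonical coupling-coupling phase:
parental `n1+n8`, second-interval-only `n2+n7`, first-interval-only
`n4+n5`, double `n3+n6`. MLEs are closed-form marginal frequencies plus
`Ĉ = doubles/(n r̂1 r̂2)`; `Ĉ` is undefined when a marginal rate is zero,
and such triples are reported without a test.

The four phase combinations of the two sub-pairs reduce to the canonical
order by flipping het/hom at a single marker: (C,R) flips marker 3, (R,C)
marker 1, (R,R) marker 2. The flip set is determined only up to the global
complement (flipping all three markers), which permutes classes within the
likelihood groupings, so estimates are invariant to the choice — this is
property-tested to bit identity. Sub-pair phases are inferred marginally
with the two-point rule; a triple with an uninformative sub-pair
(r̂ = 1/2) is skipped as phase-ambiguous.

The LR test of `C = 1` keeps `r1, r2` free; since their MLEs are the
marginal frequencies under both models, the statistic is exactly the
G-test of independence of the two intervals' crossover indicators, read
against χ²₁. Direction (negative for `Ĉ > 1`, positive for `Ĉ < 1`) is
only assigned to significant pairs. χ²₁ is an approximation with known
boundary issues at `Ĉ = 0` and is documented as such; it is also
anticonservative when the expected double count `n r1 r2` is small (at
`n = 250, r1 = r2 = 0.1` — expected doubles 2.5 — the empirical size at
nominal 0.05 is ≈ 0.08; at `n = 1000` it is ≈ 0.055). The test is applied
as specified, with the per-pair counts reported so users can judge.

Marker triples come from a greedy left-to-right chain requiring every
consecutive gap ≥ the minimum interval length (MIL, ladder 0.5–5 Mb);
consecutive triples share one interval. Per MIL and parent the scan
reports the significant-pair count split by direction and the genome
coverage of the significant pairs' physical spans (first to third marker,
unioned before dividing by genome size). Pairs significant in both parents
are matched by physical overlap — female and male triples use different
SNPs, so identity matching is impossible; a female pair is "common" if its
span overlaps any male significant span, and common coverage is the union
of the intersections.

## Crossover reconstruction and the gamma model

For one parent and chromosome, the phase chain (two-point phase of every
adjacent marker pair, flips accumulated left to right) turns the het/hom
matrix into a consistent 0/1 haplotype signal per progeny. Each sign
change between consecutive non-missing markers is one crossover, placed at
the bracket midpoint; missing markers widen the bracket. Marker genetic
positions are the cumulative sums of the adjacent canonical recombination
fractions (additive small-interval approximation; Haldane/Kosambi
transforms are deliberately not applied because adjacent intervals are
short). An adjacent pair at exactly r = 1/2 has unbounded map distance and
is capped at 0.499 with a warning.

Interference strength is the shape ν of a stationary gamma renewal chiasma
process on the four-strand bundle: inter-chiasma distances
Gamma(ν, rate 2ν) on the chromatid Morgan scale (2 chiasmata per Morgan),
each chiasma passed to the observed chromatid with probability ½, hence 1
crossover per Morgan per gamete. ν = 1 is Poisson (no interference), ν > 1
regular spacing (positive), ν < 1 clustering (negative).

The observed-chromatid likelihood uses the ½-thinned process: inter-event
density `f*(y) = Σ_k 2^-k Gamma(kν, 2ν)(y)`; the first event from the
stationary start `g*(x) = Σ_k 2^-k · 2[F_{(k−1)ν}(x) − F_{kν}(x)]`
(derived from the equilibrium residual distribution); survival past the
last event `S*(y) = 1 − Σ_k 2^-k F_{kν}(y)`; and event-free meioses
contribute the stationary no-event probability, obtained in closed form
from the CDF integrals `∫F_a = x F_a(x) − (a/2ν) F_{a+1}(x)`. The series
is truncated at k = 27 (weight < 1e-8). At ν = 1 the likelihood reduces
exactly to the unit-rate Poisson value (−L per meiosis), which is unit
tested. ν̂ comes from bounded 1-D optimization on [0.05, 20] (bound hits
flagged); the SE from the numerical observed information. Zero-length
inter-event gaps (events separated only by r = 0 intervals) are clipped at
1e-6 Morgans because Gamma densities with shape < 1 diverge at 0. Meioses
with fewer than two non-missing markers are excluded entirely; meioses
with no detected crossover are retained as censored observations.

Parents are compared with a two-sided paired t test on per-chromosome ν̂;
a constant non-zero difference yields t = ±∞, p = 0, and an all-zero
difference vector degenerates to p = 1 with a warning.

## The simulator

`simdata` inverts the gamma model: chiasmata are drawn from the stationary
renewal process (started 8 Morgans before the chromosome — 16 mean gaps of
burn-in, so the residual distribution has converged far below Monte Carlo
resolution), thinned by ½, and turned into genotypes via a random (or
all-coupling) phase assignment per SNP. The physical↔genetic map is linear
per chromosome, with independent female and male genetic lengths. Because
thinning preserves per-interval parity, the model's map function has the
closed Mather form `r(d) = (1 − p0(d))/2` with
`p0(d) = (1 − F_{ν+1}(d)) − 2d(1 − F_ν(d))`, and the model-implied CoC of
adjacent windows follows from `p0` over the union window; both are exposed
and recorded as ground truth for recovery tests, alongside every realized
crossover position.

Default conditions mirror the emulated design: 250 progeny, RAD tags of
two opposite-type SNPs 400 bp apart, up to 20% missing calls, per-interval
rates of a few percent. The end-to-end study configuration lays tags every
150 kb *before* filtering: with i.i.d. 20% missing calls, the > 20%-missing
marker filter removes about half of all markers
(P(Bin(250, 0.2)/250 > 0.2) ≈ ½), so ~300 kb effective spacing survives —
the tag density the real design operates at. Segregation distortion is off
by default; the optional distortion injector redraws calls i.i.d. with a
biased transmission probability at a chosen fraction of SNPs, which breaks
linkage at those SNPs and exists solely to exercise the 1:1 filter. A
uniform miscall-rate option exists for robustness checks. Genotyping error
is otherwise not simulated: the DP/GQ call filters of the genotyping stage
subsume it. The simulator does not enforce an obligate chiasma per
bivalent; with ν near the estimated values and chromosome maps well above
1 Morgan, the zero-chiasma probability is small, and the renewal model is
applied as stated.

What the simulator does **not** emulate: read-level noise and depth
variation (missingness is i.i.d. per call, whereas RAD coverage is locus-
and individual-structured), recombination-map heterogeneity along the
chromosome (the bp↔Morgan map is linear), linkage disequilibrium with
unmodeled selection, and genotyping-error correlation between nearby SNPs.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to every field artifact.

## Filters

Call level (VCF only, when FORMAT fields are present): a heterozygous call
needs allele depth ≥ 3 on both alleles and GQ > 30; a homozygous call
needs depth ≥ 5 on the called allele (GQ does not gate homozygotes); with
only total DP available the same thresholds apply to DP. The homozygote
impossible under the cross is set to missing. Marker level: segregation
type must be informative; the 1:1 χ² test (no continuity correction,
`χ² = (n_het − n_hom)²/n`, 1 df) must give p ≥ 0.01 — "deviating" markers
are removed, ties at exactly 0.01 kept; and markers with strictly more
than 20% missing progeny calls are removed. Filtering is idempotent.

## Known limitations

- **Marker-based ν̂ is biased toward 1.** Crossover detection sees only
  the parity between adjacent markers, so clustered double crossovers
  falling within one marker interval vanish. Under strong clustering
  (ν ≈ 0.55) with ~0.03-Morgan marker spacing this loses several percent
  of events and pulls ν̂ up (observed ≈ 1.0–1.1); regular processes
  (ν ≥ 1) are nearly unaffected. Fits on true event positions (the
  simulator's output) are unbiased — recovery at 2,000 meioses is within
  ±0.03–0.08 of truth for ν ∈ [0.5, 2]. Comparisons *between* parents
  analyzed at the same marker density preserve ordering.
- **Ĉ has irreducible sampling noise.** Its variance is driven by the
  double-crossover count `n r1 r2 C`; at `n = 10,000, r1 = r2 = 0.1` the
  delta method gives sd(log Ĉ) ≈ 5.7% at C = 2 and ≈ 13% at C = 0.5, so
  individual Ĉ values at realistic scales carry 10–25% relative error.
- The χ²₁ null of both LR tests is asymptotic; see the calibration notes
  above for when it is trustworthy.
- The additive genetic scale slightly compresses map distance where
  intervals are long or interference is negative.

## Problem sizes used by the test suite

Simulation-backed checks run at the scale the estimators are meant for:
5,000–20,000 meioses for process-level properties, 250–500 progeny for
population-level ones, 2,000 meioses per ν-recovery fit, 500–5,000
multinomial replicates for calibration and recovery rates, and a
five-chromosome, 250-progeny synthetic study for the end-to-end check.
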