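# Methods

## Genetic model

Colour is modelled as strictly binary (purple / white) and controlled by
two unlinked-or-linked loci A and B carried by haploid nuclei. The
phenotyped unit is a dikaryon; a colour rule is a total function from
(dominant allele present at A across the pair?, dominant at B?) to a
colour. The default rule is duplicate recessive epistasis — purple iff
both flags are true — which yields 9:7 in a dihybrid random union of
gametes. Alternative rules (`single_locus_A`, `single_locus_B`,
`dominant_either`) are first-class `GeneticModel` objects so competing
hypotheses can be scored on the same data; every expected ratio anywhere
in the package is derived from gamete-class frequencies plus a rule,
never looked up.

Mating is bipolar: one locus, two idiomorphs (MAT1 for the white parent's
type, MAT2 for the purple parent's), and only unlike idiomorphs fruit.
The mating-type locus is assumed unlinked to A and B. Whether A and B
share a chromosome is deliberately left open: the recombination fraction
r ∈ [0, 0.5] is an explicit parameter everywhere (r = 0.5 ≡ unlinked), so
both hypotheses are expressible.

## Meiosis and cross simulation

One F1 dikaryon of known phase produces gametes in the four haplotype
classes at (1−r)/2 (parental) and r/2 (recombinant). Segregation
distortion is modelled as per-locus transmission weights multiplying the
Mendelian frequencies before renormalisation — gamete-level viability
selection, the simplest mechanism consistent with observed skews; other
mechanisms (lethal alleles, cytoplasmic effects, rearrangements) are not
modelled. Weights are expectation-matched to the observed ratios: with
B:b weights 30:57 the expected dominant-B marginal is exactly 30/87
independent of r (each parental/recombinant pair carries one B and one
b), and likewise MAT1:MAT2 weights 54:33 give an expected 54:33 idiomorph
split.

Fruiting failure is a genotype-independent Bernoulli event (default
success 0.671, applied to the inbred and recombinant-inbred designs,
whose published success rate it is; test-cross and back-cross tables are
generated complete, as observed). Replicated cross attempts are available
via a `replicates` flag but default to a single trial per pair.

Markers are inherited along contigs under the Haldane (no interference)
model: adjacent positions switch parental origin with probability
r = (1 − e^(−2d))/2, d in Morgans, converting physical distance at a
configurable 400 kb/cM (an arbitrary but fixed scale chosen to put the
default 2 Mb marker spacing at ≈ 5 cM, i.e. adjacent r ≈ 0.048). A contig
carrying a colour locus anchors its chain on that locus's parental origin
(recessive allele = white-parent band 'A'); trait-free contigs start from
a fair coin flip, so different contigs assort independently.

## Inference pipeline

Typing proceeds exactly as the breeding logic dictates: P/W from the
test-cross colour; Pd/Pr/Wd/Wr from the recombinant-tester colour, with
disagreement between the two recombinant testers flagged `inconsistent`
(never majority-voted) and absent observations flagged `ambiguous` —
strains with failed crosses are retained and excluded from ratio
denominators, never silently dropped. Haplotype classes are *solved*, not
looked up: the unique class whose predicted cross colours match all
observations under the colour rule. The same solver deduces unknown
tester haplotypes and reports the candidate set on ambiguity.

The recombination fraction is the non-parental fraction of typed strains,
with a Clopper–Pearson 95% interval and an exact two-sided binomial test
of r = 0.5 (α = 0.05 throughout; conventional). Segregation tests use
Pearson's chi-square without continuity correction (a Yates flag exists);
df = categories − 1. Candidate colour models are ranked by chi-square
summed across populations, with expected ratios recomputed per design; a
model assigning probability zero to an observed phenotype gets infinite
chi-square. This matches ratio-test reasoning; a likelihood-based ranking
was considered and rejected as it adds nothing for two-category counts
(the chi-square is the score test of the same multinomial).

The `ColorInheritance` / `ColorInheritanceResults` pair wraps the
pipeline statsmodels-style: the model object holds the data and tester
roles, `fit()` produces the typed strain table, class counts, r estimate,
segregation verdicts, model ranking and a `summary()` table.

## Two-point linkage mapping

Haploid progeny only: rf between two markers is the mismatch fraction
over strains informative for both (missing calls excluded pairwise, never
imputed), and

    LOD = n_rec·log10(2·r̂) + n_par·log10(2·(1−r̂)),

where a zero-count term contributes nothing (the 0·log 0 = 0 likelihood
convention), so co-segregating markers score n·log10(2) and r̂ = 0.5
scores exactly 0. Linkage groups are connected components of the
LOD ≥ threshold graph (default 3). Ordering minimises total adjacent rf —
exhaustively for groups of ≤ 7 markers, otherwise greedy chain extension
from the tightest pair refined by 2-opt; ties break lexicographically and
each group is canonically oriented (first marker name ≤ last), making the
order-or-its-reverse equivalence explicit. Map distances use Kosambi by
default (common practice for fungal maps), Haldane selectable; an
adjacent rf ≥ 0.5 inside a group is capped just below 0.5 for the
distance transform and logged. A binary trait enters as a pseudo-marker
(purple ↦ purple-parent band); it is assigned to the group of its
best-LOD marker if that LOD reaches the threshold, with the two
smallest-rf group markers reported as flanking, otherwise reported
unplaced.

## Synthetic studies

`generate_study` emulates the study's structure end to end: parents ab
(MAT1) × AB (MAT2); 87 mapping gametes at r = 0.377 with the distortion
weights above; an `Ab` test-cross tester whose idiomorph is modelled as
unconstrained (the real tester mated successfully with the whole mapping
population); two `aB` recombinant testers, one per idiomorph; a
back-cross to the ab parent (only compatible strains attempt); an inbred
design over 29 strains split 15 MAT1 / 14 MAT2 — the only split of 29
producing the published 210 compatible pairs; and a recombinant-inbred
design of every strain against its compatible recombinant tester.
Markers default to three contigs (10 + 8 + 5 SSR-style markers at 2 Mb
spacing) with locus A between the 5th and 6th markers of "Contig9" and
locus B mid-"Contig19"; names follow the SSR#### style but are synthetic,
and physical coordinates are decorative metadata. Everything regenerates
byte-identically from one integer seed.

What the generator does *not* emulate: genotyping error and missing
marker calls (available via `missing_rate`, default 0), genotype-dependent
fruiting, crossover interference, more than two colour loci, and any
sequence-level biology. Passing recovery tests therefore demonstrates the
logic of the pipeline under the stated stochastic model, not robustness
to real-data artefacts.

## Problem sizes and numerical choices

Simulation-based tests use 200 replicates of n = 61 for CI coverage,
n = 10,000 gametes for goodness-of-fit of the meiosis model, 5,000
replicates of n = 87 for the chi-square type-I error, and 20 seeds of
n = 250 progeny for linkage-map recovery — sizes at which the binomial
tolerances quoted in each test are meaningful while the whole suite runs
in seconds. Phenotype-probability tables must sum to 1 within 1e-12.
Degenerate inputs are reported rather than raised wherever a field
scientist would meet them (zero fruiting → everything ambiguous; a trait
unlinked to all markers → unplaced).

## Known limitations

Two-point mapping only (no multipoint/EM likelihood and no interval QTL
mapping); haploid progeny only; a single bipolar mating locus (no
tetrapolar systems or di-mon crosses); binary colour with no intensity
scale. The fine-mapping step of the real study depends on wet-lab
genotyping of recombinants and is represented only by its logical
skeleton: flanking-marker narrowing on synthetic data.
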