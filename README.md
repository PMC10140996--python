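# auricolor

Genetic analysis of a two-locus colour trait in a bipolar heterothallic
fungus: breeding-population simulation, strain typing and haplotype
deduction from cross phenotypes, segregation-distortion testing,
recombination-fraction estimation, and two-point LOD linkage mapping in
haploid progeny.

## The problem

Fruiting-body colour in *Auricularia cornea* (a cultivated jelly fungus)
segregates purple vs white. The white phenotype is commercially valuable,
but the trait does not behave as a single Mendelian locus: test-cross and
back-cross progenies of a white × purple hybrid deviate from the expected
1:1 ratio. The data are instead explained by **duplicate recessive
epistasis** at two loci A and B: a dikaryon is purple only when a dominant
allele is present at *both* loci across its two haploid nuclei
(`A_B_` → purple; `A_bb`, `aaB_`, `aabb` → white), giving the classic 9:7
dihybrid ratio.

Because the fungus is bipolar heterothallic, every phenotyped individual
is a dikaryon formed by mating two haploid monokaryons with different
mating-type idiomorphs, and the mapping population is a set of haploid
meiotic products — which makes genotype inference a matter of solving
cross colours against testers of known haplotype class:

* a single-dominant tester (class `Ab`) splits the mapping strains into
  purple-type (P) and white-type (W);
* recombinant-class testers (`aB`) refine P/W into four types
  (`Pd`, `Pr`, `Wd`, `Wr`), each of which identifies a unique haplotype
  class (`AB`, `aB`, `ab`, `Ab`) under the colour rule;
* the proportion of recombinant classes estimates the recombination
  fraction r between A and B; and
* parental-origin SSR marker matrices place each locus on a linkage map
  via two-point rf/LOD analysis
  (`LOD = n_rec·log₁₀(2r̂) + n_par·log₁₀(2(1−r̂))`, grouping at LOD ≥ 3).

The package implements this entire genetic-logic layer, plus a seeded
synthetic-study generator so every stage is testable without wet-lab data.

## Worked example

```python
from auricolor import StudyConfig, generate_study, ColorInheritance

bundle = generate_study(StudyConfig(seed=1))   # 87-strain synthetic study
res = ColorInheritance.from_bundle(bundle).fit()
print(res.summary())
```

```
Colour-inheritance analysis
============================================================
Strain types: Pd=13, Pr=7, Wd=32, Wr=11, ambiguous=24
Haplotype classes: AB=13, Ab=11, aB=7, ab=32
Recombination: r_hat = 18/63 = 0.2857 (95% CI 0.179-0.413); linkage supported
------------------------------------------------------------
segregation test                    chi2         p  verdict
mating type 1:1                    7.184    0.0074  distorted
test-cross P:W 1:1                 9.667    0.0019  distorted
B:b 1:1                            9.667    0.0019  distorted
back-cross P:W under duplicate_recessive (r=0.5)   0.269    0.6041  consistent
------------------------------------------------------------
candidate model               chi2         p  fit
duplicate_recessive          9.935    0.0070  poor
single_locus_B              15.118    0.0005  poor
single_locus_A                 inf    0.0000  poor
dominant_either                inf    0.0000  poor
Best-fitting model: duplicate_recessive
```

Reading the output: 63 of the 87 strains received a full four-way type
(the rest stay `ambiguous` because, at the configured 67% fruiting
success, some informative crosses never fruited — they are reported, not
dropped). The recombinant classes give r̂ with an exact Clopper–Pearson
interval. The mating-type and test-cross ratios are flagged as distorted
segregation (the generator deliberately reproduces the study's 54:33 and
30:57 skews), the back-cross fits the 3:1 expectation, and the
duplicate-recessive model ranks first among the candidates — single-locus
models are excluded outright because they predict zero probability for
observed phenotypes.

Linkage mapping works the same way from a marker matrix:

```python
from auricolor import TwoPointLinkage
from auricolor.linkage import trait_vector_from_colors

res = TwoPointLinkage(bundle.marker_matrix, traits={...}).fit(lod_threshold=3)
print(res.summary())   # groups, cM positions, trait placements
```

which, on the default synthetic design, recovers the three contigs as
three linkage groups and places the colour-locus pseudo-markers between
their true flanking SSR markers.

The same pipeline is scriptable from the shell:

```sh
auricolor simulate --seed 1 --out study/
auricolor infer study/ --out study/inference.json
auricolor map study/ --out study/map.tsv
auricolor report study/ --out study/report.json
```

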