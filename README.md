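# sporemap

Crossover mapping, tetrad analysis, and mutation-effect annotation for
fungal random-spore genetics — built around the kind of study done in the
basidiomycete *Coprinus cinereus*, where ~100 haploid spores per cross are
genotyped at SSR/SNP/indel markers along a chromosome, crossovers are read
off as switches of parental origin, and meiotic chromosome-segregation
errors are inferred from how many spores of each dissected tetrad
germinate.

It is aimed at fungal geneticists who map recombination with modest marker
panels and spore counts and need the matching statistics: exact contingency
tests on small samples, Monte-Carlo chi-square for crossover distributions,
and a likelihood model that separates meiosis I nondisjunction from
meiosis II nondisjunction and background spore death.

## What it computes

**Genetic maps.** A crossover event is a switch of parental origin between
consecutive informative markers. For adjacent markers flanking interval
*i*, with `n_i` spores informative at both flanks and `r_i` of them
recombinant,

    cM_i = 100 · r_i / n_i          (uncorrected two-point distance)
    kb/cM_i = physical span / cM_i

Intervals are classified by the physical-to-genetic ratio: **hotspot**
< 15 kb/cM, **cold** > 75 kb/cM, **average** in between, **linked** when no
recombinant is seen. Maps are compared per interval by Fisher's exact
test, as a whole by chi-square, and in shape by a Monte-Carlo chi-square
over tables with fixed margins (Patefield sampling, default B = 2000,
p = (1 + #{X²_sim ≥ X²_obs})/(B + 1)).

**Tetrad viability.** The counts of tetrads with 4, 3, 2, 1, 0 viable
spores follow a three-parameter multinomial: MI nondisjunction with
probability *d* (all four spores aneuploid and inviable), MII
nondisjunction with probability *m* per division (that daughter's two
spores inviable), and independent background death *v* of euploid spores.
`nd_fit` maximises the multinomial likelihood and bootstraps confidence
intervals; the zero-viable class is attributed between a single MI event
and two independent MII events by the ratio d / ((1−d)·m²).

**Mutation effects.** A gene model (genomic sequence + exon intervals,
1-based coordinates from the A of the start codon) supports splicing,
translation, and application of substitutions, deletions, intron
retention, and cryptic-acceptor shifts, classifying each allele as
missense, nonsense, silent, frameshift, or splice disruption. A
deterministic synthetic reference gene with the documented structure of
the *C. cinereus nbs1* locus (3528 bp, 10 introns, 3000 bp CDS, 999 aa,
~110 kDa) is built in code for annotation of the five *nbs1* alleles.

**Simulator.** `meiosis_sim` draws crossovers on the four-chromatid
bivalent — either from a stationary gamma renewal process (shape ν ≥ 1
controls interference; ν = 1 is Poisson) or as per-interval Poisson counts
that emulate subtelomeric hotspots — assigns each crossover to one
chromatid of each homolog, segregates tetrads with MI/MII nondisjunction,
and emits genotype matrices of viable spores with configurable missing
calls. Study-shaped defaults live in `sporemap.study`.

## Worked example

Annotate the built-in alleles against the synthetic reference gene:

```
$ sporemap annotate
allele	kind	aa_position	ref_aa	alt_aa	truncated_length
nbs1-1-resplice	splice_disruption	400	G	*	399.0
nbs1-1-retained	splice_disruption	329	A	*	328.0
nbs1-2	missense	43	S	F
nbs1-3	nonsense	570	Q	*	569.0
nbs1-5	frameshift_truncation	289	L	*	288.0
```

`nbs1-2` changes serine 43 to phenylalanine; `nbs1-3` gains a stop at
residue 570; the `nbs1-1` splice-site allele truncates after residue 328
when intron 5 is retained and after 399 when splicing shifts to the
cryptic CAG acceptor 40 bp downstream.

Fit the nondisjunction model to a tetrad viability table (classes
4,3,2,1,0 viable):

```
$ sporemap tetrads --counts 62,11,12,4,17
total viability: 72.9%
$ sporemap ndfit --counts 62,11,12,4,17 --n-boot 200 --seed 1
{
  "v": 0.052, "d": 0.153, "m": 0.092,
  "zero_class_MI_vs_double_MII": 21.2, ...
}
```

The fitted MI nondisjunction rate is ~15% per meiosis, and a zero-viable
tetrad is ~21× more likely to come from one MI failure than from two
independent MII failures — the quantitative form of the argument that the
zero-viable class diagnoses MI nondisjunction.

Simulate a two-strain mapping study and compare the maps:

```
$ sporemap run --config examples/study.yaml
```

writes per-strain interval maps (interval, n_informative, n_recombinant,
cM, kb/cM, class), a comparison report (per-interval Fisher p, total map
lengths, Monte-Carlo distribution p), tetrad tables with the
nondisjunction fit, the allele-effect table, and a manifest that
reproduces the bundle byte-for-byte from its seed.

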