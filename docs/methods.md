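# Methods

## Crossover calling and two-point mapping

Genotypes are parental-origin calls (P1/P2/NA) of haploid spores over
physically ordered markers. A crossover event is any change of parental
origin between two consecutive **non-NA** calls, localised to the span
between those markers. Two consequences follow from this definition and
are deliberate:

* An event whose flanking informative markers are separated by an NA gap
  counts toward the spore's crossover total but toward **no** single
  interval's recombinant tally. Interval sample sizes are computed
  independently per interval from spores informative at both flanks, so
  per-interval `n` varies — the natural bookkeeping when individual PCRs
  fail.
* Two crossovers inside one inter-marker interval cancel and are
  invisible. Two-point cM (100·r/n) therefore under-counts long intervals;
  no mapping-function correction is applied to reported cM, matching
  standard adjacent-marker arithmetic. The simulator compensates in the
  opposite direction (below).

Interval classification: hotspot < 15 kb/cM, cold > 75 kb/cM, average
otherwise; values exactly on a boundary are "average" (the thresholds are
arguments of `classify_interval` for anyone who wants different cuts).
"Linked" (zero recombinants) is a class label, not infinite density;
linked intervals contribute 0 cM to map totals and intervals with no
informative spores are excluded from totals entirely.

## Statistics

* **Fisher exact (2×2)**: two-sided by probability ordering — the sum of
  hypergeometric probabilities of all tables with the observed margins no
  more probable than the observed table. This is the common convention and
  the one the exhaustive enumeration oracle in the test suite checks
  (all tables with N ≤ 40).
* **Exact 2×c test** (tetrad viability-class distributions): the same
  probability-ordering principle, by full enumeration of first-row
  compositions with the observed margins in log space. Enumeration beyond
  ~5·10⁶ tables falls back to the Monte-Carlo chi-square (B ≥ 10,000) with
  a warning.
* **Chi-square**: Pearson statistic, no continuity correction,
  df = (r−1)(c−1); zero margins are an error rather than a silent NaN.
* **Monte-Carlo chi-square**: simulated tables are drawn from the
  conditional distribution of tables given both margins under
  independence (Patefield's algorithm via `scipy.stats.random_table`) —
  the behaviour of R's `chisq.test(simulate.p.value=TRUE)`, which is the
  de-facto reference for this test. The estimator
  p = (1 + #{X²_sim ≥ X²_obs})/(B + 1) never returns zero. Note this
  conditional-null sampling is *not* uniform over tables; the uniform
  distribution would give a different (and non-standard) test.
* **Whole-chromosome comparison**: "the chromosome treated as one
  interval" is reconstructed as a 2×2 chi-square of (total crossover
  events, informative complement) per strain. The construction is flagged
  in the comparison report because other reconstructions are defensible.
* **Pooling gate**: two datasets may be pooled only if every per-interval
  Fisher p exceeds 0.1 and a homogeneity chi-square on the
  datasets × intervals recombinant-count table exceeds 0.05. With ~13
  intervals the all-intervals condition rejects a fair share of genuinely
  homogeneous pairs (13 tests at the 0.1 level); the gate is intentionally
  conservative — pooling heterogeneous mushrooms corrupts a map silently,
  refusing a homogeneous pair merely costs sample size.
* No multiple-testing correction is applied to per-interval p-values by
  default; reported values are raw, as is conventional for these maps.

## Tetrad-viability model

Class probabilities for (4,3,2,1,0) viable spores per tetrad:
with probability *d* the meiosis suffers MI nondisjunction (0 euploid
spores — two disomic, two nullisomic); otherwise each MII division fails
independently with probability *m*, costing that daughter's two spores;
euploid spores then die independently with probability *v*. All aneuploid
spores are inviable. The zero-viable class can arise three ways (MI,
double MII, or all four euploid spores dying); the attribution ratio
reported is P(MI)/P(double MII) = d/((1−d)m²), the "one rare event versus
two" comparison.

`nd_fit` maximises the multinomial log-likelihood by bounded L-BFGS-B from
four fixed starts (the likelihood surface is smooth and 3-parameter;
multistart guards the d↔m ridge at small counts). Percentile bootstrap
CIs resample tetrads (multinomial) and refit from the MLE. A flat-likelihood
screen perturbs the optimum and warns when distant parameters tie it,
which happens when classes 3/1 are empty and small. Fits require ≥ 20
tetrads. With 100 tetrads per strain — the scale of a real dissection
experiment — the CIs are wide (the MII rate is identified mostly by the
2-viable class) and should be read as such.

## Meiosis simulator

Crossovers are chiasmata on the four-chromatid bivalent; each involves one
chromatid of each homolog, chosen uniformly and independently per chiasma
(no chromatid interference). A spore therefore sees any chiasma with
probability ½, giving the factor-of-two chromatid dilution and the map
identity (total genetic length = 50·λ cM for λ expected chiasmata).

* **Renewal mode**: chiasma positions follow a stationary gamma renewal
  process with mean count λ and shape ν ≥ 1 (ν = 1 ⇒ Poisson, no
  interference; larger ν suppresses nearby double chiasmata). The first
  point is drawn exactly from the stationary delay distribution as
  U·Gamma(ν+1, θ) (uniform fraction of a size-biased spacing), so crossover
  density is uniform along the chromosome.
* **Interval-rates mode**: independent Poisson counts per inter-marker
  interval, positions uniform within the interval — used to emulate
  subtelomeric hotspots. This mode has **no interference**: simulated
  wild-type-like data show more multi-crossover spores than a strongly
  interfering real wild-type would, which is a stated limitation of the
  emulation, not of the analysis code.
* **Obligate crossover**: whole-bivalent rejection sampling of the zero
  class — exact, and unbiased for the positive classes, at the cost of
  resampling; with λ well below 1 most draws are rejected, so the option
  is meant for realistic λ ≈ 1–3.

Meiosis I groups chromatids into daughters by centromere origin; MI
nondisjunction sends both homologs to one pole (four aneuploid spores),
MII nondisjunction makes one daughter's two spores aneuploid. One
consequence worth knowing when analysing simulated tetrads: spores are
listed daughter-first, so *position in the tetrad is not a uniform random
chromatid* — selecting "the first spore" of each tetrad conditions on
crossover parity proximal to the centromere and biases spore-level
statistics. Tests that need independent spores draw one spore per meiosis
uniformly at random.

All randomness flows through a single `numpy` Generator seeded from
`SimConfig.seed`; a population, and the whole pipeline bundle, is a pure
function of (inputs, config, seed).

## Study-shaped defaults (`sporemap.study`)

The default design emulates the mapping study the package was built
around: two crosses of ~100 random spores (25 meioses × 4), 14 markers on
chromosome 3, 10 on chromosome 8, a few percent missing calls.

* Per-interval genetic lengths were solved once from the published
  per-interval kb/cM ratios plus the published totals (95.4 / 152.6 cM on
  chromosome 3; 52.7 / 58.7 cM on the chromosome 8 hotspot panel) under a
  single shared physical spacing; the resulting chromosome 3 spans
  ~4.26 Mb with subtelomeric hotspots at both ends. Physical spans with no
  genetic length on record (the linked H/I interval; chromosome 8's
  unmapped mid-section) are plausible cold-region values. None of this is
  asserted as biology — it gives simulated data the right statistical
  shape.
* Published interval cM are *observed two-point fractions*; a spore's
  crossover count in an interval is Poisson(rate/2), so the expected
  observed fraction is (1−e^(−rate))/2. Interval rates are therefore set
  to −ln(1−cM/50), making simulated maps reproduce the published cM in
  expectation rather than undershooting long intervals.
* Nondisjunction and death rates (wild-type-like: v=0.04, d=0.01, m=0.03;
  mutant-like: v=0.05, d=0.15, m=0.09) are the rounded maximum-likelihood
  fits of the viability model to the two published 100-tetrad tables.

What passing tests on simulated data do **not** show: the generator has no
gene conversion, no chromatid interference, no per-chromosome aneuploidy
bookkeeping across multiple simulated chromosomes (euploidy is drawn once
per tetrad), and hotspot emulation carries no interference. Conclusions
about real data should lean on the exact-test and calibration results,
which are data-free, and treat simulator-based power figures as
approximate.

## Synthetic reference gene

The annotation module needs a concrete gene record; the package builds one
deterministically (`sporemap.reference_gene`) instead of bundling a
sequence. The construction pins every documented structural fact of the
*nbs1* locus — 3528 bp, 10 introns (528 bp total), 3000 bp CDS, 999 aa,
~110 kDa — and arranges local context so that each characterised allele
reproduces its documented protein effect, including the GGCACT→GGTA-T
hexamer of the complex allele and the cryptic CAG acceptor exactly 40 bp
into exon 6. Unconstrained positions are filled from a fixed-seed RNG; a
repair pass removes accidental stop codons and spurious CAGs, and a
final pass nudges free codons so the product mass lands at ~110 kDa. The
record is a synthetic stand-in with the documented *structure*, not the
natural *sequence*; tests anchored on it validate coordinate conventions
and annotation logic, nothing about the real locus's other positions.

Numerical conventions in `gene_model`: coordinates are 1-based inclusive
with position 1 = A of ATG; translation uses the standard nuclear code and
stops at the first stop codon ("ATGTAA" → "M"); molecular weights use
average (not monoisotopic) residue masses plus one water, and an empty
protein is valid (one water) so immediate-stop products are representable.
Truncations report both the stop's residue position and the mutant length
(= position − 1), side-stepping the off-by-one ambiguity in prose like
"truncates after residue N" versus "a stop replaces residue N".

## Problem sizes

Defaults and test scales were chosen to keep everything on one CPU:
exhaustive Fisher oracle checks to N = 40; Monte-Carlo calibration with
500 null tables at B = 2000; simulator checks at 10,000 meioses;
nondisjunction recovery over five replicates of 10,000 tetrads with 1000
bootstrap refits each; the simulated study itself at the real experiment's
scale of 25 meioses per strain.
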