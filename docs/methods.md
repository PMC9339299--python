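# Methods

## Scope and data model

A tetrad is four spores from one meiosis; each spore carries a viability
flag, a mating phenotype (`a`, `alpha`, `non`, `nd`) and one allele per
heterozygous marker, encoded abstractly as `P`/`Q` (`-` = missing).  Dead
spores carry no genotype and no attempt is made to infer it.  The marker
map orders markers within chromosomes; adjacent pairs define the genetic
intervals.  The bundled reference map has five markers (four intervals)
on chromosome III — HIS4, CEN3, MAT, RAD18, HMR — and four markers (three
intervals) on chromosome VIII — SPO11, SPO13, THR1, LYS2.

## Classification rules

* A marker in a 4-spore-viable tetrad segregates `k:(4−k)` by its P/Q
  counts; `2:2` is Mendelian, anything else is a gene-conversion call, and
  any missing allele makes the marker `incomplete`.  `4:0`/`0:4` patterns
  are counted as conversions but logged as possible genotyping errors,
  since dissection data cannot distinguish the two.
* An interval is classified PD/TT/NPD from the four two-marker spore
  genotypes; a tetrad is excluded from an interval's tally iff it is not
  4-spore-viable or either flanking marker is non-2:2 or incomplete.
  Exclusion is per interval, which is why PD+TT+NPD totals differ between
  intervals of the same strain.
* Mapping uses tetrads with exactly 4 viable spores and at most 2 gene
  conversions (the conventional cutoff against aberrant meioses); both
  filters log their removal counts so any stricter convention can be
  audited.

## Estimators

**Perkins distance.** `cM = 100(TT/2 + 3·NPD)/N` with the multinomial
delta-method standard error `100·sqrt[(t(1−t)/4 + 9d(1−d) − 3td)/N]`
(equivalently `Var(w)/N` for the per-tetrad crossover score
`w ∈ {0, ½, 3}`).  The estimator corrects single and double crossovers
exactly and attenuates for triples and beyond.

**Expected NPD and interference.** Under a no-interference (Poisson)
chiasma model the expected NPD frequency at observed tetratype frequency
`f_T` is `½[1 − f_T − (1 − 3f_T/2)^(2/3)]`.  The power term is evaluated
as `cbrt(1 − 3f_T/2)²`: the real cube-root branch keeps the expectation
defined and positive for `f_T < 3/4`.  This matters in practice — strongly
interfering intervals can show `f_T > 2/3`, above the Poisson ceiling, and
the reference dataset contains such a row.  Interference is the ratio of
observed to expected NPDs, with `SE = ratio/sqrt(NPD_obs)` treating the
observed count as Poisson; `n.d.` is reported when `NPD_obs = 0` or the
expectation is not positive.  Near and above the `f_T = 2/3` ceiling the
inversion leaves the no-interference model's range and the ratio loses
its calibration (it may exceed 1 spuriously); ratios there should be read
qualitatively.

**Summaries.** Cumulative chromosome distances follow the presentation
convention of summing interval values rounded to 1 decimal (full-precision
sums are also available).  The gene-conversion rate ratio versus the
reference strain is computed from 2-decimal-rounded per-tetrad rates,
matching how such tables are conventionally printed.  All presentation
rounding (cM/SE to 1 decimal, ratios to 2, percentages to integers, NDJ%
to 2 decimals) happens only in the report layer; internal math is full
precision.

## Statistical tests

Two-proportion Z-tests use the pooled standard error (so `z²` equals the
uncorrected chi-square statistic); the per-strain gene-conversion table
applies it both to the fraction of tetrads with ≥1 conversion and to
conversions-per-tetrad treated as a proportion.  Fisher's exact test is
two-sided by hypergeometric probability-mass summation.  Student's
t-tests (one/two-sided, paired/unpaired) are provided for
replicate-level comparisons.  P-values are unadjusted by default, as is
standard for these small fixed families of planned contrasts; a flag
enables Benjamini–Hochberg adjustment for exploratory use.

The adjacency test for double-conversion tetrads uses the minimal chance
model: the two converted markers are a uniform draw from all C(M,2)
unordered pairs, adjacency meaning consecutive markers on the same
chromosome (with the 9-marker reference map, P(adjacent) = 7/36), tested
by an exact two-sided binomial test.  This matches the independence
assumption of the conversion model (below).

## Viability and nondisjunction

Spore viability is germinated spores over dissected spores; the
4/3/2/1/0-spore-viable class distribution is reported alongside.  MI
nondisjunction of the MAT-bearing chromosome is inferred from 2-spore
viable tetrads in which both survivors are nonmaters, with the
2-spore-viable class as denominator; `nd` mating calls are missing data
and drop the tetrad from the denominator (never counted as evidence).
Dissection data cannot separate MII nondisjunction from precocious sister
chromatid separation, and the inference makes no such claim — the
simulator generates the two event classes separately, but only their
viability signatures (2-spore-viable double nonmaters vs 3-spore-viable
enrichment) are observable.

## The forward simulator

Each chromosome is a line in genetic coordinates.  Chiasmata follow the
counting (chi-square) model: a stationary Poisson stream of rate
`2(m+1)` per Morgan in which every `(m+1)`-th event is a chiasma.  `m = 0`
gives independent (Poisson) chiasmata with mean 2 per Morgan per bivalent;
larger `m` regularises spacing, producing positive interference while
preserving the density (stationarity is enforced by starting the event
counter uniformly).  Each chiasma joins one chromatid of each local
origin, chosen uniformly — no chromatid interference, the assumption
under which P(TT | k chiasmata) = (2/3)(1 − (−1/2)^k) and on which both
the Perkins and expected-NPD formulas rest.  Segregation tracks
centromere origin through exchanges: MI separates homologous centromere
pairs (orientation randomised per chromosome, giving independent
assortment), MII separates sisters.

**Calibration.** Configured interval distances are *map* distances —
what the Perkins estimator measures.  Because Perkins attenuates triple
and higher crossovers, placing markers at the raw distance would make the
estimate converge below the configured value (about 1.6 cM low at 28.4 cM
under `m = 0`).  The simulator therefore inverts the closed-form Perkins
expectation — Poisson for `m = 0`, gamma-mixture tail sums for `m > 0` —
so that the estimate converges to the configured distance.  The
correction is a fraction of a cM for short or strongly interfering
intervals.

**Downstream events**, applied in a fixed, documented order so a seed
fully determines the output: (1) per-marker gene conversion with
probability `g` — a uniformly chosen spore's allele is overwritten,
giving 3:1 or 1:3 from 2:2 with equal probability; conversions are
independent across markers and meioses, matching the adjacency-test null;
(2) MI nondisjunction per chromosome — all four chromatids to one pole,
yielding two disomic viable spores (nonmaters when chromosome III is
involved, unless a centromere–MAT crossover homozygosed the disome) and
two dead nullisomic spores; (3) MII precocious sister separation — one
spore receives both sister chromatids and its MII sibling dies, typically
a 3-spore-viable tetrad; (4) independent random spore death.  Disomic
spores are scored at a marker only when their two chromatids agree;
heterozygous markers are left missing, as a real disome would be
unscorable.  The seed is mandatory and echoed into the output header.

**Defaults** emulate the wild-type reference conditions: the 9-marker map
with its published interval distances (28.4, 19.3, 35.0, 20.8 cM on III;
41.6, 10.6, 32.4 cM on VIII), `g = 0.015` per marker (9 markers × 0.015 =
0.135 expected conversions per tetrad, the wild-type rate), per-spore
death 0.04 (96% spore viability), no missegregation, and `m = 4` — a
counting-model strength in the range fitted for budding yeast that
reproduces wild-type-like NPD ratios (0.03–0.2 across the seven
intervals).  Missegregation rates have no empirical calibration in the
reference data and default to zero; they are set explicitly when
studying viability signatures.  The chromosome VIII centromere is not a
scored marker and is placed midway through the SPO11–SPO13 interval; its
position affects only segregation mechanics, not interval classes.

**What the simulator does not model**: double-strand-break mechanics,
conversion-associated crossovers, conversion tract lengths (conversions
hit single markers independently), chromatid interference, and aneuploidy
beyond single-chromosome MI/MII missegregation.  Passing round-trip tests
therefore validates the estimators under the standard model assumptions;
they do not certify behaviour on real data that violates them (e.g.
tract-driven co-conversion of adjacent markers).

## Numerical and design choices

* Allele relabeling `P↔Q` at one marker swaps PD and NPD and fixes TT;
  estimators depend on counts only (verified by property tests).
* Chiasma/marker position ties have measure zero (continuous positions);
  comparisons are strict.
* `reproduce` diffs recomputed values against the published tables at
  printed precision.  Two published SE cells, two ratio cells and three
  ratio-SE cells differ from the recomputation by roughly one unit in the
  last printed digit — the study's external tool did not publish its
  exact formulas — and are held to bands of ±0.08 cM, ±0.0075 and ±0.035
  respectively; all other cells must match the printed digit exactly.
* Test problem sizes (5 000 meioses for distance recovery, 3–4 000 for
  missegregation and interference checks, 10⁵ draws for resampling
  oracles) keep every stochastic assertion at ≥3 estimated standard
  errors from its threshold while the full suite runs in seconds.

## Known limitations

Mapping assumes two alleles per marker and no more than the standard
tetrad classes; aneuploid genotypes are handled only through the
mating-phenotype logic.  The interference ratio degenerates near
`f_T ≥ 2/3` (see above).  Gene-conversion tract structure is out of
scope, so per-locus conversion frequencies are reported but co-conversion
of adjacent markers is only tested against the uniform-pair null.
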