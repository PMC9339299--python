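# tetrads

Tetrad analysis for budding-yeast meiosis: segregation scoring, genetic
linkage mapping, crossover interference, gene-conversion and
spore-viability statistics — plus a forward meiosis simulator that
generates synthetic tetrad tables with configurable crossover rates,
chiasma interference, gene conversion, missegregation and spore death.

## Who this is for

In *Saccharomyces cerevisiae*, one meiosis yields four haploid spores that
can be dissected, germinated and genotyped together (a *tetrad*).  For a
pair of heterozygous markers, each tetrad falls into one of three classes
— parental ditype (PD), tetratype (TT) or nonparental ditype (NPD) — and
the class frequencies encode genetic distance and crossover interference.
This package implements the complete computation a dissection study needs:
from raw per-spore genotype tables to the map-distance, viability and
gene-conversion report tables, with every estimator validated against
closed-form oracles and by parameter recovery from the simulator.

## The core statistics

For an interval scored in `N = PD + TT + NPD` tetrads:

* **Perkins map distance**
  `cM = 100 (TT/2 + 3 NPD) / N`,
  with a multinomial delta-method standard error
  `SE = 100 sqrt[(t(1−t)/4 + 9d(1−d) − 3td)/N]`, `t = TT/N`, `d = NPD/N`.
* **Expected NPD (no interference)**
  `E[NPD] = N · ½[1 − f_T − (1 − 3 f_T/2)^(2/3)]`, `f_T = TT/N`,
  evaluated on the real cube-root branch so it stays defined for the
  tetratype excesses (`f_T > 2/3`) that strong interference produces.
* **Crossover interference** is reported as `NPD_obs / NPD_exp`
  (below 1 = positive interference), with Poisson error
  `SE = ratio / sqrt(NPD_obs)`, and `n.d.` when `NPD_obs = 0`.
* **Gene conversion**: any non-2:2 marker segregation in a 4-spore-viable
  tetrad; strains are compared by two-proportion Z-tests and Fisher's
  exact test.
* **MI nondisjunction**: 2-spore-viable tetrads whose two survivors are
  both nonmaters (disomic for the *MAT*-bearing chromosome III).

The simulator places markers on a chiasma renewal line and implements the
counting (chi-square) model of interference: every (m+1)-th event of a
Poisson stream matures into a chiasma, strand choice is uniform over
non-sister chromatids, and `m = 0` recovers the no-interference Poisson
process.  See `docs/methods.md` for the model details and calibration.

## Worked example

Map distance and interference for an interval with `PD=230, TT=251, NPD=4`:

```python
from tetrads import IntervalCounts, perkins_distance, interference_ratio

c = IntervalCounts(("HIS4", "CEN3"), pd=230, tt=251, npd=4)
cm, se = perkins_distance(c)
ratio, ratio_se = interference_ratio(c)
print(f"cM = {cm:.1f} +/- {se:.1f}; NPDobs/NPDexp = {ratio:.2f} +/- {ratio_se:.2f}")
```

prints

```
cM = 28.4 +/- 1.6; NPDobs/NPDexp = 0.14 +/- 0.07
```

i.e. a 28.4 cM interval in which only 14% of the nonparental ditypes
expected without interference were observed — strong positive crossover
interference.

From the shell, a full simulate → analyze round trip:

```
tetrads simulate --seed 9 -n 300 -o sim.tsv --strain wt --mi-ndj 0.02
tetrads analyze sim.tsv -d reports/
tetrads reproduce -d reproduced/      # rebuild the bundled reference tables
```

`analyze` writes three tab-separated reports (viability classes and NDJ,
map distances with interference, gene-conversion statistics) plus
full-precision JSON versions.  `reproduce` recomputes every derived value
of the bundled reference dataset — a published H2A.Z/H1 histone study
scoring 9 markers on chromosomes III and VIII in four strains — and exits
nonzero if anything fails to match; its map report starts:

```
strain     interval   cm    se_cm  pct_wt  cm_chrom  pct_wt_chrom
wild_type  HIS4-CEN3  28.4  1.6    100     103.5     100
wild_type  CEN3-MAT   19.3  1.6    100     103.5     100
```

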