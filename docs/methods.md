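# Methods

## The quantities computed

The package works entirely at the level of detected IBD segments; it never
touches genotypes except for the optional merge consistency check. The
chain of quantities is:

1. **Per-pair sharing** ibd(i, j): the summed cM length (and block count)
   of segments shared between individuals i and j, after gap merging and
   length binning.
2. **Group means** L(X) and L(X,Y): averages of per-pair sharing over all
   within-group and between-group individual pairs. L is additive over
   chromosomes, which later makes the jackknife exact. Within-group L is
   undefined (reported missing, never zero) for groups of fewer than two
   individuals. HBD blocks — the two haplotypes of one individual sharing a
   segment, i.e. runs of homozygosity — are excluded from L(X) by default
   because the pair sum runs over distinct individuals; an `include_hbd`
   flag adds each individual's within-individual haplotype pair as one
   extra pair for sensitivity analysis.
3. **Similarity** S(X,Y) = 2 L(X,Y) / (L(X) + L(Y)). S is 0 with no
   between-group sharing, 1 when sharing is independent of structure, can
   exceed 1 when between-group sharing exceeds the within average, and is
   missing (not 0) when L(X) + L(Y) = 0. S(X,X) is defined as 1 by
   convention and excluded from all averages.
4. **Relative similarity** R = (S_within − S_all) / (1 − S_all), where
   S_within averages S over unordered focal-set pairs and S_all over all
   unordered universe pairs (focal pairs included). Missing S values drop
   out of both means. S_all ≥ 1 makes the denominator non-positive and is
   treated as an error rather than silently clamped.

## Uncertainty and significance

**Jackknife.** The SE of R is a delete-one-chromosome jackknife:
each replicate recomputes the full L → S → R chain from the per-pair,
per-chromosome sums with one chromosome removed, and
SE = sqrt((C−1)/C · Σ_c (R₍c₎ − R̄)²). Because L is additive over
chromosomes the replicates are exact recomputations, not approximations.
Chromosomes are equally weighted; a length-weighted variant was considered
and rejected as the default because the statistic is a ratio in which
per-chromosome information content is not proportional to map length.
Plots show ±3 SE bands.

**Permutation test.** The difference ΔR = R_kula − R_non_kula is compared
with its distribution under random reassignment of the kula / non-kula
labels across the Massim groups only (class sizes preserved; groups outside
the Massim never change labels). The S matrix does not depend on the
labels, so each replicate only re-averages the same matrix — making the
test cheap and exactly consistent with the observed statistic. The p-value
uses the add-one estimator p = (1 + #{ΔR_perm ≥ ΔR_obs}) / (1 + n_perm) and
is one-sided, because the hypothesis of interest is directional (more
sharing among the trading partners). With g focal-eligible groups only
C(g, k) distinct labelings exist, so attainable p-values are discrete; the
test is valid but mildly conservative for small g.

## Segment handling rules

- **Gap merge:** two consecutive blocks of the same haplotype pair on one
  chromosome merge when the genetic gap is strictly < 0.6 cM ("within a
  0.6 cM gap": 0.599 merges, 0.600 does not). Merging is transitive
  left-to-right; merged LOD is the max of the parts. With a phased VCF
  supplied, a merge additionally requires ≤ 1 site (configurable) at which
  the two haplotypes carry different alleles across the union of both
  blocks and the gap; the window includes the full blocks, since the
  alternative (flanking margins only) is under-specified and the stricter
  check is conservative. Positional-only merging is the default mode.
- **Length bins:** half-open [e_i, e_{i+1}), last bin open-ended; segments
  below the first edge are dropped and counted in the log. Defaults: 1/5/10
  cM for networks and time slices, ≥ 2 cM for within-group demography. The
  finer seven-bin series used for the R-vs-length analysis (edges
  1,2,3,4,5,6,10 cM) carries approximate-kya annotations (~2.7 … ~0.2 kya)
  as pure metadata; the edges are configuration defaults, not a published
  table, and the annotations are never computed from.
- **Coordinates:** physical positions are 1-based inclusive; genetic
  positions come from piecewise-linear interpolation of a PLINK- or
  HapMap-style map, clamped at the anchor range. The printed cM length of a
  segment row is authoritative for statistics; map-derived endpoints are
  anchored at the interpolated start and rescaled to the printed length
  (a deviation > 0.1 cM is logged). Subsegment lengths inherit the same
  rescaling so that partitioning conserves length within the parent.
- **Ancestry partition:** an IBD segment contributes to ancestry A exactly
  on the maximal sub-intervals where *both* involved haplotypes carry a
  confident label A. Tracts with posterior < 0.95 (the usual RFMix
  forward–backward confidence cutoff) are masked UNKNOWN at load time;
  UNKNOWN or disagreeing stretches and subsegments shorter than 1 cM
  (configurable) are discarded. Ancestry-specific networks re-bin
  subsegments by their *own* cM length — the subsegment, not the parent, is
  what was co-inherited on that background.

## The synthetic generator

The generator emulates the statistical structure the sharing statistics
assume, not sequence evolution. Per individual pair and per length era, the
number of shared blocks is Poisson; block lengths are 1 cM + Exp(mean) —
the floor matches the smallest analysis bin edge — placed uniformly on
chromosomes chosen in proportion to genetic length (22 human-like autosomes,
~3.3k cM, linear 1 cM/Mb maps). Rates multiply up from a per-era baseline:
within-group pairs get the era's within rate; cross-group pairs in the same
region get a region multiplier (default 3); pairs of two Kula-practicing
groups get `kula_boost`. HBD blocks arise per individual at a per-group
rate (elevated for a drifted-isolate group). Local-ancestry tracts are
two-state Markov mosaics per haplotype with the group's stationary AN
fraction and a per-cM switch rate; a small fraction of tracts receives a
posterior below the 0.95 cutoff.

The default study design (`default_scenario`) has 12 groups of 5: five
Kula and three non-Kula Massim groups (one isolate with high HBD), plus
Bismarck, Solomon and Highland outside groups, with three eras (mean
exponential lengths 1.8 / 6 / 12 cM at within-group rates 12 / 3 / 1 and
between-group baselines 1.2 / 0.25 / 0.06 blocks per pair). These values
were chosen once to give realistic magnitudes — within-group sharing an
order of magnitude above between-group sharing, S between Massim groups a
few tenths, several thousand segments per dataset — and are not tuned.

What the generator does **not** emulate: coalescent correlations between
pairs (each pair is independent), detection error and length-dependent
power of IBD callers, phase switch errors, realistic recombination maps, or
overlap structure among segments of one haplotype. Passing tests therefore
validate the statistics, their calibration and the pipeline plumbing under
the model's own assumptions — not the behaviour of any IBD caller on real
data.

For planting ancestry-restricted gene flow, a deterministic mode labels the
first fraction of every chromosome AN and the rest PAP on all haplotypes
(`ancestry_split`) and places cross-region segments in the AN zone and
within-region segments in the PAP zone (`between_region_on_an`); the
expected signature — ancestry-specific networks whose PAP edges never cross
regions — is asserted in the acceptance suite.

## Calibration results computed by the test suite

The suite (tests/test_acceptance.py) verifies, among others: exact
agreement (1e-12 relative) of L/N/S with brute-force pair enumeration on
100 random small panels; agreement of the ancestry partition with a
per-0.01 cM grid oracle; that the delete-one-chromosome SE falls within a
factor of three of the empirical SD of R across 200 regenerated datasets
(observed ratio ≈ 0.9); that the null rejection rate of the permutation
test over 200 exchangeable datasets lies in [0.01, 0.10] (observed ≈ 0.03,
mildly conservative as expected from label discreteness); and ≥ 80% power
against a two-fold planted Kula excess over 100 datasets at five
individuals per group.

## Problem sizes and determinism

Default scenarios produce ~8,000 segments across 22 chromosomes and run the
full model fit in under a second, so calibration loops over hundreds of
regenerated datasets complete in minutes on one CPU. All randomness flows
from explicit seeds (`numpy.random.default_rng`); regenerating a scenario
with the same seed is byte-identical, and `run_all` writes a manifest with
input checksums, parameters and the seed.

## Known limitations

- The permutation test requires at least two groups per label class and
  loses resolution below ~6 focal-eligible groups.
- Groups without coordinates are silently excluded from the
  similarity-vs-distance table only; all other statistics include them.
- The genotype-consistency merge check loads the whole VCF into memory; it
  targets the array-scale data this method is used with, not WGS-scale
  files.
- Time annotations attached to length bins are literature conventions for
  interpreting segment ages, not quantities this package estimates.
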