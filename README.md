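# ibdshare

Group-level statistics for identity-by-descent (IBD) segment sharing, built
for asking whether a culturally defined set of populations — such as the
Kula-ring trading partners of the Massim region of Papua New Guinea —
exchanged more migrants with each other than the regional background would
predict.

## Who this is for

Population geneticists who already have detected IBD/HBD segments (e.g.
refinedIBD output), per-haplotype local-ancestry tracts (e.g. RFMix output),
and a sample panel assigning individuals to groups, and who want to go from
those tables to:

- per-group-pair sharing matrices and noise-filtered sharing networks,
- ancestry-specific versions of those networks (e.g. Austronesian- vs.
  Papuan-background sharing),
- a similarity statistic with jackknife errors and a permutation test for
  excess sharing within a focal set of groups.

A segment-level simulator with plantable group structure is included, so the
whole pipeline is testable without access to controlled genotype data.

## The statistics

For a group *X* with *n* individuals, the mean per-pair summed IBD length is

    L(X) = 2 / (n(n-1)) * Σ_{i<j} ibd(X_i, X_j)

and between groups *X*, *Y* of sizes *n*, *m*

    L(X,Y) = 1 / (nm) * Σ_i Σ_j ibd(X_i, Y_j)

where ibd(·,·) is the summed length (cM) of segments shared by a pair (the
block-count analogue N is defined the same way). The F<sub>ST</sub>-motivated
similarity statistic is

    S(X,Y) = 2 L(X,Y) / (L(X) + L(Y))

which is 0 with no between-group sharing and 1 when sharing is independent
of group structure. For a focal set of groups inside a larger analysis
universe, the relative similarity statistic is

    R = (S_within − S_all) / (1 − S_all)

with S_within the mean pairwise S inside the focal set and S_all the mean
over all universe pairs; R = 0 when focal sharing matches the background.
Standard errors come from a delete-one-chromosome jackknife (exact, because
L is additive over chromosomes), and the significance of
ΔR = R_focal − R_other is assessed by permuting the focal/other labels
across eligible groups while preserving class sizes.

Segments are analysed in cM length bins (1–5, 5–10, >10 cM by default)
because segment length indexes the age of the shared ancestor; network
edges are kept when the mean block count per pair is ≥ 0.5. HBD
(homozygosity-by-descent) blocks are read alongside IBD, and blocks
separated by a gap < 0.6 cM are merged first, optionally requiring no more
than one inconsistent phased genotype across the blocks and gap.

## Worked example

```python
import ibdshare as ib

# a Massim-like synthetic study: 8 Massim groups (5 Kula, 3 non-Kula,
# one drifted isolate) + 4 outside groups, with a planted two-fold
# sharing excess between Kula-practicing groups
scenario = ib.default_scenario(kula_boost=2.0, seed=42)
ds = ib.simulate(scenario, with_tracts=False)

segments = ib.merge_segments(ds.ibd + ds.hbd)          # 0.6 cM gap rule
model = ib.KulaSharingModel(segments, ds.panel, bins=ib.NETWORK_BINS)
res = model.fit(n_perm=999, seed=43)
print(res.summary())
```

```
Relative IBD similarity: Kula vs. non-Kula groups
================================================================
Groups: 12 total, 5 Kula, 3 non-Kula (universe: 12 groups)
Segments: 7677   permutations: 999   seed: 43
----------------------------------------------------------------
       bin   R_kula    (se)   R_nonK    (se)      dR       p
     1-5cM    0.466   0.037    0.128   0.028   0.338  0.0100
    5-10cM    0.355   0.052    0.194   0.087   0.160  0.1230
     >10cM    0.351   0.085   -0.053   0.040   0.403  0.0240
----------------------------------------------------------------
SE: delete-one-chromosome jackknife; p: one-sided label permutation
```

Read it as: in every length bin the Kula groups are more similar to each
other, relative to the all-group background, than the non-Kula groups are
(R_kula > R_non_kula); the planted two-fold excess is detected at p ≈ 0.01
in the best-populated 1–5 cM bin. `res.plot()` draws the per-bin R values
with ±3 SE bars, and `res.table` / `res.to_tsv(path)` expose the numbers.

The same analysis runs from files (refinedIBD-dialect segment tables, a
panel TSV, a PLINK/HapMap genetic map) via
`ib.KulaSharingModel.from_files(...)`, or end to end from a YAML config:

```sh
ibdshare simulate --seed 42 --kula-boost 2 --out data/
ibdshare run-all --config config.yaml --out results/
```

Stage-level subcommands (`merge`, `bin`, `share`, `network`, `kula`,
`ancestry-ibd`) expose each step separately.

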