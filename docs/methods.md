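# Methods

This note documents the models, numerical choices and defaults behind
`neurocnv`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Study design being emulated

The package targets a cohort design common in molecular subtyping
studies of sporadic ALS motor cortex: ~10 unaffected controls and ~30
cases split into two transcriptome-defined subgroups (defaults 17 and
13), profiled on a custom exon-centric aCGH panel covering a curated
disease-gene list (default 154 genes × 4 exons × 5 probes = 3080
probes) together with a matched expression array. The subgroup sizes
are back-derived from printed carrier frequencies (76.47% = 13/17,
76.92% = 10/13); they are configuration, not hard-coded facts.

## Aberration calling

Per sample, in fixed order:

1. **GC correction.** Probes are binned into 20 equal-width bins over
   the observed GC fraction (probe GC computed over a ~2 kb window in
   real designs); each probe's log2 ratio is reduced by its bin median.
   This removes a monotone GC trend and recentres the profile. It is a
   non-parametric detrend: it cannot create aberrations, and with no GC
   trend it reduces to a median shift plus per-bin estimation noise of
   order σ/√(bin size).
2. **Centralization.** The diploid peak is the mode of a Gaussian KDE
   (Scott's bandwidth, 2048-point grid); the subtracted shift is the
   median of values within ±0.1 of that mode, so the local median is
   exactly zero afterwards. Using the density mode rather than the mean
   keeps large aberrations (e.g. a 30% duplicated fraction) from
   dragging the baseline. At least 30 probes are required; a constant
   profile is shifted to zero directly.
3. **Noise (DLRS).** σ = IQR(first differences within chromosomes) /
   1.349 / √2. The IQR makes the estimate robust to the (rare) large
   steps at CNV edges; the √2 accounts for differencing two independent
   probes. A zero σ marks a degenerate profile and calling refuses to
   proceed rather than divide by zero.
4. **Interval scan.** Per chromosome, the maximal-score contiguous probe
   interval under score(I) = √|I| · |mean(log2)| / σ is found (all O(n²)
   intervals, vectorized over prefix sums, ties to the smallest start
   then end), accepted if score ≥ 6.0 (inclusive), its probes masked,
   and the remaining runs rescanned until nothing reaches threshold.
   Accepted intervals are therefore disjoint, and the first accepted
   interval equals the brute-force maximum — asserted per iteration
   against an independent exhaustive scorer in tests. The score is
   signed by the interval mean: positive = amplification, negative =
   deletion. Probe-quality weights used by the commercial implementation
   are proprietary and not reproduced; a 2 Mb moving-average smoothing
   exists as an off-by-default reporting option.
5. **Aberration filter.** Calls require |mean log2| ≥ 0.5 **and** ≥ 3
   consecutive probes, both inclusive ("a minimum of"). Direction is
   gain for positive mean, loss otherwise. Coordinates are 0-based
   half-open internally (probe extents) and 1-based inclusive in SEG /
   recurrence-table output; BED output keeps BED conventions.

## Recurrence ("penetrance") analysis

All case-call start/end coordinates on a chromosome partition its
covered span into atomic fragments, so every call is an exact union of
consecutive fragments. A sample carries a fragment-gain only if one of
its gain calls covers the fragment (direction-matched semantics; the
alternative — identical breakpoints — would be far stricter and is not
what penetrance percentages describe). Frequencies are
100·carriers/group size, rounded half-up to two decimals, matching the
precision recurrence tables are printed at. Fragments at ≥ 10%
(inclusive) of the chosen scope (all cases, subgroup 1 or subgroup 2)
are selected, and adjacent selected fragments with identical carrier
sets and direction are merged back into maximal regions. Gains and
losses are separate events even on coincident spans. Case-exclusive
filtering removes any region overlapped ≥ 1 bp by a same-direction
control call; an any-direction mode is available behind a flag.

Accounting identity (tested per-base on random call sets): the sum of
fragment length × carrier count equals the per-sample covered length.

## Gene annotation

The array design is the closed world. Gene spans are the min–max probe
extents per gene; a region's gene list is every panel gene it overlaps
by ≥ 1 bp, position-sorted. Regions hitting no gene are retained and
flagged intergenic. Gene-level (not exon-level) overlap is used for
reporting because recurrence tables print gene symbols; the exon
structure remains available in the panel. Disease clustering groups
recurrent CNV genes by panel tags (e.g. "ALS"), keeping gain and loss
rows separate.

## Differential expression

Raw intensities are thresholded to 1, log2-transformed, scaled per
sample to its 50th percentile and baselined per probe to the median
across samples — the classic single-channel recipe. Probes are
collapsed to genes by maximal variance across samples (ties to the
lexicographically smallest probe id); unmapped probes are dropped.

Per gene: one-way ANOVA across control/subgroup1/subgroup2, BH
adjustment across genes, and Tukey HSD pairwise p for each subgroup vs
control, using the Tukey–Kramer standard error for unequal group sizes.
The studentized-range upper tail is evaluated through a cached 601-point
log-interpolation of the exact distribution (error ~1e-5; pinned
against `scipy.stats.tukey_hsd` in tests) because per-gene exact calls
are three orders of magnitude slower and dominate the randomized-group
control. A gene is significant in a subgroup when adjusted ANOVA p <
0.05, Tukey p < 0.05 and |FC| ≥ 1.5 (inclusive; a raw-p mode is a
config flag — the published criterion is ambiguous about where the
adjustment sits, and the implemented reading is the strictest consistent
one). Fold change is signed: FC = 2^Δ for Δ ≥ 0 and −2^(−Δ) otherwise,
so |FC| ≥ 1 by construction and the sign is the direction. Zero
within-group-variance genes get p = 1 when group means coincide and a
floor p otherwise.

## Integration and the randomized-group control

Recurrent CNV genes and significant DEGs are joined by gene symbol
within each subgroup ("the same named gene"; a coordinate-overlap mode
exists behind a flag). Statuses are mutually exclusive and exhaustive
over genes with at least one signal: CNV-driven (gain∧up or loss∧down),
discordant, CNV-only, expression-only. A gene with both a recurrent
gain and a recurrent loss in one subgroup keeps the higher-frequency
event (ties to gain). The headline percentage divides CNV-driven genes
by the CNV∩DEG overlap — the denominator that reproduces the published
arithmetic (35 of 70 → 50%) — with half-up integer rounding for the
headline and two decimals internally. An empty overlap reports
not-applicable, never 0%.

The randomized-group control re-partitions the case samples into two
pseudo-subgroups of the original sizes (bipartitions sampled with
replacement), reruns penetrance → selection → control filter →
annotation → DEG → join per split, and records the overlap size.
Fragmentation is label-independent and computed once. The empirical p
uses the add-one permutation estimator (1 + #{null ≥ observed}) /
(n_splits + 1), which cannot return zero.

## Downstream statistics

*Enrichment.* Upper-tail hypergeometric p = P[X ≥ k] with X ~
HG(N, K, n) via the exact distribution, gene sets intersected with the
universe first (universe defaults to the panel), BH across terms. An
enumeration oracle over all C(N, n) draws backs the tests.

*Network.* Edges below confidence 0.8 are dropped, self-loops removed
with a warning, duplicates collapsed; hubs are nodes with degree ≥ 10
(inclusive) on the filtered simple graph; edge betweenness is computed
over unweighted shortest paths. Seed-list expansion adds at most 100
first-shell neighbours, ranked by seed connections, then degree, then
name — emulating the "max interactions" cap of interaction databases.
Both filtered- and full-neighbourhood degree modes are reachable by
setting the confidence cutoff.

*qPCR.* Replicate Cts are arithmetic means; ΔCt = Ct(target) −
Ct(reference), ΔΔCt subtracts the calibrator sample, ratio = 2^−ΔΔCt.
Classes: gain ≥ 1.4, loss ≤ 0.6, diploid ∈ [0.8, 1.2]. The published
cut-offs leave (0.6, 0.8) and (1.2, 1.4) undefined; an explicit
`indeterminate` class covers those gaps rather than silently widening
bins, keeping classification monotone and exhaustive.

## Synthetic cohorts and what the tests show

The generator plants recurrent subgroup-specific gains/losses at chosen
carrier frequencies (carriers drawn without replacement with a
dedicated RNG stream per planted region, so extending a plan never
perturbs earlier regions), adds i.i.d. Gaussian probe noise (default
σ = 0.15 log2 units, a realistic DLRS for good arrays), and produces a
matched expression matrix in which a configurable fraction (default
0.5, deterministic rounding of fraction × gene count) of CNV genes
respond in the copy-number direction in carrier samples only, plus a
set of CNV-independent subgroup DEGs. Effect defaults: +0.58 for a
single-copy gain on diploid, −1.0 for a heterozygous deletion.

Two power considerations shaped the default planting plan:

- The carrier-only expression shift is diluted to frequency × shift at
  the subgroup-mean level, so the planted shift (default 1.5 log2)
  must exceed log2(1.5)/min frequency for the FC gate to be reachable;
  default carrier frequencies are recurrence-table-like (12–15 of 17,
  8–10 of 13).
- A +0.58 gain needs ≈30+ probes for its called mean to clear the 0.5
  filter with per-carrier failure ≲10⁻³ at σ = 0.15 (the filter sits
  0.08 below the planted shift, and the called-mean standard error is
  σ/√n), whereas a −1.0 deletion clears it from a handful of probes.
  Gains therefore default to two-gene spans (~40 probes) and losses to
  single/multi-exon events (5–15 probes) — also the biologically
  sensible regime, duplications running larger than deletions.

The simulator does **not** model dye bias, scanner artifacts, probe-
quality variation, replicate arrays, GC structure along the genome
(GC bias is an optional linear term, off by default), linkage between
neighbouring CNVs, or expression covariance structure. Recovery results
on synthetic cohorts therefore demonstrate correctness of the
bookkeeping and the statistical machinery under the stated noise model,
not performance on real arrays.

Problem sizes used by the test suite and the acceptance script: a
3080-probe/40-sample cohort with 20 planted regions for recovery; 200-
probe profiles (×100) for the brute-force scan oracle; a 1000-gene null
for FDR calibration; 99 splits for the randomized-group control. These
sizes make every check sharp while keeping a full run in the minutes
range on one CPU.

## Known limitations

- The interval scan is greedy (top interval, then flanks); equivalence
  with the exhaustive oracle is guaranteed per iteration, not for the
  joint multi-interval segmentation.
- The centralization "threshold 6.0 / bin size 10" of the commercial
  algorithm is not publicly specified; the KDE-mode implementation is a
  documented, testable stand-in for the same intent (dominant copy
  state at zero).
- Symbol-level integration inherits any symbol mismatch between panel
  and expression annotation; the coordinate mode avoids this at the
  cost of resolution.
- The 45% headline for the second subgroup in the motivating study does
  not follow from nearest-integer rounding of any obvious denominator;
  the package reports both the exact two-decimal and the rounded value.
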