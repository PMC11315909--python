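# Methods

## Coordinate frame and binning

All internal coordinates are 0-based half-open; GTF input (1-based
inclusive) and bedGraph/BED (already half-open) are converted at I/O.  The
"centromeric end" of a chromosome is coordinate 0: mouse chromosomes are
telocentric, and the mm10 assembly begins each chromosome with a ~3 Mb
unassembled centromeric gap — which is why the pericentromeric boundary
window starts at 3 Mb rather than 0.  Binning tiles each chromosome from 0
at a fixed width (15 kb genome-wide scans, 10 kb boundary work); trailing
partial bins are kept and flagged but excluded from boundary statistics and
random-bin sampling, mirroring common windowing tools while keeping counts
unambiguous.

The boundary window is [3.0, 3.5) Mb on chr1–chr19 + chrX.  chrY is
excluded by default (20 chromosomes × 50 ten-kb bins = 1000 bins, matching
the published bin count for this analysis); the chromosome set is
overridable.  Whether chrY belonged to the original "all chromosomes" set
is not documented anywhere we know of — the 20-chromosome reading is
inferred from the printed 1000 and is flagged here rather than hidden.

## Signal model

A track is a sparse piecewise-constant function (sorted non-overlapping
segments; uncovered positions are 0).  The processing chain is the standard
deepTools-style one: raw per-bin counts → CPM (v·10⁶/total mapped reads) →
per-base subtraction of the matched CPM input on the overlay refinement of
the two segmentations.  Negative values are kept (signal below input).  No
pseudocounts are added anywhere.

Interval means default to **base-weighted** (per-base average, uncovered
bases contribute 0).  Because `bedtools map -o mean` instead averages the
*segments* overlapping an interval and returns a missing sentinel when none
do, an `overlap_unweighted` compatibility mode is provided; for
full-genome fixed-bin tracks aligned with the query bins the two modes
coincide, which is why base-weighted is the default.  Missing values are
dropped downstream with logged counts (pairwise for the signed-rank test,
listwise per group otherwise).

## Repeat aggregation

The analysis unit for repeat statistics is the repeat *instance*: each
group's distribution holds one per-repeat mean per instance (so group n's
are instance counts), and the heatmap cell for (group, sample) is the mean
of those per-repeat means — not a pooled base-weighted mean over the
group's concatenated bases.  Replicates are averaged after per-repeat
quantification, not pooled at the track level.  Blacklist filtering removes
a repeat on any ≥ 1 bp overlap (the most conservative reading of
"overlap"); a minimum-overlap option exists.  Heatmap ordering uses
agglomerative clustering with euclidean distance and complete linkage on
the raw group means (no z-scaling by default; an option exists).

## Permutation test of the median difference

The regional-enrichment statistic is median(boundary bins) − median(random
background bins).  The default null shuffles group labels over the pooled
values with group sizes fixed, N = 10,000 rounds, and reports
p = (1 + #{null as extreme as observed}) / (N + 1), so p is never exactly
0 and its floor is 1/(N+1).  When the number of distinct labelings
C(n, n_a) ≤ 10,000 the test enumerates all of them and reports the exact
tail fraction.  An alternative null that redraws the background bin set
each round (`permutation_background_resample_test`) is provided, since a
published legend rarely pins down which construction was used; label
shuffling is the default because it is the standard two-group
median-difference null.  The one-sided "greater" alternative is the
default for enrichment hypotheses; genome-wide contrasts use two-sided.

The sampled path draws each relabelling with a partial Fisher–Yates pass
(only min(n_a, n_b) swap steps per round, vectorised across rounds), which
is an exact uniform draw over labelings, not an approximation.

## Rank tests

Wilcoxon signed-rank (paired bins across conditions; zero differences
dropped with a logged count) uses an exact sign-flip null for n ≤ 25,
computed by dynamic programming over doubled midranks so tied |differences|
are handled exactly; larger samples use the tie-corrected normal
approximation.  Mann–Whitney U uses the exact split distribution for small
samples without ties and the tie-corrected asymptotic otherwise.  Both are
two-sided.

## Gain/loss bin calling

Per-bin delta = knockdown − control.  The `robust_z` rule standardises by
the raw median absolute deviation, z = (δ − median δ)/MAD δ, and calls
gain when z > k and loss when z < −k with k = 3; it is shift-invariant and
scale-free.  The MAD here is unscaled (no 1.4826 normal-consistency
factor); k is interpreted in MAD units.  A fixed-threshold `abs_delta`
rule is available, and is the automatic fallback when MAD = 0.  The
published gain/loss counts for real data came from an unstated rule on
external data, so recovery is assessed on planted effects only.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Genome:** 4 chromosomes × 8 Mb, 10-kb bins (3200 bins) by default; the
  boundary-enrichment surface uses 20 chromosomes so the compared groups
  are 1000 + 1000 bins, the published group sizes.
* **Regions:** satellite territory [0, 3) Mb, boundary window [3, 3.5) Mb,
  background elsewhere — the telocentric layout the real analysis assumes.
* **Counts:** per-bin reads ~ NB(mean = baseline × region enrichment ×
  condition effect, size = dispersion).  Negative binomial rather than
  Poisson because ChIP bin counts are overdispersed; baseline 100
  reads/bin and size 10 give a realistic ~35 % coefficient of variation.
  Matched inputs are NB(baseline).  Defaults: H3K9me3 is 4× enriched over
  satellite and 2× over boundary in both conditions; knockdown multiplies
  satellite H3K9me3 by 0.6 and boundary H3K9me3 by 1.5; PHF2 is 2×
  boundary-enriched in control and flat after knockdown.  H3K9me3 has 2
  replicates and PHF2 3, as in the experiments being emulated.  One RNG
  stream per (condition, target, replicate) derives from the master seed,
  so adding a replicate never changes existing tracks.
* **Annotation:** seven Satellite-class groups placed as tandem arrays
  inside the satellite span with the GSAT-like major-satellite group
  innermost (77 instances, the real GSAT_MM count; other groups
  down-scaled), plus dispersed LINE/SINE/LTR/DNA instances and a planted
  blacklist over five known records.
* **Bin-change surface:** control values are NB(baseline) counts; bins
  with no true change fluctuate by a normal jitter *clipped at 1.8 σ*, and
  planted bins shift by planted_effect (default 10) × the null MAD.  The
  clip keeps every null bin below the 3-raw-MAD ≈ 2.02 σ cutoff, making
  planted recovery exactly identifiable.  This is a deliberate departure
  from unbounded noise: with normal tails a relative 3-MAD rule miscalls a
  fixed ~2–4 % of null bins at *any* noise level (the threshold scales
  with the noise), so exact-count recovery would be meaningless as a
  correctness check.  Passing it therefore shows the calling rule is
  implemented correctly, not that real, unbounded-noise data would yield
  exact counts.
* **Imaging:** stacks are Gaussian noise on a constant background plus
  Gaussian or hard-sphere foci in voxel space; truth (centers, radii) is
  recorded.

What the generator does **not** emulate: read-level sampling (no
FASTQ/BAM, fragment lengths, GC or mappability structure), strandedness,
inter-replicate batch effects, spatially correlated coverage, or the
actual repeat sequence content.  Passing tests demonstrate correctness of
the quantification and inference machinery under the stated model, not
performance on real sequencing data.

## Imaging quantification

Corrected total fluorescence is IntDen − (ROI area × mean background),
the standard ImageJ background correction; negative values are allowed
and logged.  Foci are connected components of {intensity ≥ threshold}
(threshold inclusive, default 50 as a fixed global cutoff on 8-bit-scale
intensities — the published "average threshold of 50" is read as fixed,
with the averaging taken to be across images; connectivity 26 by default,
the 3D Objects Counter convention, with 6 available).  Volumes are voxel
counts × dz·dy·dx with dz defaulting to the 0.13 µm z-step.  No watershed
splitting of merged foci is attempted.  Radial profiles average intensity
in concentric calibrated shells, so anisotropic z is handled; channel peak
distance is the difference of interior profile maxima, ties resolving to
the smaller radius.

## Numerical and reproducibility choices

* Random-bin sampling is without replacement, excludes the boundary
  window and partial bins, and requires a seed; every stochastic output
  records its seed and is bit-reproducible from it.
* Cross-chromosome profile SE uses the sample SD (n − 1).
* bedGraph writing uses shortest round-trip float formatting, so
  read(write(track)) == track.
* Clustering tie-breaks follow input order (scipy's deterministic
  behaviour); dropped missing-value rows are logged.
* Problem sizes for the calibration studies: null calibration uses 1000
  simulated null datasets of 40 + 40 values with 999 permutations each;
  power uses 200 datasets of 1000 + 1000 with a 1-SD median shift and the
  full N = 10,000; direction recovery uses 100 seeds of the default
  simulation.  These sizes make the Monte-Carlo error on the reported
  rates a few percent.

## Known limitations

* bigWig input is optional (pyBigWig); bedGraph is the canonical format.
* No BAM/coverage computation, peak calling, multi-testing machinery, TE
  expression quantification, or liftover.
* Only telocentric (mouse-like) centromere geometry: the boundary window
  is measured from coordinate 0; metacentric chromosomes would need
  per-arm windows.
* The `overlap_unweighted` mode reproduces `bedtools map -o mean`
  semantics only for non-overlapping query-segment configurations, which
  is the case for all fixed-bin workflows here.
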