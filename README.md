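# pchtools

Quantitative analysis of epigenomic signal (ChIP-seq / ATAC-seq / RNA-seq
coverage) over repeat annotations and pericentromeric-heterochromatin (PcH)
boundary regions in the mouse genome, plus 3D nuclear-foci quantification
for chromocenter imaging.  Built for analyses of heterochromatin regulators
(e.g. the histone demethylase PHF2) where the questions are: how does signal
distribute over repeat classes such as the major satellite (GSAT_MM), what
happens at the heterochromatin boundary just distal to the centromeric end
of each telocentric mouse chromosome, and which genome-wide bins gain or
lose a mark between a control (shCT) and a knockdown (shPHF2) condition?

## What it computes

* **Binning and windows.**  The genome (mm10 chrom.sizes shipped) is tiled
  into fixed-width bins (15 kb for genome-wide gain/loss scans, 10 kb for
  boundary work).  The pericentromeric boundary window is 3.0–3.5 Mb from
  the chromosome start — mouse chromosomes are telocentric and mm10 opens
  with a ~3 Mb centromeric assembly gap, so coordinate 0 is the centromeric
  end.  On chr1–chr19 + chrX at 10 kb this window holds exactly
  20 × 50 = 1000 bins.
* **Signal quantification.**  bedGraph tracks are CPM-normalised
  (v → v·10⁶/total) and input-subtracted per base, then averaged over
  intervals (base-weighted, uncovered = 0; a `bedtools map -o mean`
  compatibility mode is available).
* **Repeat hierarchy.**  TEtranscripts-dialect GTF (gene_id / family_id /
  class_id = Repeat group / Family / Class), ENCODE-style blacklist
  filtering (any ≥ 1 bp overlap discards a repeat), per-group distributions
  of per-repeat means, group-by-sample matrices, and euclidean /
  complete-linkage clustering for heatmap ordering.
* **Boundary statistics.**  Cross-chromosome signal profiles over
  2.5–5 Mb with SE bands; a permutation test of the difference in medians
  between the 1000 pericentromeric bins and 1000 random background bins
  (label shuffling over the pooled values, N = 10,000 permutations,
  p = (1 + #{null ≥ observed}) / (N + 1), exhaustive enumeration when
  feasible); Wilcoxon signed-rank (paired bins across conditions) and
  Mann–Whitney U (independent bin sets), exact for small samples.
* **Gain/loss bin calling.**  Per-bin delta (knockdown − control) labelled
  by a robust z-score, z = (δ − median)/MAD, gain if z > 3, loss if z < −3.
* **Imaging.**  Corrected total fluorescence
  (IntDen − area × background mean), 3D foci segmentation by global
  threshold (default 50) and 26-connectivity with volumes in µm³
  (z-step 0.13 µm), radial intensity profiles and channel peak distances.
* **Synthetic data.**  A seeded generator producing toy genomes, repeat
  annotations, blacklists, and negative-binomial paired-condition tracks
  with planted satellite/boundary/bin-level effects, so the whole pipeline
  is testable without downloads.

## Worked example

```python
import numpy as np
from pchtools import (
    BoundaryWindowSpec, boundary_bins, mm10_layout, tile_genome,
    sample_random_bins, permutation_median_test,
)
from pchtools.simulate import (
    SimulationConfig, make_toy_genome, simulate_tracks, condition_bin_means,
)

# 1000 pericentromeric bins on mm10
grid = tile_genome(mm10_layout(), 10_000)
peri = boundary_bins(grid, BoundaryWindowSpec())
print(len(peri))                      # -> 1000

# planted boundary enrichment on a 20-chromosome toy genome
cfg = SimulationConfig(n_chromosomes=20)
layout, toy_grid = make_toy_genome(cfg)
sim = simulate_tracks(layout, toy_grid, cfg, seed=1)
phf2 = condition_bin_means(sim, "PHF2", "shCT")   # input-subtracted CPM/bin

spec = BoundaryWindowSpec(chromosomes=tuple(layout.names))
peri = boundary_bins(toy_grid, spec)
rng = np.random.default_rng(1)
rand = sample_random_bins(toy_grid, len(peri), exclude=peri, rng=rng)
idx = {b: i for i, b in enumerate(toy_grid.bins)}
res = permutation_median_test(
    phf2[[idx[b] for b in peri]], phf2[[idx[b] for b in rand]],
    n_permutations=10_000, rng=rng, alternative="greater",
)
print(round(res.observed_diff, 2))    # -> 59.38
print(res.p_value)                    # -> 9.999000099990002e-05
```

The observed difference in medians (boundary minus background,
input-subtracted CPM units) is large and the permutation p-value is at its
floor 1/(N+1) ≈ 1e-4: the planted two-fold boundary enrichment is
decisively detected.

A CLI wraps the same stages:

```bash
pchtools simulate --out fixtures/ --seed 1
pchtools boundary-test --chrom-sizes fixtures/toy.chrom.sizes \
    --track my_track.bedgraph --seed 1 --out results/
pchtools bin-changes --chrom-sizes fixtures/toy.chrom.sizes \
    --ct ct.bedgraph --kd kd.bedgraph --out results/
```

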