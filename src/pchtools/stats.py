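"""Boundary profiles, the median-difference permutation test, rank tests,
and genome-wide gain/loss bin calling.

The regional-enrichment statistic is the difference of group medians
(pericentromeric bins vs random background bins).  Its null is built by
pooling the two groups and permuting labels with group sizes fixed
(N = 10,000 by default), with the +1-corrected p-value so p is never
exactly zero; when the number of distinct labelings is small the test
enumerates them all instead of sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BinGrid, BoundaryWindowSpec, GenomicInterval
from .tracks import BASE_WEIGHTED, SignalTrack, quantify

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 10_000
EXHAUSTIVE_LIMIT = 10_000


@dataclass
class BoundaryProfile:
    """Signal profile over offset bins near the centromeric end.

    ``per_chromosome`` has one row per chromosome and one column per offset
    bin start within the plotting range; ``cross_mean``/``cross_se`` are the
    across-chromosome mean and standard error (sample SD / sqrt(n)).
    """

    offsets: np.ndarray
    per_chromosome: pd.DataFrame
    cross_mean: np.ndarray
    cross_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.per_chromosome.T.copy()
        out.insert(0, "offset", self.offsets)
        out["mean"] = self.cross_mean
        out["se"] = self.cross_se
        return out


def boundary_profile(
    track: SignalTrack,
    spec: BoundaryWindowSpec,
    bin_width: int = 10_000,
    mode: str = BASE_WEIGHTED,
) -> BoundaryProfile:
    """Mean signal in ``bin_width`` bins across the plotting range.

    Chromosomes shorter than the plotting range are dropped with a warning;
    with none eligible an error is raised.
    """
    lo, hi = spec.plot_range
    offsets = np.arange(lo, hi, bin_width, dtype=np.int64)
    rows = {}
    for chrom in spec.chromosomes:
        if track.layout.length_of(chrom) < hi:
            logger.warning("chromosome %s shorter than plot range; dropped", chrom)
            continue
        bins = [
            GenomicInterval(chrom, int(o), int(min(o + bin_width, hi)))
            for o in offsets
        ]
        rows[chrom] = quantify(track, bins, mode=mode)
    if not rows:
        raise ValueError("no chromosome long enough for the plot range")
    per_chrom = pd.DataFrame(rows).T
    per_chrom.columns = offsets
    values = per_chrom.to_numpy()
    cross_mean = values.mean(axis=0)
    n = values.shape[0]
    cross_se = (
        values.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(len(offsets))
    )
    return BoundaryProfile(
        offsets=offsets,
        per_chromosome=per_chrom,
        cross_mean=cross_mean,
        cross_se=cross_se,
    )


@dataclass
class PermutationResult:
    """Observed median difference, its permutation null, and the p-value."""

    observed_diff: float
    null_diffs: np.ndarray
    n_permutations: int
    p_value: float
    alternative: str
    seed: int | None
    exhaustive: bool = False

    def summary(self) -> dict:
        return {
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "alternative": self.alternative,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


def _drop_missing(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    n_missing = int(np.isnan(x).sum())
    if n_missing:
        logger.info("dropped %d missing values", n_missing)
        x = x[~np.isnan(x)]
    return x


def _tail_count(null: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "greater":
        return int(np.sum(null >= observed))
    if alternative == "less":
        return int(np.sum(null <= observed))
    if alternative == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed)))
    raise ValueError(f"unknown alternative {alternative!r}")


def _col_medians(block: np.ndarray) -> np.ndarray:
    """Median along axis 0 via partial sort (faster than np.median here)."""
    n = block.shape[0]
    k = n // 2
    if n % 2:
        return np.partition(block, k, axis=0)[k]
    part = np.partition(block, [k - 1, k], axis=0)
    return 0.5 * (part[k - 1] + part[k])


def permutation_median_test(
    a,
    b,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    alternative: str = "greater",
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test of median(a) − median(b) by label shuffling.

    The pooled values are relabelled ``n_permutations`` times with group
    sizes fixed and the median difference recomputed; the p-value is
    (1 + tail count) / (n_permutations + 1).  When the number of distinct
    labelings C(n_a+n_b, n_a) is at most 10,000 all labelings are
    enumerated instead and the p-value is the exact tail fraction.
    """
    a = _drop_missing(a)
    b = _drop_missing(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty after missing-value removal")
    observed = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)

    n_labelings = math.comb(n, n_a)
    if n_labelings <= EXHAUSTIVE_LIMIT:
        null = np.empty(n_labelings)
        for i, idx in enumerate(combinations(range(n), n_a)):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            null[i] = np.median(pooled[sel]) - np.median(pooled[~sel])
        p = _tail_count(null, observed, alternative) / n_labelings
        return PermutationResult(
            observed_diff=observed,
            null_diffs=null,
            n_permutations=n_labelings,
            p_value=p,
            alternative=alternative,
            seed=seed,
            exhaustive=True,
        )

    if rng is None:
        rng = np.random.default_rng(seed)
    # partial Fisher-Yates per row: after k swap steps the first k columns
    # hold a uniform random k-subset and the rest its complement
    null = np.empty(n_permutations)
    block_size = max(1, min(n_permutations, 20_000_000 // max(n, 1)))
    k = min(n_a, n - n_a)
    done = 0
    while done < n_permutations:
        m = min(block_size, n_permutations - done)
        block = np.repeat(pooled[:, None], m, axis=1)  # (n, m): rows contiguous
        cols = np.arange(m)
        for j in range(k):
            r = rng.integers(j, n, size=m)
            tmp = block[j].copy()
            block[j] = block[r, cols]
            block[r, cols] = tmp
        med_small = _col_medians(block[:k])
        med_large = _col_medians(block[k:])
        if k == n_a:
            null[done : done + m] = med_small - med_large
        else:
            null[done : done + m] = med_large - med_small
        done += m
    p = (1 + _tail_count(null, observed, alternative)) / (n_permutations + 1)
    return PermutationResult(
        observed_diff=observed,
        null_diffs=null,
        n_permutations=n_permutations,
        p_value=p,
        alternative=alternative,
        seed=seed,
    )


def permutation_background_resample_test(
    track: SignalTrack,
    boundary: list[GenomicInterval],
    grid: BinGrid,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    alternative: str = "greater",
    mode: str = BASE_WEIGHTED,
) -> PermutationResult:
    """Alternative null: redraw the background bin set each round.

    Instead of shuffling labels over pooled values, each permutation draws
    a fresh random bin set of the background's size from the grid
    (excluding the boundary bins) and recomputes the median difference
    against the fixed boundary quantification.
    """
    from .genome import sample_random_bins

    rng = np.random.default_rng(seed)
    bvals = _drop_missing(quantify(track, boundary, mode=mode))
    obs_bg = sample_random_bins(grid, len(boundary), exclude=boundary, rng=rng)
    bg_vals = _drop_missing(quantify(track, obs_bg, mode=mode))
    observed = float(np.median(bvals) - np.median(bg_vals))
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        draw = sample_random_bins(grid, len(boundary), exclude=boundary, rng=rng)
        vals = _drop_missing(quantify(track, draw, mode=mode))
        null[i] = float(np.median(bvals) - np.median(vals))
    p = (1 + _tail_count(null, observed, alternative)) / (n_permutations + 1)
    return PermutationResult(
        observed_diff=observed,
        null_diffs=null,
        n_permutations=n_permutations,
        p_value=p,
        alternative=alternative,
        seed=seed,
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided sign-flip p for the signed-rank sum.

    Builds the null distribution of W+ over all 2^n sign assignments by
    dynamic programming on (doubled, hence integer) midranks, so tied
    |differences| are handled exactly.  Two-sided tail: deviations from
    the null mean at least as large as observed.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    m2 = int(r2.sum())
    dp = np.zeros(m2 + 1)
    dp[0] = 1.0
    for r in r2:
        new = dp.copy()
        new[r:] += dp[: m2 + 1 - r]
        dp = new
    values = np.arange(m2 + 1)
    center = m2 / 2.0
    dev = abs(2 * w_plus - center)
    tail = dp[np.abs(values - center) >= dev - 1e-9].sum()
    return float(min(1.0, tail / 2 ** len(ranks)))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (logged).  Exact sign-flip null for
    n <= 25 (tie-safe via midranks); tie-corrected normal approximation
    for larger samples.  The statistic is min(W+, W-).
    """
    a = np.asarray(paired_a, dtype=np.float64).ravel()
    b = np.asarray(paired_b, dtype=np.float64).ravel()
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info("dropped %d pairs with missing values", n_missing)
    d = a[ok] - b[ok]
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info("dropped %d zero differences", n_zero)
    d = d[nonzero]
    if len(d) == 0:
        logger.warning("all differences zero; p = 1")
        return 0.0, 1.0
    if len(d) <= 25:
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        w_minus = float(ranks.sum() - w_plus)
        return min(w_plus, w_minus), _exact_signed_rank_p(ranks, w_plus)
    res = sps.wilcoxon(d, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test on independent samples.

    Exact null for small samples without ties, tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = _drop_missing(a)
    b = _drop_missing(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BinChangeCalls:
    """Per-bin condition deltas with gain/loss/unchanged labels."""

    delta: np.ndarray
    labels: np.ndarray  # array of {"gain", "loss", "unchanged"}
    threshold_spec: dict
    n_gain: int
    n_loss: int

    def to_bed(self, bins: list[GenomicInterval]) -> str:
        out = []
        for iv, lab, d in zip(bins, self.labels, self.delta):
            if lab != "unchanged":
                out.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\t{d:g}\n")
        return "".join(out)


def call_bin_changes(
    ct,
    kd,
    method: str = "robust_z",
    k: float = 3.0,
    tau: float | None = None,
) -> BinChangeCalls:
    """Label bins gain/loss by the knockdown-minus-control delta.

    ``robust_z``: z = (delta − median(delta)) / MAD(delta) with the raw
    (unscaled) median absolute deviation; gain iff z > k, loss iff z < −k
    (k = 3 by default).  ``abs_delta``: gain iff delta > tau, loss iff
    delta < −tau.  MAD of 0 falls back to abs_delta with a warning.
    The rule is shift-invariant: adding a constant to both conditions
    leaves the calls unchanged.
    """
    ct = np.asarray(ct, dtype=np.float64).ravel()
    kd = np.asarray(kd, dtype=np.float64).ravel()
    if len(ct) != len(kd):
        raise ValueError("ct and kd must have equal length (aligned bins)")
    delta = kd - ct
    spec: dict = {"method": method}
    if method == "robust_z":
        med = float(np.median(delta))
        mad = float(np.median(np.abs(delta - med)))
        if mad == 0.0:
            logger.warning("MAD is 0; falling back to abs_delta")
            return call_bin_changes(
                ct, kd, method="abs_delta", tau=0.0 if tau is None else tau
            )
        z = (delta - med) / mad
        gain = z > k
        loss = z < -k
        spec.update(k=k, median=med, mad=mad)
    elif method == "abs_delta":
        if tau is None:
            raise ValueError("abs_delta requires tau")
        gain = delta > tau
        loss = delta < -tau
        spec.update(tau=tau)
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = np.full(len(delta), "unchanged", dtype=object)
    labels[gain] = "gain"
    labels[loss] = "loss"
    return BinChangeCalls(
        delta=delta,
        labels=labels,
        threshold_spec=spec,
        n_gain=int(gain.sum()),
        n_loss=int(loss.sum()),
    )
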