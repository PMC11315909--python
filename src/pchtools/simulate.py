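"""Synthetic genomes, repeat annotations and paired-condition signal tracks.

The generator emulates the statistical structure the boundary analysis
assumes: telocentric chromosomes whose proximal ~3 Mb is satellite repeat
territory, a 3–3.5 Mb boundary window, negative-binomial per-bin read
counts (overdispersed, as ChIP bins are), and multiplicative condition
effects — in the knockdown, satellite H3K9me3 drops (x0.6) while boundary
H3K9me3 rises (x1.5); PHF2 is boundary-enriched in the control (x2.0) and
flat after knockdown.  Matched inputs are flat negative-binomial noise.

Everything is seeded: one RNG stream per (condition, target, replicate) is
derived from the master seed, so adding a replicate never perturbs the
counts of existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import (
    BinGrid,
    GenomeLayout,
    GenomicInterval,
    intervals_to_bed,
    tile_genome,
)
from .imaging import ImageStack3D
from .repeats import RepeatHierarchy, RepeatRecord, write_repeat_gtf
from .tracks import RAW_COUNTS, SignalTrack, cpm_normalize, subtract_tracks, write_bedgraph

CONDITIONS = ("shCT", "shPHF2")

# raw-MAD of a standard normal: |N(0,1)| median
_NORMAL_MAD = 0.6744897501960817


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic genome and tracks."""

    n_chromosomes: int = 4
    chromosome_length: int = 8_000_000
    satellite_span: tuple[int, int] = (0, 3_000_000)
    boundary_window: tuple[int, int] = (3_000_000, 3_500_000)
    bin_width: int = 10_000
    baseline_mean: float = 100.0
    dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    #: per-target enrichment over background, identical in both conditions
    region_enrichment: dict = field(
        default_factory=lambda: {
            "H3K9me3": {"satellite": 4.0, "boundary": 2.0, "background": 1.0},
            "PHF2": {"satellite": 1.0, "boundary": 1.0, "background": 1.0},
        }
    )
    #: multiplicative condition effects keyed (target, region, condition)
    condition_effects: dict = field(
        default_factory=lambda: {
            ("H3K9me3", "satellite", "shPHF2"): 0.6,
            ("H3K9me3", "boundary", "shPHF2"): 1.5,
            ("PHF2", "boundary", "shCT"): 2.0,
        }
    )
    replicates: dict = field(default_factory=lambda: {"H3K9me3": 2, "PHF2": 3})
    #: planted bin-change surface
    n_gain_bins: int = 168
    n_loss_bins: int = 22
    planted_effect: float = 10.0  # in MAD multiples of the null delta

    def __post_init__(self) -> None:
        if self.satellite_span[1] > self.chromosome_length:
            raise ValueError("satellite span exceeds chromosome length")
        if self.boundary_window[1] > self.chromosome_length:
            raise ValueError("boundary window exceeds chromosome length")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")
        for v in self.condition_effects.values():
            if v <= 0:
                raise ValueError("condition effects must be > 0")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside simulated data."""

    region_labels: np.ndarray  # per grid bin: satellite/boundary/background
    gain_bin_ids: np.ndarray
    loss_bin_ids: np.ndarray
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "region_labels": self.region_labels.tolist(),
                "gain_bin_ids": self.gain_bin_ids.tolist(),
                "loss_bin_ids": self.loss_bin_ids.tolist(),
                "seed": self.seed,
            }
        )


def _stream(seed: int, *parts: str) -> np.random.Generator:
    """Independent RNG stream derived from the master seed and a name."""
    tags = [zlib.crc32(p.encode()) for p in parts]
    return np.random.default_rng([int(seed), *tags])


def make_toy_genome(config: SimulationConfig) -> tuple[GenomeLayout, BinGrid]:
    """Equal-length toy chromosomes tiled at the configured bin width."""
    layout = GenomeLayout(
        tuple(
            (f"chr{i + 1}", config.chromosome_length)
            for i in range(config.n_chromosomes)
        )
    )
    grid = tile_genome(layout, config.bin_width, keep_partial=True)
    return layout, grid


def region_labels(grid: BinGrid, config: SimulationConfig) -> np.ndarray:
    """Per-bin region label: satellite / boundary / background."""
    s_lo, s_hi = config.satellite_span
    b_lo, b_hi = config.boundary_window
    labels = np.full(len(grid.bins), "background", dtype=object)
    for i, b in enumerate(grid.bins):
        if b.start >= s_lo and b.end <= s_hi:
            labels[i] = "satellite"
        elif b.start >= b_lo and b.end <= b_hi:
            labels[i] = "boundary"
    return labels


#: default Satellite-class group counts (down-scaled tandem arrays; the
#: GSAT-like major-satellite group keeps its real instance count of 77)
DEFAULT_SATELLITE_GROUPS: dict[str, int] = {
    "GSAT_MM": 77,
    "MMSAT4": 60,
    "MurSAT1": 54,
    "IMPB_01": 40,
    "ZP3AR": 26,
    "SUBTEL_sa": 31,
    "SYNREP_MM": 20,
}

DEFAULT_INTERSPERSED: dict[str, tuple[str, str, int]] = {
    # group: (family, class, count)
    "L1Md_A": ("L1", "LINE", 120),
    "B1_Mus1": ("Alu", "SINE", 150),
    "IAPEz-int": ("ERVK", "LTR", 90),
    "Tigger1": ("TcMar-Tigger", "DNA", 60),
}


def make_toy_annotation(
    layout: GenomeLayout,
    config: SimulationConfig,
    seed: int,
    satellite_groups: dict[str, int] | None = None,
    interspersed: dict[str, tuple[str, str, int]] | None = None,
    n_blacklisted: int = 5,
) -> tuple[list[RepeatRecord], RepeatHierarchy, list[GenomicInterval], dict]:
    """Toy repeat annotation with tandem satellites and dispersed repeats.

    Satellite groups sit tandem within the satellite span, the GSAT-like
    group innermost (closest to the centromeric end at coordinate 0);
    interspersed LINE/SINE/LTR/DNA instances are uniform outside it.  A
    small blacklist is planted over ``n_blacklisted`` known satellite
    records; their indices are returned in the truth dict.
    """
    rng = _stream(seed, "annotation")
    sat_groups = dict(
        DEFAULT_SATELLITE_GROUPS if satellite_groups is None else satellite_groups
    )
    inter = dict(DEFAULT_INTERSPERSED if interspersed is None else interspersed)
    s_lo, s_hi = config.satellite_span
    chrom_names = layout.names
    records: list[RepeatRecord] = []
    hierarchy = RepeatHierarchy()

    # tandem satellite arrays: per chromosome, groups laid inner -> outer
    cursors = {c: s_lo + 50_000 for c in chrom_names}
    for group, count in sat_groups.items():
        hierarchy.add(group, "Satellite", "Satellite")
        for j in range(count):
            chrom = chrom_names[j % len(chrom_names)]
            length = int(rng.integers(500, 5_000))
            start = cursors[chrom]
            end = start + length
            if end > s_hi:
                raise ValueError(
                    f"satellite span overflow on {chrom} placing {group}"
                )
            records.append(
                RepeatRecord(
                    interval=GenomicInterval(chrom, start, end),
                    strand="+" if rng.random() < 0.5 else "-",
                    group=group,
                    family="Satellite",
                    class_name="Satellite",
                )
            )
            cursors[chrom] = end + int(rng.integers(100, 2_000))

    # interspersed repeats uniform outside the satellite span
    for group, (family, class_name, count) in inter.items():
        hierarchy.add(group, family, class_name)
        for _ in range(count):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            length = int(rng.integers(300, 6_000))
            start = int(rng.integers(s_hi, layout.length_of(chrom) - length))
            records.append(
                RepeatRecord(
                    interval=GenomicInterval(chrom, start, start + length),
                    strand="+" if rng.random() < 0.5 else "-",
                    group=group,
                    family=family,
                    class_name=class_name,
                )
            )

    # plant a blacklist over a known subset of satellite records
    sat_idx = [i for i, r in enumerate(records) if r.class_name == "Satellite"]
    chosen = sorted(
        int(i) for i in rng.choice(sat_idx, size=n_blacklisted, replace=False)
    )
    blacklist = [
        GenomicInterval(
            records[i].interval.chrom,
            records[i].interval.start,
            records[i].interval.start + 1,
        )
        for i in chosen
    ]
    truth = {"blacklisted_record_ids": chosen, "seed": seed}
    return records, hierarchy, blacklist, truth


@dataclass
class SimulatedTracks:
    """Raw-count signal and matched input tracks plus ground truth."""

    signal: dict[tuple[str, str, int], SignalTrack]
    input: dict[tuple[str, str, int], SignalTrack]
    truth: SimulationTruth
    grid: BinGrid


def simulate_tracks(
    layout: GenomeLayout,
    grid: BinGrid,
    config: SimulationConfig,
    seed: int,
) -> SimulatedTracks:
    """Negative-binomial per-bin counts for every condition/target/replicate.

    Per-bin mean = baseline x region enrichment x condition effect; matched
    inputs are NB(baseline).  Totals (sums of bin counts) are recorded on
    each track for CPM scaling.
    """
    labels = region_labels(grid, config)
    n_bins = len(grid.bins)
    signal: dict[tuple[str, str, int], SignalTrack] = {}
    inputs: dict[tuple[str, str, int], SignalTrack] = {}
    for target, n_reps in config.replicates.items():
        enr = config.region_enrichment.get(target, {})
        base_mu = np.array(
            [config.baseline_mean * enr.get(lab, 1.0) for lab in labels]
        )
        for condition in CONDITIONS:
            mu = base_mu.copy()
            for region in ("satellite", "boundary", "background"):
                eff = config.condition_effects.get((target, region, condition))
                if eff is not None:
                    mu[labels == region] *= eff
            for rep in range(1, n_reps + 1):
                rng = _stream(seed, f"{condition}/{target}/rep{rep}")
                p = config.dispersion / (config.dispersion + mu)
                counts = rng.negative_binomial(config.dispersion, p, size=n_bins)
                counts = counts.astype(np.float64)
                signal[(condition, target, rep)] = SignalTrack.from_bin_values(
                    grid, counts, kind=RAW_COUNTS, total_units=float(counts.sum())
                )
                rng_in = _stream(seed, f"{condition}/{target}/input{rep}")
                p0 = config.dispersion / (config.dispersion + config.baseline_mean)
                in_counts = rng_in.negative_binomial(
                    config.dispersion, p0, size=n_bins
                ).astype(np.float64)
                inputs[(condition, target, rep)] = SignalTrack.from_bin_values(
                    grid,
                    in_counts,
                    kind=RAW_COUNTS,
                    total_units=float(in_counts.sum()),
                )
    truth = SimulationTruth(
        region_labels=labels,
        gain_bin_ids=np.empty(0, dtype=int),
        loss_bin_ids=np.empty(0, dtype=int),
        seed=seed,
    )
    return SimulatedTracks(signal=signal, input=inputs, truth=truth, grid=grid)


def input_subtracted_cpm(
    signal: SignalTrack, input_: SignalTrack
) -> SignalTrack:
    """CPM-normalise both tracks (by their recorded totals) and subtract."""
    return subtract_tracks(cpm_normalize(signal), cpm_normalize(input_))


def condition_bin_means(
    sim: SimulatedTracks, target: str, condition: str
) -> np.ndarray:
    """Replicate-averaged input-subtracted CPM per grid bin.

    Replicates are averaged after per-bin quantification, matching the
    "averaged values obtained from replicates" convention.
    """
    from .tracks import quantify

    reps = sorted(
        rep for (c, t, rep) in sim.signal if c == condition and t == target
    )
    if not reps:
        raise ValueError(f"no replicates for ({condition}, {target})")
    acc = np.zeros(len(sim.grid.bins))
    for rep in reps:
        track = input_subtracted_cpm(
            sim.signal[(condition, target, rep)],
            sim.input[(condition, target, rep)],
        )
        acc += quantify(track, sim.grid.bins)
    return acc / len(reps)


def simulate_bin_deltas(
    config: SimulationConfig,
    seed: int,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Paired condition bin values with planted gain/loss bins.

    Control values are NB(baseline) counts.  Unchanged bins fluctuate by a
    clipped normal (|jitter| <= 1.8 sigma, below the 3-raw-MAD cutoff of
    about 2.02 sigma), so the null never crosses a 3-MAD threshold and the
    planted bins — shifted by ``planted_effect`` x the null MAD — are the
    only calls.  This is the identifiability construction for planted
    recovery; see the methods note for what it does and does not emulate.
    """
    if n_bins is None:
        n_bins = config.n_chromosomes * (
            config.chromosome_length // config.bin_width
        )
    n_planted = config.n_gain_bins + config.n_loss_bins
    if n_planted > n_bins:
        raise ValueError("more planted bins than bins")
    rng = _stream(seed, "bin_deltas")
    p0 = config.dispersion / (config.dispersion + config.baseline_mean)
    ct = rng.negative_binomial(config.dispersion, p0, size=n_bins).astype(
        np.float64
    )
    sigma = 1.0  # null fluctuation scale; calls are scale-relative
    jitter = np.clip(rng.normal(0.0, sigma, size=n_bins), -1.8 * sigma, 1.8 * sigma)
    kd = ct + jitter
    planted = rng.choice(n_bins, size=n_planted, replace=False)
    gain_ids = np.sort(planted[: config.n_gain_bins])
    loss_ids = np.sort(planted[config.n_gain_bins :])
    shift = config.planted_effect * _NORMAL_MAD * sigma
    kd[gain_ids] += shift
    kd[loss_ids] -= shift
    truth = SimulationTruth(
        region_labels=np.full(n_bins, "background", dtype=object),
        gain_bin_ids=gain_ids,
        loss_bin_ids=loss_ids,
        seed=seed,
    )
    return ct, kd, truth


def make_toy_stack(
    shape: tuple[int, int, int],
    foci: Sequence[tuple[tuple[float, float, float], float, float]],
    background_mean: float = 10.0,
    noise_sd: float = 2.0,
    calibration: tuple[float, float, float] = (0.13, 0.1, 0.1),
    seed: int = 0,
    profile: str = "gaussian",
) -> tuple[ImageStack3D, dict]:
    """Noisy background stack with planted foci.

    ``foci`` is a list of (center (z, y, x) in voxels, radius in voxels,
    amplitude).  ``gaussian`` blobs use the radius as the Gaussian sigma;
    ``sphere`` paints a hard ball of that voxel radius (useful for exact
    voxel-count checks).  Truth (centers, radii, amplitudes) is returned.
    """
    rng = _stream(seed, "stack")
    nz, ny, nx = shape
    for (cz, cy, cx), _r, _a in foci:
        if not (0 <= cz < nz and 0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"focus center {(cz, cy, cx)} outside volume {shape}")
    vox = np.full(shape, float(background_mean))
    if noise_sd > 0:
        vox += rng.normal(0.0, noise_sd, size=shape)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    for (cz, cy, cx), radius, amplitude in foci:
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        if profile == "gaussian":
            vox += amplitude * np.exp(-d2 / (2.0 * radius**2))
        elif profile == "sphere":
            vox += amplitude * (d2 <= radius**2)
        else:
            raise ValueError(f"unknown profile {profile!r}")
    vox = np.clip(vox, 0.0, None)
    truth = {
        "centers": [list(c) for c, _, _ in foci],
        "radii": [r for _, r, _ in foci],
        "amplitudes": [a for _, _, a in foci],
        "seed": seed,
        "profile": profile,
    }
    return ImageStack3D(voxels=vox, calibration=calibration), truth


def write_fixture_dir(
    out_dir: str | Path, config: SimulationConfig, seed: int
) -> dict:
    """Write a complete text fixture set regenerable from one seed.

    Produces chrom.sizes, annotation GTF, blacklist BED, one bedGraph per
    signal and input track, and a truth JSON; returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, grid = make_toy_genome(config)
    (out / "toy.chrom.sizes").write_text(
        "".join(f"{n}\t{l}\n" for n, l in layout.chromosomes)
    )
    records, hierarchy, blacklist, ann_truth = make_toy_annotation(
        layout, config, seed
    )
    (out / "annotation.gtf").write_text(write_repeat_gtf(records))
    (out / "blacklist.bed").write_text(intervals_to_bed(blacklist))
    sim = simulate_tracks(layout, grid, config, seed)
    track_files = []
    for (condition, target, rep), track in sorted(sim.signal.items()):
        name = f"{condition}_{target}_rep{rep}.bedgraph"
        (out / name).write_text(write_bedgraph(track))
        track_files.append({"file": name, "total_units": track.total_units})
    for (condition, target, rep), track in sorted(sim.input.items()):
        name = f"{condition}_{target}_input{rep}.bedgraph"
        (out / name).write_text(write_bedgraph(track))
        track_files.append({"file": name, "total_units": track.total_units})
    truth = {
        "seed": seed,
        "annotation": ann_truth,
        "region_labels": sim.truth.region_labels.tolist(),
        "tracks": track_files,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    manifest = {
        "chrom_sizes": "toy.chrom.sizes",
        "annotation": "annotation.gtf",
        "blacklist": "blacklist.bed",
        "tracks": [t["file"] for t in track_files],
        "truth": "truth.json",
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
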