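"""Chromosome coordinate frame, fixed-width binning and boundary-window bins.

All coordinates in this package are 0-based half-open (``[start, end)``),
the BED/bedGraph convention; GTF input (1-based inclusive) is converted at
read time.  The "centromeric end" of a mouse chromosome is coordinate 0:
mouse chromosomes are telocentric and the mm10 assembly opens with a ~3 Mb
unassembled centromeric gap, which is why the pericentromeric test window
starts at 3 Mb from the start of each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: chromosomes used for the 1000-bin pericentromeric window (20 x 50 bins of
#: 10 kb in a 500-kb window); chrY and unplaced scaffolds are excluded.
DEFAULT_BOUNDARY_CHROMOSOMES: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 20)] + ["chrX"]
)


class GenomicInterval(NamedTuple):
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Named, ordered chromosomes with lengths.

    The frame for all interval arithmetic: every interval used with a layout
    must name one of its chromosomes and lie within ``[0, length)``.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        for name, length in self.chromosomes:
            if not name:
                raise ValueError("empty chromosome name")
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self:
            raise ValueError(f"interval on unknown chromosome {interval.chrom!r}")
        if not (0 <= interval.start < interval.end <= self.length_of(interval.chrom)):
            raise ValueError(
                f"invalid interval {interval} on {interval.chrom} "
                f"(length {self.length_of(interval.chrom)})"
            )


@dataclass
class BinGrid:
    """Fixed-width tiling of a genome, chromosome by chromosome from 0.

    ``partial_flags[i]`` marks terminal bins shorter than ``bin_width``;
    partial bins are kept when ``keep_partial`` but excluded from boundary
    statistics and random-bin sampling.
    """

    layout: GenomeLayout
    bin_width: int
    bins: list[GenomicInterval]
    keep_partial: bool
    partial_flags: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.bins)

    def chrom_bins(self, chrom: str) -> list[GenomicInterval]:
        return [b for b in self.bins if b.chrom == chrom]

    def to_bed(self) -> str:
        return "".join(f"{b.chrom}\t{b.start}\t{b.end}\n" for b in self.bins)


@dataclass(frozen=True)
class BoundaryWindowSpec:
    """Pericentromeric boundary window: offsets from the centromeric end.

    Defaults give the 3.0–3.5 Mb test window and the 2.5–5 Mb plotting range;
    with 10-kb bins on 20 chromosomes the window holds 20 x 50 = 1000 bins.
    """

    inner: int = 3_000_000
    outer: int = 3_500_000
    plot_range: tuple[int, int] = (2_500_000, 5_000_000)
    chromosomes: tuple[str, ...] = DEFAULT_BOUNDARY_CHROMOSOMES

    def __post_init__(self) -> None:
        if not (0 <= self.inner < self.outer):
            raise ValueError(f"need 0 <= inner < outer, got {self.inner}, {self.outer}")
        lo, hi = self.plot_range
        if not (lo <= self.inner and self.outer <= hi):
            raise ValueError("plot_range must contain [inner, outer)")
        if not self.chromosomes:
            raise ValueError("chromosomes must be non-empty")


def load_chrom_sizes(source: str | Path | Iterable[str]) -> GenomeLayout:
    """Read a UCSC-style two-column chrom.sizes file into a layout.

    ``source`` may be a path or an iterable of lines.  File order is
    preserved; duplicate names and non-positive lengths are rejected.
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    chroms: list[tuple[str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected 'name length', got {raw!r}")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-integer length {fields[1]!r}"
            ) from None
        if length <= 0:
            raise ValueError(f"line {lineno}: non-positive length for {name!r}")
        chroms.append((name, length))
    return GenomeLayout(tuple(chroms))


def mm10_layout() -> GenomeLayout:
    """The canonical mm10 chromosomes (chr1–chr19, chrX, chrY), shipped."""
    text = (
        resources.files("pchtools").joinpath("data/mm10.chrom.sizes").read_text()
    )
    return load_chrom_sizes(text.splitlines())


def tile_genome(
    layout: GenomeLayout, bin_width: int, keep_partial: bool = True
) -> BinGrid:
    """Tile every chromosome with ``bin_width`` bins starting at 0.

    With ``keep_partial`` the trailing sub-width bin is kept and flagged;
    otherwise it is dropped, leaving ``floor(length / bin_width)`` bins.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if not layout.chromosomes:
        raise ValueError("empty layout")
    bins: list[GenomicInterval] = []
    flags: list[bool] = []
    for name, length in layout.chromosomes:
        starts = np.arange(0, length, bin_width)
        for s in starts:
            e = min(int(s) + bin_width, length)
            partial = (e - s) < bin_width
            if partial and not keep_partial:
                continue
            bins.append(GenomicInterval(name, int(s), int(e)))
            flags.append(partial)
    return BinGrid(
        layout=layout,
        bin_width=bin_width,
        bins=bins,
        keep_partial=keep_partial,
        partial_flags=np.asarray(flags, dtype=bool),
    )


def boundary_bins(grid: BinGrid, spec: BoundaryWindowSpec) -> list[GenomicInterval]:
    """Bins fully contained in ``[inner, outer)`` on each selected chromosome.

    Chromosomes shorter than ``spec.outer`` contribute only their fully
    contained bins (a warning is logged).  With 10-kb bins, the default
    window and chr1–chr19 + chrX this yields the 1000 pericentromeric bins.
    """
    missing = [c for c in spec.chromosomes if c not in grid.layout]
    if missing:
        raise ValueError(f"chromosomes not in layout: {missing}")
    selected = set(spec.chromosomes)
    out: list[GenomicInterval] = []
    short: list[str] = []
    for b, partial in zip(grid.bins, grid.partial_flags):
        if b.chrom in selected and not partial:
            if b.start >= spec.inner and b.end <= spec.outer:
                out.append(b)
    for c in spec.chromosomes:
        if grid.layout.length_of(c) < spec.outer:
            short.append(c)
    if short:
        logger.warning(
            "chromosomes shorter than the outer window offset (%d): %s — "
            "only fully contained bins contribute",
            spec.outer,
            short,
        )
    return out


def sample_random_bins(
    grid: BinGrid,
    n: int,
    exclude: Sequence[GenomicInterval] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """Draw ``n`` distinct full-width bins uniformly, avoiding ``exclude``.

    Eligible bins are non-partial bins that overlap no excluded interval.
    A seed (or generator) makes the draw reproducible; bins are drawn
    without replacement.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    eligible: list[GenomicInterval] = []
    for b, partial in zip(grid.bins, grid.partial_flags):
        if partial:
            continue
        hit = False
        for s, e in excl_by_chrom.get(b.chrom, ()):
            if b.start < e and s < b.end:
                hit = True
                break
        if not hit:
            eligible.append(b)
    if len(eligible) < n:
        raise ValueError(
            f"requested {n} random bins but only {len(eligible)} eligible"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in idx]


def intervals_to_bed(
    intervals: Sequence[GenomicInterval], name: str | None = None
) -> str:
    """BED text for a set of intervals, optionally with a name column."""
    if name is None:
        return "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in intervals)
    return "".join(
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n" for iv in intervals
    )
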