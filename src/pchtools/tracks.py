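"""Coverage tracks: bedGraph I/O, CPM normalisation, input subtraction,
and mean signal over intervals — the quantification kernel.

A :class:`SignalTrack` is a sparse piecewise-constant function over a
genome: sorted non-overlapping segments with float values, with every
uncovered base implicitly 0.  The processing chain mirrors the standard
ChIP/ATAC track pipeline: raw per-bin counts -> counts-per-million (CPM)
-> per-base subtraction of the matched CPM-normalised input, after which
negative values are meaningful (signal below input).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeLayout, GenomicInterval, BinGrid

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
CPM = "cpm"
CPM_INPUT_SUBTRACTED = "cpm_input_subtracted"
_KINDS = (RAW_COUNTS, CPM, CPM_INPUT_SUBTRACTED)


@dataclass
class SignalTrack:
    """Piecewise-constant signal over a :class:`GenomeLayout`.

    ``data`` maps chromosome -> (starts, ends, values) sorted arrays with no
    overlaps.  ``total_units`` is the total mapped-read count, kept for raw
    count tracks so CPM scaling can be applied later.
    """

    layout: GenomeLayout
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    kind: str = RAW_COUNTS
    total_units: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        for chrom, (starts, ends, values) in self.data.items():
            if chrom not in self.layout:
                raise ValueError(f"track chromosome {chrom!r} not in layout")
            if len(starts) == 0:
                continue
            if not (np.all(starts[1:] >= ends[:-1])):
                raise ValueError(f"overlapping segments on {chrom}")
            if not (np.all(starts < ends)):
                raise ValueError(f"empty segment on {chrom}")
            if starts[0] < 0 or ends[-1] > self.layout.length_of(chrom):
                raise ValueError(f"segment outside chromosome {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite values on {chrom}")
            if self.kind == RAW_COUNTS and np.any(values < 0):
                raise ValueError("raw count values must be >= 0")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_segments(
        cls,
        layout: GenomeLayout,
        segments: Iterable[tuple[GenomicInterval, float]],
        kind: str = RAW_COUNTS,
        total_units: float | None = None,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, v in segments:
            layout.validate_interval(iv)
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(v)))
        data = {}
        for chrom, segs in by_chrom.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=np.float64)
            data[chrom] = (starts, ends, values)
        return cls(layout=layout, data=data, kind=kind, total_units=total_units)

    @classmethod
    def from_bin_values(
        cls,
        grid: BinGrid,
        values: np.ndarray,
        kind: str = RAW_COUNTS,
        total_units: float | None = None,
    ) -> "SignalTrack":
        """Fast path for one value per grid bin (bamCompare-style tracks)."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (len(grid.bins),):
            raise ValueError("values must have one entry per grid bin")
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        i = 0
        for chrom in grid.layout.names:
            n = sum(1 for b in grid.bins if b.chrom == chrom)
            if n == 0:
                continue
            chrom_bins = grid.bins[i : i + n]
            starts = np.array([b.start for b in chrom_bins], dtype=np.int64)
            ends = np.array([b.end for b in chrom_bins], dtype=np.int64)
            data[chrom] = (starts, ends, values[i : i + n].copy())
            i += n
        return cls(layout=grid.layout, data=data, kind=kind, total_units=total_units)

    # -- canonical form & equality ---------------------------------------

    def canonical(self) -> "SignalTrack":
        """Drop zero-valued segments and merge adjacent equal-valued ones."""
        data = {}
        for chrom, (starts, ends, values) in self.data.items():
            keep = values != 0.0
            s, e, v = starts[keep], ends[keep], values[keep]
            if len(s) == 0:
                continue
            merged_s, merged_e, merged_v = [s[0]], [e[0]], [v[0]]
            for i in range(1, len(s)):
                if s[i] == merged_e[-1] and v[i] == merged_v[-1]:
                    merged_e[-1] = e[i]
                else:
                    merged_s.append(s[i])
                    merged_e.append(e[i])
                    merged_v.append(v[i])
            data[chrom] = (
                np.asarray(merged_s, dtype=np.int64),
                np.asarray(merged_e, dtype=np.int64),
                np.asarray(merged_v, dtype=np.float64),
            )
        return SignalTrack(
            layout=self.layout, data=data, kind=self.kind,
            total_units=self.total_units,
        )

    def __eq__(self, other: object) -> bool:
        """Value equality: same signal as a function of genomic position.

        Compared on canonical form (zero segments dropped, equal-valued
        neighbours merged); the ``kind`` tag is not part of the value.
        """
        if not isinstance(other, SignalTrack):
            return NotImplemented
        a, b = self.canonical(), other.canonical()
        if a.layout != b.layout or set(a.data) != set(b.data):
            return False
        for chrom in a.data:
            for x, y in zip(a.data[chrom], b.data[chrom]):
                if not np.array_equal(x, y):
                    return False
        return True

    def dense(self, chrom: str) -> np.ndarray:
        """Per-base value array for a whole chromosome (test-scale only)."""
        arr = np.zeros(self.layout.length_of(chrom), dtype=np.float64)
        if chrom in self.data:
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                arr[s:e] = v
        return arr


# -- bedGraph I/O ---------------------------------------------------------


def read_bedgraph(
    source: str | Path | Iterable[str],
    layout: GenomeLayout,
    kind: str = CPM_INPUT_SUBTRACTED,
    total_units: float | None = None,
) -> SignalTrack:
    """Parse 4-column bedGraph text (0-based half-open) into a track.

    Overlapping segments are rejected; lines on chromosomes absent from the
    layout raise (bedGraph tracks are expected to match their genome).
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    segments: list[tuple[GenomicInterval, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
        try:
            value = float(fields[3])
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-numeric value {fields[3]!r}"
            ) from None
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        layout.validate_interval(iv)
        segments.append((iv, value))
    return SignalTrack.from_segments(
        layout, segments, kind=kind, total_units=total_units
    )


def write_bedgraph(track: SignalTrack, merge: bool = True) -> str:
    """Serialise a track to bedGraph text (zero segments dropped)."""
    t = track.canonical() if merge else track
    buf = io.StringIO()
    for chrom in t.layout.names:
        if chrom not in t.data:
            continue
        starts, ends, values = t.data[chrom]
        for s, e, v in zip(starts, ends, values):
            # shortest round-trip float repr; integral values written bare
            sv = repr(float(v))
            if sv.endswith(".0"):
                sv = sv[:-2]
            buf.write(f"{chrom}\t{s}\t{e}\t{sv}\n")
    return buf.getvalue()


def read_bigwig(path: str | Path, layout: GenomeLayout, kind: str = CPM) -> SignalTrack:
    """Optional bigWig reader (requires pyBigWig at runtime)."""
    try:
        import pyBigWig  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "bigWig support requires the optional pyBigWig dependency"
        ) from exc
    bw = pyBigWig.open(str(path))
    segments = []
    try:
        for chrom in layout.names:
            if chrom not in bw.chroms():
                continue
            for s, e, v in bw.intervals(chrom) or []:
                segments.append((GenomicInterval(chrom, s, e), v))
    finally:
        bw.close()
    return SignalTrack.from_segments(layout, segments, kind=kind)


# -- normalisation and subtraction ----------------------------------------


def cpm_normalize(
    track: SignalTrack, total_units: float | None = None
) -> SignalTrack:
    """Scale raw counts to counts-per-million: v -> v * 1e6 / total.

    ``total_units`` defaults to the track's recorded total mapped reads.
    """
    if total_units is None:
        total_units = track.total_units
    if total_units is None or total_units <= 0:
        raise ValueError(f"total_units must be > 0, got {total_units}")
    data = {
        chrom: (starts, ends, values * (1e6 / total_units))
        for chrom, (starts, ends, values) in track.data.items()
    }
    return SignalTrack(layout=track.layout, data=data, kind=CPM)


def _eval_at(
    chrom_data: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    points: np.ndarray,
) -> np.ndarray:
    """Track value at each point, 0 where uncovered."""
    out = np.zeros(len(points), dtype=np.float64)
    if chrom_data is None:
        return out
    starts, ends, values = chrom_data
    if len(starts) == 0:
        return out
    idx = np.searchsorted(starts, points, side="right") - 1
    valid = (idx >= 0) & (points < ends[np.clip(idx, 0, None)])
    out[valid] = values[idx[valid]]
    return out


def subtract_tracks(chip: SignalTrack, input_: SignalTrack) -> SignalTrack:
    """Per-base subtraction chip(b) − input(b) on the overlay refinement.

    Both tracks must be CPM-normalised on the same layout (the bamCompare
    ``--operation subtract --normalizeUsing CPM`` contract).  Uncovered
    bases count as 0; negative results are kept.
    """
    if chip.layout != input_.layout:
        raise ValueError("layout mismatch between chip and input tracks")
    if chip.kind != CPM or input_.kind != CPM:
        raise ValueError("subtract_tracks requires two CPM tracks")
    data = {}
    for chrom in set(chip.data) | set(input_.data):
        pieces = []
        for t in (chip, input_):
            if chrom in t.data:
                s, e, _ = t.data[chrom]
                pieces.extend((s, e))
        breaks = np.unique(np.concatenate(pieces))
        if len(breaks) < 2:
            continue
        seg_starts, seg_ends = breaks[:-1], breaks[1:]
        v = _eval_at(chip.data.get(chrom), seg_starts) - _eval_at(
            input_.data.get(chrom), seg_starts
        )
        data[chrom] = (seg_starts, seg_ends, v)
    return SignalTrack(
        layout=chip.layout, data=data, kind=CPM_INPUT_SUBTRACTED
    ).canonical()


# -- interval quantification ----------------------------------------------

BASE_WEIGHTED = "base_weighted"
OVERLAP_UNWEIGHTED = "overlap_unweighted"


def mean_over_interval(
    track: SignalTrack, interval: GenomicInterval, mode: str = BASE_WEIGHTED
) -> float:
    """Mean track signal over one interval.

    ``base_weighted`` (default): per-base average with uncovered bases
    contributing 0 — the value bamCompare-style full-genome tracks imply.
    ``overlap_unweighted``: plain mean of the values of segments touching
    the interval, NaN when none touch — the ``bedtools map -o mean``
    convention.  The two coincide when segments are full-genome fixed bins
    aligned with the query.
    """
    track.layout.validate_interval(interval)
    chrom_data = track.data.get(interval.chrom)
    if chrom_data is None:
        return 0.0 if mode == BASE_WEIGHTED else float("nan")
    starts, ends, values = chrom_data
    i0 = int(np.searchsorted(ends, interval.start, side="right"))
    i1 = int(np.searchsorted(starts, interval.end, side="left"))
    if mode == BASE_WEIGHTED:
        if i0 >= i1:
            return 0.0
        lo = np.maximum(starts[i0:i1], interval.start)
        hi = np.minimum(ends[i0:i1], interval.end)
        return float((values[i0:i1] * (hi - lo)).sum() / interval.length)
    if mode == OVERLAP_UNWEIGHTED:
        if i0 >= i1:
            return float("nan")
        return float(values[i0:i1].mean())
    raise ValueError(f"unknown mode {mode!r}")


def quantify(
    track: SignalTrack,
    intervals: Sequence[GenomicInterval],
    mode: str = BASE_WEIGHTED,
) -> np.ndarray:
    """Vectorised :func:`mean_over_interval` for many intervals.

    A single sweep per chromosome using prefix sums; order is preserved
    and the result equals the per-interval naive loop exactly.
    """
    out = np.empty(len(intervals), dtype=np.float64)
    if not intervals:
        return out
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(intervals):
        track.layout.validate_interval(iv)
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        qs = np.array([intervals[i].start for i in idxs], dtype=np.int64)
        qe = np.array([intervals[i].end for i in idxs], dtype=np.int64)
        chrom_data = track.data.get(chrom)
        if chrom_data is None or len(chrom_data[0]) == 0:
            fill = 0.0 if mode == BASE_WEIGHTED else float("nan")
            out[np.asarray(idxs)] = fill
            continue
        starts, ends, values = chrom_data
        i0 = np.searchsorted(ends, qs, side="right")
        i1 = np.searchsorted(starts, qe, side="left")
        if mode == BASE_WEIGHTED:
            weighted = values * (ends - starts)
            csum = np.concatenate(([0.0], np.cumsum(weighted)))
            total = csum[i1] - csum[i0]
            # trim the partially overlapping edge segments
            has = i1 > i0
            left = np.where(has, np.clip(i0, 0, len(starts) - 1), 0)
            right = np.where(has, np.clip(i1 - 1, 0, len(starts) - 1), 0)
            left_trim = np.clip(qs - starts[left], 0, None) * values[left]
            right_trim = np.clip(ends[right] - qe, 0, None) * values[right]
            # when one segment spans the query, both trims apply to it
            total = np.where(has, total - left_trim - right_trim, 0.0)
            out[np.asarray(idxs)] = total / (qe - qs)
        elif mode == OVERLAP_UNWEIGHTED:
            csum = np.concatenate(([0.0], np.cumsum(values)))
            n = (i1 - i0).astype(np.float64)
            with np.errstate(invalid="ignore"):
                means = np.where(n > 0, (csum[i1] - csum[i0]) / n, np.nan)
            out[np.asarray(idxs)] = means
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def quantify_table(
    tracks: dict[str, SignalTrack],
    intervals: Sequence[GenomicInterval],
    mode: str = BASE_WEIGHTED,
):
    """Interval-by-sample quantification as a pandas DataFrame."""
    import pandas as pd  # deferred: keep module import light

    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals]
    return pd.DataFrame(
        {name: quantify(t, intervals, mode=mode) for name, t in tracks.items()},
        index=index,
    )
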