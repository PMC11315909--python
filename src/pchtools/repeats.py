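"""Repeat annotation: TEtranscripts-style GTF, blacklist filter, hierarchy.

The TEtranscripts repeat annotation is a RepeatMasker-derived GTF in which
every feature carries ``gene_id`` (the repeat group, e.g. GSAT_MM),
``family_id`` and ``class_id`` attributes, organising repeats into three
levels: Class -> Family -> Repeat group.  Records overlapping a blacklist
region (ENCODE blacklist for real data) are discarded before any signal
quantification, mirroring standard ChIP/ATAC practice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeLayout, GenomicInterval

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat instance with its Class/Family/Group assignment."""

    interval: GenomicInterval
    strand: str
    group: str
    family: str
    class_name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (self.group and self.family and self.class_name):
            raise ValueError("group/family/class must be non-empty")


@dataclass
class RepeatHierarchy:
    """Class -> Family -> Repeat-group taxonomy.

    Each group belongs to exactly one (family, class) pair; inconsistent
    reassignment is an error.
    """

    group_to_family_class: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, group: str, family: str, class_name: str) -> None:
        existing = self.group_to_family_class.get(group)
        if existing is not None and existing != (family, class_name):
            raise ValueError(
                f"group {group!r} assigned to both {existing} and "
                f"{(family, class_name)}"
            )
        self.group_to_family_class[group] = (family, class_name)

    @property
    def classes(self) -> list[str]:
        return sorted({c for _, c in self.group_to_family_class.values()})

    def groups_in_class(self, class_name: str) -> list[str]:
        return sorted(
            g
            for g, (_, c) in self.group_to_family_class.items()
            if c == class_name
        )

    def family_of(self, group: str) -> str:
        return self.group_to_family_class[group][0]

    def class_of(self, group: str) -> str:
        return self.group_to_family_class[group][1]


def read_repeat_gtf(
    source: str | Path | Iterable[str], layout: GenomeLayout
) -> tuple[list[RepeatRecord], RepeatHierarchy]:
    """Parse a TEtranscripts-dialect GTF into records plus hierarchy.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open.  Records on chromosomes absent from ``layout`` (unplaced
    scaffolds, typically) are dropped with a logged count.
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    records: list[RepeatRecord] = []
    hierarchy = RepeatHierarchy()
    n_dropped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"line {lineno}: expected 9 GTF columns")
        chrom, _source, _feature, start1, end1, _score, strand, _frame, attrs = (
            fields[:9]
        )
        try:
            start1_i, end1_i = int(start1), int(end1)
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer coordinates") from None
        if start1_i > end1_i:
            raise ValueError(f"line {lineno}: start > end ({start1_i} > {end1_i})")
        attr = dict(_ATTR_RE.findall(attrs))
        for key in ("gene_id", "family_id", "class_id"):
            if key not in attr:
                raise ValueError(f"line {lineno}: missing attribute {key!r}")
        if chrom not in layout:
            n_dropped += 1
            continue
        interval = GenomicInterval(chrom, start1_i - 1, end1_i)
        layout.validate_interval(interval)
        group, family, class_name = (
            attr["gene_id"],
            attr["family_id"],
            attr["class_id"],
        )
        hierarchy.add(group, family, class_name)
        records.append(
            RepeatRecord(
                interval=interval,
                strand=strand if strand in ("+", "-") else ".",
                group=group,
                family=family,
                class_name=class_name,
            )
        )
    if n_dropped:
        logger.warning(
            "dropped %d repeat records on chromosomes absent from layout",
            n_dropped,
        )
    return records, hierarchy


def write_repeat_gtf(records: Sequence[RepeatRecord]) -> str:
    """Serialise records back to TEtranscripts-dialect GTF text."""
    out = []
    for r in records:
        attrs = (
            f'gene_id "{r.group}"; family_id "{r.family}"; '
            f'class_id "{r.class_name}";'
        )
        out.append(
            f"{r.interval.chrom}\tpchtools\texon\t{r.interval.start + 1}\t"
            f"{r.interval.end}\t.\t{r.strand}\t.\t{attrs}\n"
        )
    return "".join(out)


def read_bed(
    source: str | Path | Iterable[str], layout: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open); extra columns ignored."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    else:
        lines = source
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: expected >= 3 BED columns")
        iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        if layout is not None:
            layout.validate_interval(iv)
        out.append(iv)
    return out


def _merged_by_chrom(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def filter_blacklist(
    records: Sequence[RepeatRecord],
    blacklist: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[RepeatRecord]:
    """Drop records overlapping any blacklist interval by >= ``min_overlap`` bp.

    The default threshold of one base pair is the most conservative reading
    of "overlap"; order is preserved and the removed count logged.
    Idempotent: filtering an already filtered set is the identity.
    """
    if not blacklist:
        return list(records)
    merged = _merged_by_chrom(blacklist)
    kept: list[RepeatRecord] = []
    n_removed = 0
    for rec in records:
        entry = merged.get(rec.interval.chrom)
        overlap = 0
        if entry is not None:
            starts, ends = entry
            # merged intervals are disjoint+sorted: sum clipped overlaps
            lo = np.maximum(starts, rec.interval.start)
            hi = np.minimum(ends, rec.interval.end)
            overlap = int(np.clip(hi - lo, 0, None).sum())
        if overlap >= min_overlap:
            n_removed += 1
        else:
            kept.append(rec)
    if n_removed:
        logger.info("blacklist filter removed %d repeat records", n_removed)
    return kept


def groups_by_class(
    records: Sequence[RepeatRecord],
    hierarchy: RepeatHierarchy,
    class_name: str,
) -> dict[str, list[GenomicInterval]]:
    """Bucket a class's records into group -> interval lists.

    Every record of the class lands in exactly one bucket, so bucket sizes
    sum to the class record count.  Groups of the class with no surviving
    records appear as empty buckets.
    """
    if class_name not in hierarchy.classes:
        raise ValueError(
            f"unknown class {class_name!r}; available: {hierarchy.classes}"
        )
    buckets: dict[str, list[GenomicInterval]] = {
        g: [] for g in hierarchy.groups_in_class(class_name)
    }
    for rec in records:
        if rec.class_name == class_name:
            buckets[rec.group].append(rec.interval)
    return buckets


def records_to_bed6(records: Sequence[RepeatRecord]) -> str:
    """BED6 export with name ``class/family/group``."""
    out = []
    for r in records:
        name = f"{r.class_name}/{r.family}/{r.group}"
        out.append(
            f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
            f"{name}\t0\t{r.strand}\n"
        )
    return "".join(out)
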