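"""Genomic interval primitives and peak-set operations.

Coordinates are 0-based half-open (BED convention) throughout. The
"center" of an interval is ``floor((start + end) / 2)``, which makes
even-width windows deterministic. Two intervals overlap iff they share
at least one base pair on the same chromosome.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "PeakSetComparison",
    "parse_bed",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_tss_bed",
    "center_window",
    "remove_overlapping",
    "sample_random_regions",
    "classify_tss_proximity",
    "assign_peaks_to_genes",
    "compare_peak_sets",
]

_STRANDS = (None, "+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSSRecord:
    """An annotated transcription start site."""

    chrom: str
    position: int
    gene: str
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative TSS position for {self.gene}")


class PeakSetComparison(NamedTuple):
    """Partition of two peak sets by mutual (>=1 bp) overlap."""

    shared_a: list
    shared_b: list
    a_only: list
    b_only: list


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_bed(lines: Iterable[str]) -> list[GenomicInterval]:
    """Parse BED3/BED4/BED6 text into intervals, order preserved.

    Comment (``#``), ``track`` and ``browser`` lines are skipped. A
    ``.`` placeholder in the name column maps to ``None``. Malformed
    lines raise ``ValueError`` naming the (1-based) line number.
    """
    out: list[GenomicInterval] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"fewer than 3 columns at line {lineno}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"non-integer coordinates at line {lineno}") from None
        if start >= end:
            raise ValueError(f"start >= end at line {lineno}")
        if start < 0:
            raise ValueError(f"negative start at line {lineno}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        strand = fields[5] if len(fields) > 5 else None
        out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return out


def read_bed(path) -> list[GenomicInterval]:
    with _open_text(path) as fh:
        return parse_bed(fh)


def write_bed(intervals: Sequence[GenomicInterval], path_or_handle) -> None:
    """Write intervals as BED; column count adapts to populated fields."""

    def _emit(fh):
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand is not None:
                cols += [iv.name if iv.name is not None else ".", ".", iv.strand]
            elif iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _emit(fh)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column (name, length) TSV into an ordered mapping."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"expected two columns at line {lineno}")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"non-positive length for {name} at line {lineno}")
            if name in sizes:
                raise ValueError(f"duplicate chromosome {name} at line {lineno}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_tss_bed(path) -> list[TSSRecord]:
    """Read TSS annotations from BED6 (gene symbol in column 4).

    The TSS position is the interval start for ``+``/unstranded records
    and ``end - 1`` for ``-`` records.
    """
    records = []
    for iv in read_bed(path):
        pos = iv.start if iv.strand != "-" else iv.end - 1
        records.append(TSSRecord(iv.chrom, pos, iv.name or f"{iv.chrom}:{pos}", iv.strand))
    return records


# ---------------------------------------------------------------------------
# Window arithmetic
# ---------------------------------------------------------------------------

def center_window(
    interval: GenomicInterval,
    half_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Return ``[c - half_width, c + half_width)`` around the interval center.

    Clamped to ``[0, chrom_length)`` when a sizes table is supplied, so
    windows at chromosome edges are truncated rather than discarded.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    c = interval.center
    start = max(0, c - half_width)
    end = c + half_width
    if chrom_sizes is not None:
        length = chrom_sizes[interval.chrom]
        end = min(end, length)
    return replace(interval, start=start, end=end)


# ---------------------------------------------------------------------------
# Overlap algebra
# ---------------------------------------------------------------------------

def _overlap_index(intervals: Sequence[GenomicInterval]):
    """Per-chromosome (sorted starts, running-max ends) for overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    index = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([e for _, e in spans], dtype=np.int64))
        index[chrom] = (starts, ends)
    return index


def _overlaps_any(index, iv: GenomicInterval) -> bool:
    entry = index.get(iv.chrom)
    if entry is None:
        return False
    starts, cummax_ends = entry
    i = int(np.searchsorted(starts, iv.end, side="left"))
    return i > 0 and cummax_ends[i - 1] > iv.start


def remove_overlapping(
    loci: Sequence[GenomicInterval],
    exclusions: Sequence[GenomicInterval],
    also_remove_mutual: bool = False,
) -> list[GenomicInterval]:
    """Drop loci overlapping any exclusion; optionally also drop every
    locus that overlaps another locus (both members of a mutually
    overlapping pair are removed)."""
    mutual_flag = [False] * len(loci)
    if also_remove_mutual:
        order: dict[str, list[int]] = {}
        for i, iv in enumerate(loci):
            order.setdefault(iv.chrom, []).append(i)
        for idxs in order.values():
            idxs.sort(key=lambda i: (loci[i].start, loci[i].end))
            running_max_end = -1
            for pos, i in enumerate(idxs):
                iv = loci[i]
                if pos > 0 and iv.start < running_max_end:
                    mutual_flag[i] = True
                if pos + 1 < len(idxs) and loci[idxs[pos + 1]].start < iv.end:
                    mutual_flag[i] = True
                running_max_end = max(running_max_end, iv.end)
    excl_index = _overlap_index(exclusions)
    return [
        iv
        for i, iv in enumerate(loci)
        if not mutual_flag[i] and not _overlaps_any(excl_index, iv)
    ]


def compare_peak_sets(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> PeakSetComparison:
    """Partition two peak sets into shared and set-exclusive peaks.

    A peak is "shared" iff it overlaps (>=1 bp) at least one peak of the
    other set; multi-overlaps count once. Mirrors a Venn comparison of
    two peak calls (e.g. control vs knockdown accessibility peaks).
    """
    index_a = _overlap_index(set_a)
    index_b = _overlap_index(set_b)
    shared_a = [iv for iv in set_a if _overlaps_any(index_b, iv)]
    a_only = [iv for iv in set_a if not _overlaps_any(index_b, iv)]
    shared_b = [iv for iv in set_b if _overlaps_any(index_a, iv)]
    b_only = [iv for iv in set_b if not _overlaps_any(index_a, iv)]
    return PeakSetComparison(shared_a, shared_b, a_only, b_only)


# ---------------------------------------------------------------------------
# Random background sampling
# ---------------------------------------------------------------------------

def sample_random_regions(
    chrom_sizes: Mapping[str, int],
    n: int,
    width: int,
    seed: int,
) -> list[GenomicInterval]:
    """Sample ``n`` random regions of exactly ``width`` bp.

    Chromosomes are chosen with probability proportional to their
    length (among chromosomes long enough to hold a window) and the
    start is uniform on the valid range. Fully reproducible from
    ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if width <= 0:
        raise ValueError("width must be positive")
    eligible = [(name, length) for name, length in chrom_sizes.items() if length >= width]
    if not eligible:
        raise ValueError(f"width {width} exceeds every chromosome length")
    rng = np.random.default_rng(seed)
    names = [name for name, _ in eligible]
    lengths = np.array([length for _, length in eligible], dtype=np.float64)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=n, p=probs)
    highs = lengths.astype(np.int64)[chrom_idx] - width + 1
    starts = rng.integers(0, highs)
    return [
        GenomicInterval(names[ci], int(s), int(s) + width, name=f"random_{i}")
        for i, (ci, s) in enumerate(zip(chrom_idx, starts))
    ]


# ---------------------------------------------------------------------------
# TSS proximity and gene assignment
# ---------------------------------------------------------------------------

def _tss_index(tss_records: Sequence[TSSRecord]):
    by_chrom: dict[str, list[TSSRecord]] = {}
    for rec in tss_records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    index = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.position, r.gene))
        index[chrom] = (np.array([r.position for r in recs], dtype=np.int64), recs)
    return index


def classify_tss_proximity(
    peaks: Sequence[GenomicInterval],
    tss_records: Sequence[TSSRecord],
    threshold: int = 1000,
) -> list[str]:
    """Label each peak ``"TSS"`` when its center lies within ``threshold``
    bp of the nearest annotated TSS, else ``"non-TSS"``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not tss_records:
        warnings.warn("no TSS records supplied; labelling every peak non-TSS")
        return ["non-TSS"] * len(peaks)
    index = _tss_index(tss_records)
    labels = []
    for peak in peaks:
        entry = index.get(peak.chrom)
        if entry is None:
            labels.append("non-TSS")
            continue
        positions, _ = entry
        c = peak.center
        i = int(np.searchsorted(positions, c))
        dist = min(
            abs(c - positions[i - 1]) if i > 0 else np.inf,
            abs(positions[i] - c) if i < len(positions) else np.inf,
        )
        labels.append("TSS" if dist <= threshold else "non-TSS")
    return labels


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    tss_records: Sequence[TSSRecord],
    max_dist: int = 100_000,
) -> list[tuple[GenomicInterval, str | None]]:
    """Assign each peak the gene with the nearest TSS within ``max_dist``.

    Ties are broken deterministically: smaller TSS coordinate first,
    then lexicographically smaller gene name.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    index = _tss_index(tss_records)
    out: list[tuple[GenomicInterval, str | None]] = []
    for peak in peaks:
        entry = index.get(peak.chrom)
        if entry is None:
            out.append((peak, None))
            continue
        positions, recs = entry
        c = peak.center
        i = int(np.searchsorted(positions, c))
        candidates: list[tuple[int, int, str]] = []  # (dist, position, gene)
        if i > 0:
            left_pos = positions[i - 1]
            j = int(np.searchsorted(positions, left_pos, side="left"))
            candidates.append((abs(c - left_pos), int(left_pos), recs[j].gene))
        if i < len(positions):
            candidates.append((abs(positions[i] - c), int(positions[i]), recs[i].gene))
        if not candidates:
            out.append((peak, None))
            continue
        dist, _, gene = min(candidates)
        out.append((peak, gene if dist <= max_dist else None))
    return out
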