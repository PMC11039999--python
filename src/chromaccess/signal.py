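"""Depth normalization, windowed counting, anchor-centered signal
matrices, metaplots, reference (time-0) ratio normalization and
bedGraph export.

Events are point positions (fragment midpoints or nucleosome dyads)
held per chromosome as sorted integer arrays; every aggregation below
counts points in half-open windows.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragments import DyadPosition, FragmentRecord
from .intervals import GenomicInterval

__all__ = [
    "PositionEvents",
    "SignalMatrix",
    "scale_factor",
    "count_in_window",
    "count_overlapping_fragments",
    "build_signal_matrix",
    "metaplot",
    "normalize_to_reference",
    "write_bedgraph",
    "read_bedgraph",
]


class PositionEvents:
    """Point events indexed per chromosome as sorted position arrays.

    Positions keep multiplicity: two fragments with the same midpoint
    contribute two entries.
    """

    def __init__(self, positions: Mapping[str, np.ndarray] | None = None):
        self.positions: dict[str, np.ndarray] = {}
        if positions:
            for chrom, arr in positions.items():
                arr = np.sort(np.asarray(arr, dtype=np.int64))
                self.positions[chrom] = arr

    @classmethod
    def from_fragments(cls, fragments: Iterable[FragmentRecord]) -> "PositionEvents":
        """Reduce fragments to their midpoints (the default counting mode)."""
        by_chrom: dict[str, list[int]] = {}
        for frag in fragments:
            by_chrom.setdefault(frag.chrom, []).append(frag.midpoint)
        return cls({c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()})

    @classmethod
    def from_dyads(cls, dyad_list: Iterable[DyadPosition]) -> "PositionEvents":
        by_chrom: dict[str, list[int]] = {}
        for d in dyad_list:
            by_chrom.setdefault(d.chrom, []).append(d.pos)
        return cls({c: np.array(p, dtype=np.int64) for c, p in by_chrom.items()})

    @property
    def total(self) -> int:
        return int(sum(arr.size for arr in self.positions.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr, start, side="left")
        hi = np.searchsorted(arr, end, side="left")
        return int(hi - lo)

    def chroms(self) -> list[str]:
        return list(self.positions)


@dataclass
class SignalMatrix:
    """Anchors x bins matrix underlying metaplots and heatmaps."""

    anchors: list[GenomicInterval]
    flank: int
    bin_size: int
    values: np.ndarray
    units: str = "raw_count"  # raw_count | normalized_count | log2_ratio
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected_cols = 2 * self.flank // self.bin_size
        if self.values.ndim != 2 or self.values.shape != (
            len(self.anchors),
            expected_cols,
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.anchors)} anchors x {expected_cols} bins"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the anchor center (bp)."""
        return -self.flank + np.arange(self.n_bins) * self.bin_size

    def to_dataframe(self) -> pd.DataFrame:
        labels = [
            a.name if a.name else f"{a.chrom}:{a.start}-{a.end}" for a in self.anchors
        ]
        return pd.DataFrame(self.values, index=labels, columns=self.bin_offsets())


def scale_factor(total_fragments: int, target: int = 10_000_000) -> float:
    """Library-size scaling: counts x ``target / total_fragments`` puts
    libraries of different depth on a common scale."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    return target / total_fragments


def count_in_window(events: PositionEvents, interval: GenomicInterval) -> int:
    """Number of event positions ``p`` with ``start <= p < end``."""
    return events.count_in(interval.chrom, interval.start, interval.end)


def count_overlapping_fragments(
    fragments: Iterable[FragmentRecord], interval: GenomicInterval
) -> int:
    """Any-overlap counting mode: fragments sharing >=1 bp with the window."""
    return sum(
        1
        for f in fragments
        if f.chrom == interval.chrom and f.start < interval.end and interval.start < f.end
    )


def build_signal_matrix(
    events: PositionEvents,
    anchors: Sequence[GenomicInterval],
    flank: int = 1000,
    bin_size: int = 10,
    scale: float = 1.0,
    units: str | None = None,
) -> SignalMatrix:
    """Count events in ``bin_size`` bins across ``[center - flank,
    center + flank)`` of every anchor.

    Entry ``(i, j)`` is the number of events in
    ``[c_i - flank + j*bin, c_i - flank + (j+1)*bin)`` times ``scale``.
    Anchors on chromosomes absent from the events give zero rows (with
    a warning).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_bins), dtype=float)
    missing: set[str] = set()
    for i, anchor in enumerate(anchors):
        arr = events.positions.get(anchor.chrom)
        if arr is None:
            missing.add(anchor.chrom)
            continue
        c = anchor.center
        lo = np.searchsorted(arr, c - flank, side="left")
        hi = np.searchsorted(arr, c + flank, side="left")
        if hi > lo:
            bins = (arr[lo:hi] - (c - flank)) // bin_size
            values[i] = np.bincount(bins, minlength=n_bins)
    if missing:
        warnings.warn(
            f"anchors on chromosomes absent from events: {sorted(missing)}; "
            "rows left at zero"
        )
    if scale != 1.0:
        values *= scale
    if units is None:
        units = "raw_count" if scale == 1.0 else "normalized_count"
    return SignalMatrix(list(anchors), flank, bin_size, values, units=units, scale_factor=scale)


def metaplot(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin column means (average signal per anchor)."""
    if len(matrix.anchors) == 0:
        raise ValueError("metaplot of an empty matrix")
    return matrix.values.mean(axis=0)


def normalize_to_reference(
    matrix: SignalMatrix, reference: SignalMatrix, pseudocount: float = 1.0
) -> SignalMatrix:
    """Entry-wise ``log2((a + pseudocount) / (r + pseudocount))``.

    Both matrices must share anchors, flank and bin size, and should be
    depth-scaled to the same target before the ratio is taken (the
    time-0 normalization of dyad heatmaps).
    """
    if (
        matrix.values.shape != reference.values.shape
        or matrix.flank != reference.flank
        or matrix.bin_size != reference.bin_size
    ):
        raise ValueError("matrix and reference shapes do not match")
    values = np.log2(
        (matrix.values + pseudocount) / (reference.values + pseudocount)
    )
    return SignalMatrix(
        matrix.anchors,
        matrix.flank,
        matrix.bin_size,
        values,
        units="log2_ratio",
        scale_factor=matrix.scale_factor,
    )


def write_bedgraph(events: PositionEvents, scale: float, path) -> None:
    """Write per-position event counts x ``scale`` as a sorted,
    run-length-merged 4-column bedGraph."""

    def _fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:g}"

    with open(path, "w") as fh:
        for chrom in sorted(events.positions):
            pos, counts = np.unique(events.positions[chrom], return_counts=True)
            if pos.size == 0:
                continue
            vals = counts * scale
            # break runs where positions are non-adjacent or values differ
            breaks = np.flatnonzero(
                (np.diff(pos) != 1) | (np.diff(vals) != 0)
            )
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [pos.size - 1]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{pos[s]}\t{pos[e] + 1}\t{_fmt(vals[s])}\n"
                )


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Minimal bedGraph reader (round-trip checks and track reuse)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out
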