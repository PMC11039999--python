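"""Paired-end fragment handling: BEDPE/fragment-BED input, length
filtering, assay-specific deduplication and dyad (midpoint) extraction.

A "fragment" is the full DNA molecule inferred from a read pair; the
two mates are collapsed to a single span. For MNase-protected
mono-nucleosomal fragments the fragment midpoint estimates the
nucleosome dyad.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FragmentRecord",
    "DyadPosition",
    "AssayPolicy",
    "ASSAY_POLICIES",
    "read_fragments",
    "write_fragment_bed",
    "filter_mononucleosomal",
    "deduplicate",
    "fragment_midpoint",
    "dyads",
    "apply_policy",
]


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced DNA fragment on ``chrom`` spanning ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has length < 1"
            )
        if self.start < 0:
            raise ValueError("negative fragment start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class DyadPosition:
    """Estimated nucleosome dyad: the midpoint of a protected fragment."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class AssayPolicy:
    """Per-assay processing rules.

    ATAC and ChIP libraries keep only non-duplicate fragments; capture
    MNase retains duplicates (deep targeted coverage makes identical
    fragments expected rather than artifactual). Mono-nucleosomal
    length bounds are closed: ``length_min <= length <= length_max``.
    """

    assay: str
    dedup: bool
    length_min: int | None = None
    length_max: int | None = None

    def __post_init__(self) -> None:
        if (
            self.length_min is not None
            and self.length_max is not None
            and self.length_min > self.length_max
        ):
            raise ValueError("length_min > length_max")


ASSAY_POLICIES: dict[str, AssayPolicy] = {
    "atac": AssayPolicy("atac", dedup=True),
    "chip": AssayPolicy("chip", dedup=True),
    "mnase": AssayPolicy("mnase", dedup=True, length_min=120, length_max=170),
    "capture_mnase": AssayPolicy(
        "capture_mnase", dedup=False, length_min=120, length_max=170
    ),
}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fragments(
    lines: Iterable[str], format: str = "bedpe"
) -> tuple[list[FragmentRecord], int]:
    """Parse fragment records from text lines.

    ``bedpe``: both mates on one line (10-column BEDPE, first six used);
    the pair is converted to a single fragment spanning
    ``min(starts)..max(ends)``. Inter-chromosomal pairs are dropped and
    counted. ``fragment_bed``: BED3+ of already-merged fragments.

    Returns ``(fragments, n_interchromosomal_dropped)``.
    """
    if format not in ("bedpe", "fragment_bed"):
        raise ValueError(f"unknown fragment format {format!r}")
    fragments: list[FragmentRecord] = []
    dropped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        try:
            if format == "bedpe":
                if len(fields) < 6:
                    raise ValueError("fewer than 6 columns")
                c1, s1, e1, c2, s2, e2 = fields[:6]
                if c1 != c2:
                    dropped += 1
                    continue
                start = min(int(s1), int(s2))
                end = max(int(e1), int(e2))
                fragments.append(FragmentRecord(c1, start, end))
            else:
                if len(fields) < 3:
                    raise ValueError("fewer than 3 columns")
                fragments.append(
                    FragmentRecord(fields[0], int(fields[1]), int(fields[2]))
                )
        except ValueError as exc:
            raise ValueError(f"malformed {format} line {lineno}: {exc}") from None
    return fragments, dropped


def read_fragments(path, format: str = "bedpe") -> tuple[list[FragmentRecord], int]:
    """Read a (possibly gzipped) BEDPE or fragment-BED file."""
    with _open_text(path) as fh:
        return parse_fragments(fh, format=format)


def write_fragment_bed(fragments: Sequence[FragmentRecord], path) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")


def filter_mononucleosomal(
    fragments: Iterable[FragmentRecord], lo: int = 120, hi: int = 170
) -> list[FragmentRecord]:
    """Retain fragments with ``lo <= length <= hi`` (closed bounds)."""
    if lo > hi:
        raise ValueError("lo > hi")
    return [f for f in fragments if lo <= f.length <= hi]


def deduplicate(
    fragments: Iterable[FragmentRecord], policy: AssayPolicy
) -> list[FragmentRecord]:
    """Keep one fragment per identical ``(chrom, start, end)`` when the
    assay policy requires deduplication; identity otherwise."""
    if not policy.dedup:
        return list(fragments)
    seen: set[tuple[str, int, int]] = set()
    out = []
    for frag in fragments:
        key = (frag.chrom, frag.start, frag.end)
        if key not in seen:
            seen.add(key)
            out.append(frag)
    return out


def apply_policy(
    fragments: Iterable[FragmentRecord], policy: AssayPolicy
) -> list[FragmentRecord]:
    """Length-filter then deduplicate according to an assay policy."""
    frags = list(fragments)
    if policy.length_min is not None or policy.length_max is not None:
        lo = policy.length_min if policy.length_min is not None else 1
        hi = policy.length_max if policy.length_max is not None else max(
            (f.length for f in frags), default=1
        )
        frags = filter_mononucleosomal(frags, lo=lo, hi=hi)
    return deduplicate(frags, policy)


def fragment_midpoint(fragment: FragmentRecord) -> DyadPosition:
    """Fragment midpoint (``floor`` of the half-open span center); for
    mono-nucleosomal fragments this is the dyad estimate."""
    return DyadPosition(fragment.chrom, fragment.midpoint)


def dyads(fragments: Iterable[FragmentRecord]) -> list[DyadPosition]:
    return [fragment_midpoint(f) for f in fragments]
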