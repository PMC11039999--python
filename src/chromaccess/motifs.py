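"""IUPAC consensus motif scanning, peak-excluded motif-sampling loci,
enrichment against random genomic background, and the analytic
motif-density expectation.

Degenerate consensus patterns (e.g. WGATAR for GATA factors, TGASTCA
for AP-1) are matched exactly per position; an ``N`` in the genome
never matches any code, so assembly gaps are ignored.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, center_window, remove_overlapping
from .signal import PositionEvents, count_in_window

__all__ = [
    "IUPAC_CODES",
    "MotifSite",
    "EnrichmentResult",
    "reverse_complement_pattern",
    "reverse_complement",
    "scan_motif",
    "build_sampling_loci",
    "sampling_enrichment",
    "expected_motif_spacing",
    "write_motif_bed",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

_BASE_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class MotifSite:
    """One consensus-motif occurrence; ``matched`` is the motif-strand
    sequence (the reverse complement of the genomic substring for
    ``-`` sites)."""

    chrom: str
    start: int
    end: int
    strand: str
    matched: str


@dataclass(frozen=True)
class EnrichmentResult:
    """Mann-Whitney comparison of per-locus signal vs random background."""

    u_statistic: float
    p_value: float
    n_loci: int
    n_background: int
    median_loci: float
    median_background: float
    median_ratio: float
    degenerate: bool
    loci_counts: np.ndarray
    background_counts: np.ndarray

    def summary(self) -> dict:
        return {
            "U": self.u_statistic,
            "p": self.p_value,
            "n_loci": self.n_loci,
            "n_background": self.n_background,
            "median_loci": self.median_loci,
            "median_background": self.median_background,
            "median_ratio": self.median_ratio,
            "degenerate": self.degenerate,
        }


def _validate_pattern(pattern: str) -> str:
    if not pattern:
        raise ValueError("empty motif pattern")
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {pattern!r}")
    return pattern


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (W<->W, R<->Y, ...)."""
    pattern = _validate_pattern(pattern)
    return "".join(_COMPLEMENT[c] for c in reversed(pattern))


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_BASE_COMPLEMENT)[::-1]


def _pattern_regex(pattern: str) -> re.Pattern:
    # character classes of concrete bases only: genomic N never matches
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan_motif(
    sequence: str,
    pattern: str,
    both_strands: bool = True,
    collapse_palindromes: bool = True,
    chrom: str = "seq",
) -> list[MotifSite]:
    """All occurrences of an IUPAC consensus in ``sequence``.

    Forward-strand matches are reported on ``+``; positions where the
    reverse complement of the pattern matches are reported on ``-``.
    When one position matches on both strands and
    ``collapse_palindromes`` is set, a single ``+`` site is reported
    (avoids double counting palindromic consensi such as TGASTCA).
    Overlapping occurrences are all reported.
    """
    pattern = _validate_pattern(pattern)
    sequence = sequence.upper()
    fwd_positions = {
        m.start(): m.group(1) for m in _pattern_regex(pattern).finditer(sequence)
    }
    sites: list[MotifSite] = []
    L = len(pattern)
    if not both_strands:
        return [
            MotifSite(chrom, p, p + L, "+", s) for p, s in sorted(fwd_positions.items())
        ]
    rc_pattern = reverse_complement_pattern(pattern)
    rev_positions = {
        m.start(): m.group(1) for m in _pattern_regex(rc_pattern).finditer(sequence)
    }
    for p in sorted(set(fwd_positions) | set(rev_positions)):
        on_fwd = p in fwd_positions
        on_rev = p in rev_positions
        if on_fwd:
            sites.append(MotifSite(chrom, p, p + L, "+", fwd_positions[p]))
        if on_rev and not (on_fwd and collapse_palindromes):
            sites.append(
                MotifSite(chrom, p, p + L, "-", reverse_complement(rev_positions[p]))
            )
    return sites


def build_sampling_loci(
    motif_sites: Sequence[MotifSite],
    chip_peaks: Sequence[GenomicInterval],
    width: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Motif-sampling loci: every consensus site extended to ``width``
    bp, then loci overlapping any observed ChIP peak — or another
    extended locus — are removed.

    What remains are isolated consensus instances outside called
    binding peaks, where aggregate ChIP signal above random background
    reveals sub-peak-threshold motif sampling.
    """
    loci = [
        center_window(
            GenomicInterval(s.chrom, s.start, s.end, name=s.matched, strand=s.strand),
            width // 2,
            chrom_sizes,
        )
        for s in motif_sites
    ]
    return remove_overlapping(loci, chip_peaks, also_remove_mutual=True)


def sampling_enrichment(
    events: PositionEvents,
    loci: Sequence[GenomicInterval],
    background_loci: Sequence[GenomicInterval],
    scale: float = 1.0,
) -> EnrichmentResult:
    """Compare normalized per-locus event counts at motif loci vs random
    background with a two-sided Mann-Whitney test.

    The U statistic uses midranks for ties. The p-value is exact
    (full permutation distribution) when ``n1*n2 <= 10000`` and there
    are no ties, otherwise the normal approximation with tie and
    continuity correction. When every count in both groups is identical
    the comparison is degenerate and ``p = 1`` is reported.
    """
    if not loci or not background_loci:
        raise ValueError("loci and background_loci must both be non-empty")
    x = np.array([count_in_window(events, iv) for iv in loci], dtype=float) * scale
    y = (
        np.array([count_in_window(events, iv) for iv in background_loci], dtype=float)
        * scale
    )
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return EnrichmentResult(
            u_statistic=n1 * n2 / 2.0,
            p_value=1.0,
            n_loci=n1,
            n_background=n2,
            median_loci=float(np.median(x)),
            median_background=float(np.median(y)),
            median_ratio=_safe_ratio(np.median(x), np.median(y)),
            degenerate=True,
            loci_counts=x,
            background_counts=y,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (n1 * n2 <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return EnrichmentResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_loci=n1,
        n_background=n2,
        median_loci=float(np.median(x)),
        median_background=float(np.median(y)),
        median_ratio=_safe_ratio(np.median(x), np.median(y)),
        degenerate=False,
        loci_counts=x,
        background_counts=y,
    )


def _safe_ratio(a: float, b: float) -> float:
    if b == 0:
        return math.nan if a == 0 else math.inf
    return float(a / b)


def expected_motif_spacing(
    pattern: str,
    base_composition: Mapping[str, float] | None = None,
    both_strands: bool = True,
) -> float:
    """Expected bp between consensus matches on i.i.d. sequence.

    The per-position match probability sums the forward-pattern and
    reverse-complement-pattern probabilities and subtracts the
    probability that one position matches both strands at once (which
    collapses self-reverse-complementary patterns like TGASTCA to a
    single event, matching the scanner's palindrome collapsing).
    For WGATAR under uniform bases this gives 4096/8 = 512 bp — the
    "roughly one site every 500 bp" density expected of a degenerate
    hexamer.
    """
    pattern = _validate_pattern(pattern)
    if base_composition is None:
        base_composition = {b: 0.25 for b in "ACGT"}

    def _prob(pat: str) -> float:
        p = 1.0
        for c in pat:
            p *= sum(base_composition[b] for b in IUPAC_CODES[c])
        return p

    p_fwd = _prob(pattern)
    if both_strands:
        rc = reverse_complement_pattern(pattern)
        p_rev = _prob(rc)
        p_both = 1.0
        for cf, cr in zip(pattern, rc):
            allowed = set(IUPAC_CODES[cf]) & set(IUPAC_CODES[cr])
            p_both *= sum(base_composition[b] for b in allowed)
        p = p_fwd + p_rev - p_both
    else:
        p = p_fwd
    if p <= 0:
        raise ValueError(f"pattern {pattern!r} has zero match probability")
    return 1.0 / p


def write_motif_bed(sites: Sequence[MotifSite], path) -> None:
    """BED6 with the matched sequence in the name column."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.matched}\t.\t{s.strand}\n")
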