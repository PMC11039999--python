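"""Independent brute-force oracles used to validate the optimized
implementations. These deliberately share no code with the package:
per-position loops and exhaustive enumeration only."""
from __future__ import annotations

import numpy as np

from chromaccess.motifs import IUPAC_CODES

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_scan(seq: str, pattern: str, both_strands: bool = True,
               collapse: bool = True):
    """Per-position IUPAC match check; returns (start, strand) tuples."""
    seq = seq.upper()
    pattern = pattern.upper()
    L = len(pattern)
    rc_seq_pattern_hits = []
    out = []
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        fwd = all(b in IUPAC_CODES[c] for b, c in zip(window, pattern))
        rev = False
        if both_strands:
            rc_window = "".join(_COMP[b] for b in reversed(window))
            rev = all(b in IUPAC_CODES[c] for b, c in zip(rc_window, pattern))
        if fwd:
            out.append((i, "+"))
        if rev and not (fwd and collapse):
            out.append((i, "-"))
    return out


def naive_signal_matrix(positions_by_chrom, anchors, flank, bin_size):
    """O(anchors x positions) per-event recount."""
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(anchors), n_bins))
    for i, anchor in enumerate(anchors):
        c = (anchor.start + anchor.end) // 2
        for pos in positions_by_chrom.get(anchor.chrom, []):
            offset = pos - (c - flank)
            if 0 <= offset < 2 * flank:
                values[i, offset // bin_size] += 1
    return values


def brute_force_u(x, y):
    """Mann-Whitney U for the first group by exhaustive pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def naive_remove_overlapping(loci, exclusions, also_remove_mutual):
    """Quadratic pairwise overlap filter."""

    def ov(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    kept = []
    for i, locus in enumerate(loci):
        if any(ov(locus, e) for e in exclusions):
            continue
        if also_remove_mutual and any(
            ov(locus, other) for j, other in enumerate(loci) if j != i
        ):
            continue
        kept.append(locus)
    return kept
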