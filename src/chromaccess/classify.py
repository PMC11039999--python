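"""Three-class accessibility classification of transcription-factor
peaks, and the reference-peak count matrix for external differential
testing.

A TF peak is classified from accessibility (ATAC) fragment counts
before ("pre", time 0) and after ("post") factor induction:

* ``newly_accessible`` — accessibility at the peak center (+/-200 bp)
  rises more than ``fc_threshold``-fold (default >2) AND the
  post-induction flanking region (+/-1 kb) carries more than
  ``flank_threshold`` normalized reads (default >30);
* ``constitutively_accessible`` — otherwise, the flanking region is
  already open (>30 normalized reads) without induction;
* ``constitutively_inaccessible`` — otherwise (flanking signal <=30).

All inequalities are strict; boundary values fall through to the next
rule. The three rules are evaluated in this order, which is the only
precedence making them mutually exclusive, so every peak receives
exactly one label.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, center_window
from .signal import PositionEvents, count_in_window

__all__ = [
    "CLASS_LABELS",
    "PeakClassLabel",
    "label_from_quantities",
    "classify_peak",
    "classify_all",
    "build_count_matrix",
    "write_class_bed",
]

CLASS_LABELS = (
    "newly_accessible",
    "constitutively_accessible",
    "constitutively_inaccessible",
)


@dataclass(frozen=True)
class PeakClassLabel:
    """A classified peak together with the quantities that justified it."""

    peak: GenomicInterval
    label: str
    fold_change_center: float
    flank_reads_pre: float
    flank_reads_post: float
    center_reads_pre: float
    center_reads_post: float


def label_from_quantities(
    fold_change: float,
    flank_pre: float,
    flank_post: float,
    fc_threshold: float = 2.0,
    flank_threshold: float = 30.0,
    constitutive_on: str = "pre",
) -> str:
    """Pure classification rule on already-normalized quantities.

    ``constitutive_on`` selects which condition's flanking counts decide
    the constitutive split (default the pre-induction state, matching
    the "constitutive" semantics of chromatin that is open or closed
    before the factor acts).
    """
    if constitutive_on not in ("pre", "post"):
        raise ValueError("constitutive_on must be 'pre' or 'post'")
    if fold_change > fc_threshold and flank_post > flank_threshold:
        return "newly_accessible"
    flank_ref = flank_pre if constitutive_on == "pre" else flank_post
    if flank_ref > flank_threshold:
        return "constitutively_accessible"
    return "constitutively_inaccessible"


def classify_peak(
    peak: GenomicInterval,
    events_pre: PositionEvents,
    events_post: PositionEvents,
    scale_pre: float,
    scale_post: float,
    fc_threshold: float = 2.0,
    flank_threshold: float = 30.0,
    center_half: int = 200,
    flank_half: int = 1000,
    pseudocount: float = 1.0,
    constitutive_on: str = "pre",
) -> PeakClassLabel:
    """Classify one peak from pre/post accessibility fragment events.

    Counts are midpoint counts in the +/-``center_half`` and
    +/-``flank_half`` windows, multiplied by the per-library scale
    factors; the center fold change uses a pseudocount so fully closed
    peaks do not divide by zero.
    """
    if peak.chrom not in events_pre.positions or peak.chrom not in events_post.positions:
        warnings.warn(
            f"chromosome {peak.chrom} missing from one condition; "
            "classifying with zero counts"
        )
    cw = center_window(peak, center_half)
    fw = center_window(peak, flank_half)
    center_pre = count_in_window(events_pre, cw) * scale_pre
    center_post = count_in_window(events_post, cw) * scale_post
    flank_pre = count_in_window(events_pre, fw) * scale_pre
    flank_post = count_in_window(events_post, fw) * scale_post
    fold_change = (center_post + pseudocount) / (center_pre + pseudocount)
    label = label_from_quantities(
        fold_change,
        flank_pre,
        flank_post,
        fc_threshold=fc_threshold,
        flank_threshold=flank_threshold,
        constitutive_on=constitutive_on,
    )
    return PeakClassLabel(
        peak, label, fold_change, flank_pre, flank_post, center_pre, center_post
    )


def classify_all(
    peaks: Sequence[GenomicInterval],
    events_pre: PositionEvents,
    events_post: PositionEvents,
    scale_pre: float,
    scale_post: float,
    **params,
) -> tuple[list[PeakClassLabel], dict[str, int]]:
    """Classify every peak; returns labels plus per-class summary counts
    (which always sum to ``len(peaks)``)."""
    labels = [
        classify_peak(p, events_pre, events_post, scale_pre, scale_post, **params)
        for p in peaks
    ]
    summary = Counter(l.label for l in labels)
    return labels, {name: summary.get(name, 0) for name in CLASS_LABELS}


def build_count_matrix(
    reference_peaks: Sequence[GenomicInterval],
    fragment_sets_by_sample: Mapping[str, PositionEvents],
    window_half: int = 200,
) -> pd.DataFrame:
    """Raw (unscaled) fragment counts per peak-center window per sample.

    The output is the input expected by external differential tools;
    rows are peak IDs, columns sample names.
    """
    if not fragment_sets_by_sample:
        raise ValueError("at least one sample is required")
    ids = [
        p.name if p.name else f"{p.chrom}:{p.start}-{p.end}" for p in reference_peaks
    ]
    data = {}
    for sample, events in fragment_sets_by_sample.items():
        data[sample] = [
            count_in_window(events, center_window(p, window_half))
            for p in reference_peaks
        ]
    return pd.DataFrame(data, index=ids, dtype=int)


def write_class_bed(labels: Sequence[PeakClassLabel], path) -> None:
    """BED with the class label in column 4."""
    with open(path, "w") as fh:
        for rec in labels:
            p = rec.peak
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{rec.label}\n")
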