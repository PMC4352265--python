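"""Binding segments: maximal runs of consecutive binding residues.

A binding segment is a maximal stretch of consecutive binding residues
(nucleotides) along the observed polymer sequence.  Runs never span chain
boundaries, and a gap in author numbering (unresolved residues in the
crystal) breaks a run, since the binding status of unobserved residues is
unknown.  Lengths are binned 1, 2, 3, 4, 5, 6 and >6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import BindingAnnotation

__all__ = ["Segment", "SegmentDistribution", "extract_segments", "segment_distribution"]

#: Bin labels for the length distribution; the last bin collects runs longer than 6.
BIN_LABELS = ("1", "2", "3", "4", "5", "6", ">6")


@dataclass(frozen=True)
class Segment:
    """One maximal run of binding residues within a chain."""

    chain_id: str
    start_ordinal: int
    length: int


@dataclass
class SegmentDistribution:
    """Binned run-length counts with two normalisations.

    ``segment_fraction[L]`` is the percentage of segments falling in bin L;
    ``accommodated_fraction[L]`` is the percentage of all binding residues
    accommodated by segments in bin L (for the >6 bin, their summed lengths).
    Both vectors sum to 100 when any segment exists.
    """

    counts: np.ndarray                 # len 7, per bin
    segment_fraction: np.ndarray       # percent, NaN when no segments
    accommodated_fraction: np.ndarray  # percent, NaN when no segments
    total_segments: int
    total_binding: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.counts,
                "segment_fraction": self.segment_fraction,
                "accommodated_fraction": self.accommodated_fraction,
            },
            index=list(BIN_LABELS),
        )


def extract_segments(annotation: BindingAnnotation, kind: str) -> list[Segment]:
    """Decompose the binding mask into maximal consecutive runs.

    Consecutiveness requires adjacency in the observed sequence *and*
    contiguous author numbering (a numbering jump of more than one indicates
    unresolved residues and breaks the run).
    """
    runs: list[Segment] = []
    for cid, chain in annotation.complex.chains(kind).items():
        mask = annotation.mask(kind)[cid]
        start = None
        prev_num = None
        for res, flag in zip(chain, mask):
            gap = prev_num is not None and res.author_number - prev_num > 1
            if flag:
                if start is None or gap:
                    if start is not None:
                        runs.append(Segment(cid, start, length))
                    start = res.ordinal
                    length = 0
                length += 1
            else:
                if start is not None:
                    runs.append(Segment(cid, start, length))
                    start = None
            prev_num = res.author_number
        if start is not None:
            runs.append(Segment(cid, start, length))
    return runs


def segment_distribution(runs: Sequence[Segment | int]) -> SegmentDistribution:
    """Bin run lengths into 1..6 and >6 and compute both fraction metrics."""
    lengths = [r.length if isinstance(r, Segment) else int(r) for r in runs]
    counts = np.zeros(7, dtype=np.int64)
    over6_total = 0
    for L in lengths:
        if L <= 6:
            counts[L - 1] += 1
        else:
            counts[6] += 1
            over6_total += L
    total_segments = int(counts.sum())
    total_binding = int(sum(lengths))
    if total_segments == 0:
        nan7 = np.full(7, np.nan)
        return SegmentDistribution(counts, nan7, nan7.copy(), 0, 0)
    segment_fraction = 100.0 * counts / total_segments
    accommodated = np.array(
        [counts[i] * (i + 1) for i in range(6)] + [over6_total], dtype=float
    )
    accommodated_fraction = 100.0 * accommodated / total_binding
    return SegmentDistribution(
        counts=counts,
        segment_fraction=segment_fraction,
        accommodated_fraction=accommodated_fraction,
        total_segments=total_segments,
        total_binding=total_binding,
    )
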