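"""Binding motifs: k-mer binding probabilities and neighbour-pair preferences.

Tripeptides/trinucleotides are scored with the *B* pattern (asterisks are any
residue, B a binding residue): a window counts as binding when its centre
residue is a binding site.  Ordered dipeptides are scored with the *B pattern
(second residue binding) or B* pattern (first residue binding).  Windows are
taken over contiguous stretches of the observed sequence only — they never
span chain boundaries or unresolved-residue gaps.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import BindingAnnotation
from .errors import RnaIfaceError
from .structure_io import PolymerResidue

__all__ = ["kmer_binding_probability", "neighbor_pair_preference", "preferred_pairs"]

#: Reporting threshold (strict) for the preferred-pair tables.
PREFERRED_THRESHOLD = 75.0
#: Minimum k-mer occurrences for inclusion in preferred-motif reports.
MIN_OCCURRENCE_REPORT = 3


def _contiguous_blocks(
    chain: Sequence[PolymerResidue], mask: np.ndarray
) -> Iterable[tuple[list[PolymerResidue], list[bool]]]:
    """Split a chain into stretches with contiguous author numbering."""
    block_res: list[PolymerResidue] = []
    block_mask: list[bool] = []
    prev_num = None
    for res, flag in zip(chain, mask):
        if prev_num is not None and res.author_number - prev_num > 1:
            if block_res:
                yield block_res, block_mask
            block_res, block_mask = [], []
        block_res.append(res)
        block_mask.append(bool(flag))
        prev_num = res.author_number
    if block_res:
        yield block_res, block_mask


def _windows(annotations: Iterable[BindingAnnotation], kind: str, k: int):
    """Yield (codes, flags) for every length-k window over contiguous stretches."""
    for ann in annotations:
        for cid, chain in ann.complex.chains(kind).items():
            mask = ann.mask(kind)[cid]
            for block, flags in _contiguous_blocks(chain, mask):
                codes = [r.code for r in block]
                standard = [r.is_standard for r in block]
                for i in range(len(block) - k + 1):
                    if all(standard[i : i + k]):
                        yield codes[i : i + k], flags[i : i + k]


def kmer_binding_probability(
    annotations: Sequence[BindingAnnotation],
    k: int = 3,
    kind: str = "protein",
    pattern: str = "center_binding",
    min_occurrence: int = 1,
) -> pd.DataFrame:
    """Binding probability of every observed k-mer in a group of complexes.

    Under ``center_binding`` (the *B* pattern, requires odd k) a window
    matches when its central residue is flagged; under ``all_binding`` when
    every residue in the window is flagged.  Probability is
    ``100 * binding_occurrences / occurrences``, set to NaN below
    ``min_occurrence``.  k-mers containing UNKNOWN residues are skipped.
    """
    annotations = list(annotations)
    if not annotations:
        raise RnaIfaceError("kmer_binding_probability: empty group")
    if pattern not in ("center_binding", "all_binding"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "center_binding" and k % 2 == 0:
        raise ValueError("center_binding requires odd k")
    occ: dict[str, int] = {}
    hit: dict[str, int] = {}
    centre = k // 2
    for codes, flags in _windows(annotations, kind, k):
        kmer = "".join(codes)
        occ[kmer] = occ.get(kmer, 0) + 1
        match = flags[centre] if pattern == "center_binding" else all(flags)
        if match:
            hit[kmer] = hit.get(kmer, 0) + 1
    rows = []
    for kmer in sorted(occ):
        n = occ[kmer]
        b = hit.get(kmer, 0)
        prob = 100.0 * b / n if n >= min_occurrence else np.nan
        rows.append((kmer, n, b, prob))
    return pd.DataFrame(
        rows, columns=["kmer", "occurrences", "binding_occurrences", "probability"]
    ).set_index("kmer")


def neighbor_pair_preference(
    annotations: Sequence[BindingAnnotation],
    pattern: str = "*B",
    kind: str = "protein",
    min_occurrence: int = 1,
) -> pd.DataFrame:
    """Binding probability of ordered residue pairs under the *B or B* pattern.

    For ``*B`` a pair (x, y) matches when y is a binding residue; for ``B*``
    when x is.  Probabilities are per ordered pair, pooled over the group.
    """
    if pattern not in ("*B", "B*"):
        raise ValueError(f"pattern must be '*B' or 'B*', got {pattern!r}")
    annotations = list(annotations)
    if not annotations:
        raise RnaIfaceError("neighbor_pair_preference: empty group")
    occ: dict[str, int] = {}
    hit: dict[str, int] = {}
    for codes, flags in _windows(annotations, kind, 2):
        pair = "".join(codes)
        occ[pair] = occ.get(pair, 0) + 1
        match = flags[1] if pattern == "*B" else flags[0]
        if match:
            hit[pair] = hit.get(pair, 0) + 1
    rows = []
    for pair in sorted(occ):
        n = occ[pair]
        b = hit.get(pair, 0)
        prob = 100.0 * b / n if n >= min_occurrence else np.nan
        rows.append((pair, n, b, prob))
    return pd.DataFrame(
        rows, columns=["pair", "occurrences", "binding_occurrences", "probability"]
    ).set_index("pair")


def preferred_pairs(
    tables: Mapping[str, pd.DataFrame],
    threshold: float = PREFERRED_THRESHOLD,
    min_occurrence: int = MIN_OCCURRENCE_REPORT,
) -> pd.DataFrame:
    """Cross-group report of pairs preferred (> threshold %) in any group.

    ``tables`` maps group name to the output of
    :func:`neighbor_pair_preference` (or :func:`kmer_binding_probability`).
    A pair qualifies when some group has at least ``min_occurrence``
    occurrences and probability strictly above ``threshold``; the report
    lists its probability in every group (NaN where unobserved).
    """
    all_keys: list[str] = []
    for df in tables.values():
        for key in df.index:
            if key not in all_keys:
                all_keys.append(key)
    rows = {}
    for key in sorted(all_keys):
        probs = {}
        qualifies = False
        for group, df in tables.items():
            if key in df.index:
                n = int(df.loc[key, "occurrences"])
                p = float(df.loc[key, "probability"]) if n >= 1 else np.nan
                probs[group] = p
                if n >= min_occurrence and np.isfinite(p) and p > threshold:
                    qualifies = True
            else:
                probs[group] = np.nan
        if qualifies:
            rows[key] = probs
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(tables))
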