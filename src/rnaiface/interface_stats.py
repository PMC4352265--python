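"""Normalized binding propensities and group-difference statistics.

The propensity of symbol i (one of the 20 amino acids or 4 ribonucleotides) is

    P_bind(i)  = 100 * f_b(i) / f_t(i)
    Norm       = 100 * sum(f_b) / sum(f_t)
    Pnorm(i)   = P_bind(i) / Norm

where f_b counts occurrences at binding sites and f_t occurrences overall.
Pnorm is a dimensionless enrichment with neutral value 1: the f_t-weighted
mean of Pnorm over the alphabet is exactly 1 by construction.  Values above 2
are conventionally read as a strong interface preference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabets import AMINO_ACIDS, NUCLEOTIDES
from .contacts import BindingAnnotation
from .errors import AlignmentError, RnaIfaceError

__all__ = [
    "CountTable",
    "PropensityTable",
    "count_binding",
    "binding_propensity",
    "aggregate_propensity",
    "conserved_propensity",
    "anova_group_test",
    "load_conservation",
]


def _alphabet(kind: str) -> tuple[str, ...]:
    if kind == "protein":
        return AMINO_ACIDS
    if kind == "rna":
        return NUCLEOTIDES
    raise ValueError(f"kind must be 'protein' or 'rna', got {kind!r}")


@dataclass
class CountTable:
    """Binding and total occurrence counts per alphabet symbol."""

    alphabet: tuple[str, ...]
    f_b: np.ndarray
    f_t: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.f_b = np.asarray(self.f_b, dtype=np.int64)
        self.f_t = np.asarray(self.f_t, dtype=np.int64)
        if self.f_b.shape != (len(self.alphabet),) or self.f_t.shape != (len(self.alphabet),):
            raise ValueError("count vectors must match the alphabet length")
        if np.any(self.f_b < 0) or np.any(self.f_b > self.f_t):
            raise ValueError("requires 0 <= f_b(i) <= f_t(i)")

    def __add__(self, other: "CountTable") -> "CountTable":
        if self.alphabet != other.alphabet:
            raise ValueError("cannot add count tables over different alphabets")
        return CountTable(self.alphabet, self.f_b + other.f_b, self.f_t + other.f_t, self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f_b": self.f_b, "f_t": self.f_t}, index=list(self.alphabet))


@dataclass
class PropensityTable:
    """Normalized binding propensities, pooled or averaged over complexes."""

    alphabet: tuple[str, ...]
    p_bind: np.ndarray          # percent; NaN where f_t = 0
    pnorm: np.ndarray           # dimensionless; NaN where undefined/absent
    norm: float | None          # pooled mode only
    mode: str                   # "pooled" | "per_complex_mean"
    kind: str
    sd: np.ndarray | None = None           # per_complex_mean mode: sample SD
    n_complexes: np.ndarray | None = None  # per_complex_mean mode: complexes used
    counts: CountTable | None = None       # pooled mode: the underlying counts

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"P_bind": self.p_bind, "Pnorm": self.pnorm}
        if self.sd is not None:
            data["SD"] = self.sd
        if self.n_complexes is not None:
            data["n_complexes"] = self.n_complexes
        return pd.DataFrame(data, index=list(self.alphabet))

    def __getitem__(self, symbol: str) -> float:
        return float(self.pnorm[self.alphabet.index(symbol)])


def count_binding(
    annotations: BindingAnnotation | Iterable[BindingAnnotation], kind: str
) -> CountTable:
    """Pool f_b/f_t counts over one or more annotated complexes.

    UNKNOWN-code residues are excluded from both counts.
    """
    if isinstance(annotations, BindingAnnotation):
        annotations = [annotations]
    annotations = list(annotations)
    if not annotations:
        raise RnaIfaceError("count_binding: empty annotation list")
    alphabet = _alphabet(kind)
    index = {s: i for i, s in enumerate(alphabet)}
    f_b = np.zeros(len(alphabet), dtype=np.int64)
    f_t = np.zeros(len(alphabet), dtype=np.int64)
    for ann in annotations:
        for cid, chain in ann.complex.chains(kind).items():
            mask = ann.mask(kind)[cid]
            for res, flag in zip(chain, mask):
                i = index.get(res.code)
                if i is None:
                    continue
                f_t[i] += 1
                if flag:
                    f_b[i] += 1
    return CountTable(alphabet, f_b, f_t, kind)


def binding_propensity(counts: CountTable) -> PropensityTable:
    """Pooled normalized binding propensity from a count table.

    ``Pnorm(i) = (f_b(i)/f_t(i)) / (sum(f_b)/sum(f_t))``; symbols absent from
    the pool (f_t = 0) get NaN.
    """
    total_b = int(counts.f_b.sum())
    total_t = int(counts.f_t.sum())
    if total_b == 0:
        raise RnaIfaceError("propensity undefined: no binding residues in the pool")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bind = np.where(counts.f_t > 0, 100.0 * counts.f_b / counts.f_t, np.nan)
    norm = 100.0 * total_b / total_t
    pnorm = p_bind / norm
    return PropensityTable(
        alphabet=counts.alphabet,
        p_bind=p_bind,
        pnorm=pnorm,
        norm=norm,
        mode="pooled",
        kind=counts.kind,
        counts=counts,
    )


def aggregate_propensity(
    tables: Sequence[PropensityTable], exclude: str = "fb_zero"
) -> PropensityTable:
    """Mean ± SD of per-complex propensities.

    For each symbol, complexes where that symbol never occurs (f_t = 0) are
    excluded; with ``exclude="fb_zero"`` (default) complexes where it occurs
    but never binds (f_b = 0) are excluded as well, so the average is over
    complexes where the residue has binding sites.  ``exclude="ft_zero"``
    keeps zero-propensity complexes in the mean.  SD is the sample standard
    deviation (n-1); symbols observed in a single complex get SD 0.
    """
    if not tables:
        raise RnaIfaceError("aggregate_propensity: empty table list")
    if exclude not in ("fb_zero", "ft_zero"):
        raise ValueError(f"exclude must be 'fb_zero' or 'ft_zero', got {exclude!r}")
    alphabet = tables[0].alphabet
    kind = tables[0].kind
    for t in tables:
        if t.alphabet != alphabet:
            raise ValueError("tables use different alphabets")
        if t.counts is None:
            raise ValueError("aggregate_propensity requires pooled tables carrying counts")

    n = len(alphabet)
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    used = np.zeros(n, dtype=np.int64)
    for i in range(n):
        vals = []
        for t in tables:
            assert t.counts is not None
            if t.counts.f_t[i] == 0:
                continue
            if exclude == "fb_zero" and t.counts.f_b[i] == 0:
                continue
            vals.append(t.pnorm[i])
        if vals:
            mean[i] = float(np.mean(vals))
            sd[i] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            used[i] = len(vals)
    return PropensityTable(
        alphabet=alphabet,
        p_bind=np.full(n, np.nan),
        pnorm=mean,
        norm=None,
        mode="per_complex_mean",
        kind=kind,
        sd=sd,
        n_complexes=used,
    )


ConservationProfile = Mapping[tuple[str, int], int]
"""Per-residue conservation grades keyed by (chain_id, author_number); 1..9."""


def conserved_propensity(
    annotations: Sequence[BindingAnnotation],
    profiles: Sequence[ConservationProfile],
    min_grade: int = 8,
) -> PropensityTable:
    """Binding propensity restricted to conserved protein positions.

    A position counts when its conservation grade (1 = highly variable,
    9 = highly conserved) is at least ``min_grade``.  Every standard residue
    of every annotated complex must carry a grade.
    """
    if len(annotations) != len(profiles):
        raise AlignmentError("one conservation profile required per complex")
    if not 1 <= min_grade <= 9:
        raise ValueError("min_grade must be within 1..9")
    alphabet = _alphabet("protein")
    index = {s: i for i, s in enumerate(alphabet)}
    f_b = np.zeros(len(alphabet), dtype=np.int64)
    f_t = np.zeros(len(alphabet), dtype=np.int64)
    any_pass = False
    for ann, profile in zip(annotations, profiles):
        for cid, chain in ann.complex.chains("protein").items():
            mask = ann.mask("protein")[cid]
            for res, flag in zip(chain, mask):
                if res.code not in index:
                    continue
                key = (cid, res.author_number)
                if key not in profile:
                    raise AlignmentError(
                        f"{ann.complex.entry.pdb_id}: no conservation grade for "
                        f"chain {cid} residue {res.author_number}"
                    )
                grade = int(profile[key])
                if not 1 <= grade <= 9:
                    raise ValueError(f"conservation grade out of range 1..9: {grade}")
                if grade < min_grade:
                    continue
                any_pass = True
                i = index[res.code]
                f_t[i] += 1
                if flag:
                    f_b[i] += 1
    if not any_pass:
        raise RnaIfaceError(f"no conserved positions at min_grade={min_grade}")
    return binding_propensity(CountTable(alphabet, f_b, f_t, "protein"))


def load_conservation(path: str | Path) -> dict[tuple[str, int], int]:
    """Read a ConSurf-style grade export: TSV with chain, author_number, grade."""
    grades: dict[tuple[str, int], int] = {}
    with open(path) as fh:
        header_skipped = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_skipped:
                header_skipped = True
                if not fields[-1].lstrip("-").isdigit():
                    continue  # header row
            grades[(fields[0], int(fields[1]))] = int(fields[2])
    return grades


def anova_group_test(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    """One-way fixed-effects ANOVA computed from sums of squares.

    Returns (F, p).  When both the between- and within-group sums of squares
    vanish (all values identical) the test is degenerate and (0, 1) is
    returned by convention.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise RnaIfaceError("ANOVA requires at least two groups")
    for g in arrays:
        if g.size < 2:
            raise RnaIfaceError("ANOVA requires at least two values per group")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return np.inf, 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p
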