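"""Residue-nucleotide pair preferences and knowledge-based pair potentials.

For an organism group, the pair preference of residue type i and nucleotide
type j is

    Pair_org(i,j) = N_ij / (sum N_i + sum N_j)

where N_ij counts contacting residue-nucleotide pairs of those types at the
interface (each contacting pair counted once, regardless of how many atom
pairs are below the cutoff) and sum N_i / sum N_j are the total compositions
of the group's proteins and RNAs.  Normalising by the same quantity over the
whole dataset gives the propensity, and the potential follows as a Boltzmann
inversion:

    Propen(i,j)    = Pair_org(i,j) / Pair_all(i,j)
    Potential(i,j) = -R T ln Propen(i,j)      [kcal/mol]

Pairs with potential below -0.5 kcal/mol are classified as preferred and
above +0.5 as avoided (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .alphabets import AA_INDEX, AMINO_ACIDS, NT_INDEX, NUCLEOTIDES
from .contacts import BindingAnnotation
from .errors import RnaIfaceError

__all__ = [
    "PairCounts",
    "interface_pair_counts",
    "pair_preference",
    "pair_potential",
    "classify_pairs",
]

#: Gas constant in kcal/(mol K).
R_GAS = 1.987e-3
#: Default temperature in K.
DEFAULT_T = 300.0
#: Classification thresholds on the kcal/mol scale (strict inequalities).
PREFERRED_BELOW = -0.5
AVOIDED_ABOVE = 0.5


@dataclass
class PairCounts:
    """Interface pair counts N_ij plus total compositions of the pool."""

    n_ij: np.ndarray      # (20, 4) int
    sigma_i: np.ndarray   # (20,) total residues of each type in the pool
    sigma_j: np.ndarray   # (4,) total nucleotides of each type in the pool

    def __post_init__(self) -> None:
        self.n_ij = np.asarray(self.n_ij, dtype=np.int64)
        self.sigma_i = np.asarray(self.sigma_i, dtype=np.int64)
        self.sigma_j = np.asarray(self.sigma_j, dtype=np.int64)
        if self.n_ij.shape != (len(AMINO_ACIDS), len(NUCLEOTIDES)):
            raise ValueError("n_ij must be 20x4")
        if np.any(self.n_ij < 0) or np.any(self.sigma_i < 0) or np.any(self.sigma_j < 0):
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "PairCounts") -> "PairCounts":
        return PairCounts(
            self.n_ij + other.n_ij,
            self.sigma_i + other.sigma_i,
            self.sigma_j + other.sigma_j,
        )


def interface_pair_counts(annotations: Iterable[BindingAnnotation]) -> PairCounts:
    """Count typed residue-nucleotide contact pairs over a group of complexes.

    Each contacting residue-nucleotide pair contributes one count to N_ij
    however many atom pairs fall below the cutoff.  Compositions are taken
    over all standard residues/nucleotides of the group, binding or not.
    """
    annotations = list(annotations)
    if not annotations:
        raise RnaIfaceError("interface_pair_counts: empty group")
    n_ij = np.zeros((len(AMINO_ACIDS), len(NUCLEOTIDES)), dtype=np.int64)
    sigma_i = np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    sigma_j = np.zeros(len(NUCLEOTIDES), dtype=np.int64)
    for ann in annotations:
        for contact in ann.contacts:
            i = AA_INDEX.get(contact.protein_code)
            j = NT_INDEX.get(contact.rna_code)
            if i is not None and j is not None:
                n_ij[i, j] += 1
        for res in ann.complex.residues("protein"):
            if res.code in AA_INDEX:
                sigma_i[AA_INDEX[res.code]] += 1
        for res in ann.complex.residues("rna"):
            if res.code in NT_INDEX:
                sigma_j[NT_INDEX[res.code]] += 1
    return PairCounts(n_ij, sigma_i, sigma_j)


def pair_preference(counts: PairCounts) -> np.ndarray:
    """Pair_org(i,j) = N_ij / (sigma_i + sigma_j); NaN where the denominator is 0."""
    denom = counts.sigma_i[:, None] + counts.sigma_j[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, counts.n_ij / denom, np.nan)
    return out


def pair_potential(
    org: PairCounts, all_: PairCounts, temperature: float = DEFAULT_T
) -> pd.DataFrame:
    """Per-pair propensity, potential and classification for one organism group.

    Returns the 80-row long-form table (residue, nucleotide, n_ij, pair_org,
    pair_all, propen, potential, class).  Cells unobserved in the organism
    group (N_ij = 0) carry NaN potential and class ``unobserved`` rather than
    an infinite value; cells whose global reference Pair_all is 0 or NaN are
    also unobserved.
    """
    p_org = pair_preference(org)
    p_all = pair_preference(all_)
    if np.any((org.n_ij > 0) & ~(np.nan_to_num(p_all) > 0)):
        raise RnaIfaceError(
            "organism pool contains pairs absent from the global pool; "
            "the global pool must contain every group"
        )
    rows = []
    rt = R_GAS * temperature
    for i, aa in enumerate(AMINO_ACIDS):
        for j, nt in enumerate(NUCLEOTIDES):
            n = int(org.n_ij[i, j])
            po, pa = p_org[i, j], p_all[i, j]
            if n == 0 or not np.isfinite(po) or not np.isfinite(pa) or pa == 0:
                propen = np.nan
                potential = np.nan
            else:
                propen = po / pa
                potential = -rt * np.log(propen)
            rows.append((aa, nt, n, po, pa, propen, potential))
    df = pd.DataFrame(
        rows,
        columns=["residue", "nucleotide", "n_ij", "pair_org", "pair_all", "propen", "potential"],
    )
    df["class"] = classify_pairs(df["potential"].to_numpy())
    return df


def classify_pairs(
    potential: np.ndarray, lo: float = PREFERRED_BELOW, hi: float = AVOIDED_ABOVE
) -> np.ndarray:
    """Classify potentials: preferred (< lo), avoided (> hi), neutral, unobserved (NaN)."""
    if not lo < hi:
        raise ValueError("thresholds must satisfy lo < hi")
    potential = np.asarray(potential, dtype=float)
    labels = np.full(potential.shape, "neutral", dtype=object)
    labels[~np.isfinite(potential)] = "unobserved"
    labels[np.isfinite(potential) & (potential < lo)] = "preferred"
    labels[np.isfinite(potential) & (potential > hi)] = "avoided"
    return labels
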