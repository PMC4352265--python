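"""Distance-based identification of binding-site residues and nucleotides.

A protein residue and an RNA nucleotide are in contact when any pair of their
heavy atoms lies strictly closer than the cutoff (default 3.5 Å).  The
implementation uses a k-d tree over atom coordinates; an all-pairs brute-force
oracle lives in the test suite, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import RnaIfaceError
from .structure_io import ComplexStructure, PolymerResidue

__all__ = ["Contact", "BindingAnnotation", "find_binding_sites", "binding_percentages"]

DEFAULT_CUTOFF = 3.5  # Å, strict upper bound on heavy-atom distance


@dataclass(frozen=True)
class Contact:
    """One residue-nucleotide pair with at least one heavy-atom pair below cutoff."""

    protein_chain: str
    protein_ordinal: int
    protein_code: str
    rna_chain: str
    rna_ordinal: int
    rna_code: str
    min_distance: float


@dataclass
class BindingAnnotation:
    """Binding flags for every residue/nucleotide of a complex plus the contact list."""

    complex: ComplexStructure
    cutoff: float
    contacts: list[Contact]
    binding_mask_protein: dict[str, np.ndarray] = field(default_factory=dict)
    binding_mask_rna: dict[str, np.ndarray] = field(default_factory=dict)

    def mask(self, kind: str) -> dict[str, np.ndarray]:
        return self.binding_mask_protein if kind == "protein" else self.binding_mask_rna

    def flagged_residues(self, kind: str) -> list[PolymerResidue]:
        out = []
        for cid, chain in self.complex.chains(kind).items():
            m = self.mask(kind)[cid]
            out.extend(res for res, flag in zip(chain, m) if flag)
        return out


def _atom_table(complex_: ComplexStructure, kind: str):
    """Flatten all heavy atoms of one molecule into (coords, chain index, ordinal)."""
    coords = []
    chain_ids = []
    ordinals = []
    for cid, chain in complex_.chains(kind).items():
        for res in chain:
            for atom in res.heavy_atoms:
                coords.append(atom.xyz)
                chain_ids.append(cid)
                ordinals.append(res.ordinal)
    if not coords:
        raise RnaIfaceError(f"complex {complex_.entry.pdb_id}: no {kind} heavy atoms")
    return np.asarray(coords, dtype=float), np.asarray(chain_ids), np.asarray(ordinals)


def find_binding_sites(
    complex_: ComplexStructure, cutoff: float = DEFAULT_CUTOFF
) -> BindingAnnotation:
    """Identify all protein-RNA contacts under the strict heavy-atom distance cutoff.

    A residue (nucleotide) is flagged as binding iff it appears in at least one
    contact.  Only protein-RNA atom pairs are examined; the result is
    deterministic for a given complex and cutoff.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    p_xyz, p_chain, p_ord = _atom_table(complex_, "protein")
    r_xyz, r_chain, r_ord = _atom_table(complex_, "rna")

    tree_p = cKDTree(p_xyz)
    tree_r = cKDTree(r_xyz)
    # query_ball_tree is inclusive at the radius; the strict '<' is enforced below
    neighbours = tree_p.query_ball_tree(tree_r, r=cutoff)

    best: dict[tuple[str, int, str, int], float] = {}
    for ip, hits in enumerate(neighbours):
        if not hits:
            continue
        d = np.linalg.norm(r_xyz[hits] - p_xyz[ip], axis=1)
        for ir, dist in zip(hits, d):
            if dist >= cutoff:
                continue
            key = (p_chain[ip], int(p_ord[ip]), r_chain[ir], int(r_ord[ir]))
            if dist < best.get(key, np.inf):
                best[key] = float(dist)

    prot_chains = complex_.chains("protein")
    rna_chains = complex_.chains("rna")
    mask_p = {cid: np.zeros(len(chain), dtype=bool) for cid, chain in prot_chains.items()}
    mask_r = {cid: np.zeros(len(chain), dtype=bool) for cid, chain in rna_chains.items()}
    contacts = []
    for (pc, po, rc, ro), dist in sorted(best.items()):
        contacts.append(
            Contact(
                protein_chain=pc,
                protein_ordinal=po,
                protein_code=prot_chains[pc][po].code,
                rna_chain=rc,
                rna_ordinal=ro,
                rna_code=rna_chains[rc][ro].code,
                min_distance=dist,
            )
        )
        mask_p[pc][po] = True
        mask_r[rc][ro] = True

    return BindingAnnotation(
        complex=complex_,
        cutoff=cutoff,
        contacts=contacts,
        binding_mask_protein=mask_p,
        binding_mask_rna=mask_r,
    )


def binding_percentages(annotation: BindingAnnotation) -> tuple[float, float]:
    """Percentage of standard-code residues (nucleotides) that are binding sites.

    Residues with UNKNOWN code are excluded from both numerator and
    denominator.
    """
    out = []
    for kind in ("protein", "rna"):
        total = flagged = 0
        for cid, chain in annotation.complex.chains(kind).items():
            m = annotation.mask(kind)[cid]
            for res, flag in zip(chain, m):
                if not res.is_standard:
                    continue
                total += 1
                flagged += bool(flag)
        if total == 0:
            raise RnaIfaceError(f"no standard {kind} residues to compute percentage over")
        out.append(100.0 * flagged / total)
    return out[0], out[1]


def write_contacts_tsv(annotation: BindingAnnotation, path: str | Path) -> Path:
    """Write the contact list as TSV (one row per residue-nucleotide pair)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pdb_id = annotation.complex.entry.pdb_id
    prot = annotation.complex.chains("protein")
    rna = annotation.complex.chains("rna")
    with open(path, "w") as fh:
        fh.write(
            "pdb_id\tprotein_chain\tprotein_resnum\tprotein_code\t"
            "rna_chain\trna_resnum\trna_code\tmin_distance\n"
        )
        for c in annotation.contacts:
            pres = prot[c.protein_chain][c.protein_ordinal]
            rres = rna[c.rna_chain][c.rna_ordinal]
            fh.write(
                f"{pdb_id}\t{c.protein_chain}\t{pres.author_number}{pres.insertion_code}\t"
                f"{c.protein_code}\t{c.rna_chain}\t{rres.author_number}{rres.insertion_code}\t"
                f"{c.rna_code}\t{c.min_distance:.3f}\n"
            )
    return path
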