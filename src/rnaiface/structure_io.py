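"""Reading and writing protein-RNA complex structures.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF) and normalised into a
light polymer model: per-chain ordered lists of residues carrying only heavy
atoms.  The first model is used, alternate locations are collapsed to the
highest-occupancy conformer, and waters/ligands/hydrogens are discarded.
Modified components are mapped to their standard parent where the bundled
table knows one, and to UNKNOWN otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import gemmi
import numpy as np

from .alphabets import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    ONE_TO_THREE,
    UNKNOWN,
    is_modified,
    map_modified_components,
)
from .errors import DatasetCriteriaError, ManifestError, StructureError

__all__ = [
    "Atom",
    "PolymerResidue",
    "ManifestEntry",
    "ComplexStructure",
    "DatasetCriteriaWarning",
    "load_complex",
    "write_structure",
    "load_manifest",
]

#: Default dataset inclusion criteria: minimum polymer lengths.
MIN_PROTEIN_RESIDUES = 30
MIN_RNA_NUCLEOTIDES = 5

#: Organism groups recognised by the comparative analysis.
ORGANISM_GROUPS = ("ecoli", "human", "yeast", "thermophile", "archaea", "other")


class DatasetCriteriaWarning(UserWarning):
    """A complex violates the dataset inclusion criteria but was loaded anyway."""


class Atom(NamedTuple):
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class PolymerResidue:
    """One observed residue or nucleotide with its heavy atoms."""

    chain_id: str
    ordinal: int               # 0-based position in the chain's observed sequence
    author_number: int
    insertion_code: str
    code: str                  # one-letter standard code or UNKNOWN
    raw_name: str              # component id as found in the file
    heavy_atoms: list[Atom] = field(default_factory=list)
    was_modified: bool = False

    @property
    def is_standard(self) -> bool:
        return self.code != UNKNOWN

    def coords(self) -> np.ndarray:
        return np.asarray([a.xyz for a in self.heavy_atoms], dtype=float)


@dataclass
class ManifestEntry:
    """One row of the dataset manifest: which chains of which entry to analyse."""

    set_id: str
    pdb_id: str
    protein_chains: tuple[str, ...]
    rna_chains: tuple[str, ...]
    organism: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        self.protein_chains = tuple(self.protein_chains)
        self.rna_chains = tuple(self.rna_chains)
        if not self.pdb_id:
            raise ManifestError("pdb_id must be non-empty")
        if not self.protein_chains or not self.rna_chains:
            raise ManifestError(f"{self.pdb_id}: protein and RNA chain lists must be non-empty")
        if set(self.protein_chains) & set(self.rna_chains):
            raise ManifestError(f"{self.pdb_id}: protein and RNA chain lists must be disjoint")
        # the five canonical comparison groups plus "other" are the convention,
        # but grouping is manifest-driven, so any non-empty label is accepted
        if not self.group:
            raise ManifestError(f"{self.pdb_id}: group label must be non-empty")


@dataclass
class ComplexStructure:
    """A parsed protein-RNA complex: per-chain ordered residue lists."""

    entry: ManifestEntry
    protein: dict[str, list[PolymerResidue]]
    rna: dict[str, list[PolymerResidue]]

    def chains(self, kind: str) -> dict[str, list[PolymerResidue]]:
        if kind == "protein":
            return self.protein
        if kind == "rna":
            return self.rna
        raise ValueError(f"kind must be 'protein' or 'rna', got {kind!r}")

    def residues(self, kind: str) -> Iterator[PolymerResidue]:
        for chain in self.chains(kind).values():
            yield from chain

    def n_residues(self, kind: str, standard_only: bool = False) -> int:
        if standard_only:
            return sum(1 for r in self.residues(kind) if r.is_standard)
        return sum(len(c) for c in self.chains(kind).values())


_HYDROGEN_ELEMENTS = {"H", "D"}


def _pick_altloc(residue: gemmi.Residue) -> str | None:
    """Return the altloc id to keep (highest mean occupancy, first on tie)."""
    occ: dict[str, list[float]] = {}
    order: list[str] = []
    for atom in residue:
        loc = atom.altloc
        if loc and loc != "\x00":
            if loc not in occ:
                occ[loc] = []
                order.append(loc)
            occ[loc].append(atom.occ)
    if not order:
        return None
    means = {loc: float(np.mean(v)) for loc, v in occ.items()}
    best = order[0]
    for loc in order[1:]:
        if means[loc] > means[best]:
            best = loc
    return best


def _is_polymer_component(name: str, kind: str) -> bool:
    """Keep standard/modified polymer components and tabulated polymer residues."""
    code = map_modified_components(name, kind)
    if code != UNKNOWN:
        return True
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return False
    if info.is_water():
        return False
    if kind == "protein":
        return info.is_amino_acid()
    return info.is_nucleic_acid()


def _extract_chain(chain: gemmi.Chain, kind: str) -> list[PolymerResidue]:
    residues: list[PolymerResidue] = []
    for res in chain:
        if res.is_water() or not _is_polymer_component(res.name, kind):
            continue
        keep_loc = _pick_altloc(res)
        atoms: list[Atom] = []
        for atom in res:
            elem = atom.element.name.upper()
            if elem in _HYDROGEN_ELEMENTS:
                continue
            loc = atom.altloc
            if loc and loc != "\x00" and loc != keep_loc:
                continue
            atoms.append(Atom(atom.name, elem, (atom.pos.x, atom.pos.y, atom.pos.z)))
        if not atoms:
            continue
        code = map_modified_components(res.name, kind)
        residues.append(
            PolymerResidue(
                chain_id=chain.name,
                ordinal=len(residues),
                author_number=res.seqid.num,
                insertion_code=res.seqid.icode.strip(),
                code=code,
                raw_name=res.name.strip().upper(),
                heavy_atoms=atoms,
                was_modified=is_modified(res.name, kind),
            )
        )
    return residues


def load_complex(
    path: str | Path,
    entry: ManifestEntry,
    min_protein: int = MIN_PROTEIN_RESIDUES,
    min_rna: int = MIN_RNA_NUCLEOTIDES,
    strict_criteria: bool = False,
) -> ComplexStructure:
    """Load the chains named in ``entry`` from a PDB or mmCIF file.

    Only the first model is used; alternate locations collapse to the
    highest-occupancy conformer (first on tie); hydrogens, waters and
    non-polymer components are discarded.

    Raises
    ------
    ManifestError
        If a listed chain is absent from the file.
    DatasetCriteriaError
        If ``strict_criteria`` and a polymer is shorter than the minima
        (otherwise a :class:`DatasetCriteriaWarning` is issued).
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on malformed input
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    def grab(chain_ids: tuple[str, ...], kind: str) -> dict[str, list[PolymerResidue]]:
        out: dict[str, list[PolymerResidue]] = {}
        for cid in chain_ids:
            chain = model.find_chain(cid)
            if chain is None:
                raise ManifestError(
                    f"{entry.pdb_id}: chain {cid!r} listed in manifest but absent from {path.name}"
                )
            out[cid] = _extract_chain(chain, kind)
        return out

    protein = grab(entry.protein_chains, "protein")
    rna = grab(entry.rna_chains, "rna")

    n_prot = sum(len(c) for c in protein.values())
    n_rna = sum(len(c) for c in rna.values())
    problems = []
    if n_prot < min_protein:
        problems.append(f"protein has {n_prot} residues (< {min_protein})")
    if n_rna < min_rna:
        problems.append(f"RNA has {n_rna} nucleotides (< {min_rna})")
    if problems:
        msg = f"{entry.pdb_id}: dataset criteria violated: " + "; ".join(problems)
        if strict_criteria:
            raise DatasetCriteriaError(msg)
        warnings.warn(msg, DatasetCriteriaWarning, stacklevel=2)

    return ComplexStructure(entry=entry, protein=protein, rna=rna)


def _residue_name(res: PolymerResidue, kind: str) -> str:
    if res.raw_name:
        return res.raw_name
    if res.code == UNKNOWN:
        return "UNK" if kind == "protein" else "N"
    if kind == "protein":
        return ONE_TO_THREE[res.code]
    return res.code


def write_structure(complex_: ComplexStructure, path: str | Path) -> Path:
    """Write the complex as a standards-conformant PDB file.

    ``load_complex(write_structure(c))`` reproduces codes, ordinals and
    coordinates to the PDB coordinate precision (1e-3 Å).
    """
    for kind in ("protein", "rna"):
        for cid, chain in complex_.chains(kind).items():
            if not chain:
                raise StructureError(f"chain {cid!r} ({kind}) is empty")
            for res in chain:
                if not res.heavy_atoms:
                    raise StructureError(
                        f"residue {cid}/{res.author_number} has no heavy atoms"
                    )
                for atom in res.heavy_atoms:
                    if not np.all(np.isfinite(atom.xyz)):
                        raise StructureError(
                            f"non-finite coordinate in {cid}/{res.author_number}/{atom.name}"
                        )

    st = gemmi.Structure()
    st.name = complex_.entry.pdb_id
    model = gemmi.Model("1")
    for kind in ("protein", "rna"):
        for cid, chain_res in complex_.chains(kind).items():
            chain = gemmi.Chain(cid)
            for res in chain_res:
                gres = gemmi.Residue()
                gres.name = _residue_name(res, kind)
                gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
                for atom in res.heavy_atoms:
                    gat = gemmi.Atom()
                    gat.name = atom.name
                    gat.element = gemmi.Element(atom.element)
                    gat.pos = gemmi.Position(*atom.xyz)
                    gat.occ = 1.0
                    gres.add_atom(gat)
                chain.add_residue(gres)
            model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(path))
    return path


def _parse_chain_list(raw: str) -> tuple[str, ...]:
    return tuple(c.strip() for c in raw.replace(";", ",").split(",") if c.strip())


def load_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a dataset manifest from TSV or JSON.

    TSV columns: set_id, pdb_id, protein_chains, rna_chains, organism, group
    (chain lists comma-separated).  JSON: a list of objects with the same keys.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    if path.suffix.lower() == ".json":
        for row in json.loads(path.read_text()):
            entries.append(
                ManifestEntry(
                    set_id=row["set_id"],
                    pdb_id=row["pdb_id"],
                    protein_chains=tuple(row["protein_chains"]),
                    rna_chains=tuple(row["rna_chains"]),
                    organism=row.get("organism", ""),
                    group=row.get("group", "other"),
                )
            )
        return entries

    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                continue
            row = dict(zip(header, fields))
            entries.append(
                ManifestEntry(
                    set_id=row["set_id"],
                    pdb_id=row["pdb_id"],
                    protein_chains=_parse_chain_list(row["protein_chains"]),
                    rna_chains=_parse_chain_list(row["rna_chains"]),
                    organism=row.get("organism", ""),
                    group=row.get("group", "other"),
                )
            )
    if header is None:
        raise ManifestError(f"{path}: empty manifest")
    return entries
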