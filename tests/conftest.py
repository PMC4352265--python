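"""Shared fixtures: hand-built complexes and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rnaiface.structure_io import Atom, ComplexStructure, ManifestEntry, PolymerResidue


def make_residue(chain_id, ordinal, code, atom_coords, author_number=None, kind="protein"):
    """Build a residue with one generic heavy atom per coordinate triple."""
    atoms = [Atom(f"C{i}", "C", tuple(map(float, xyz))) for i, xyz in enumerate(atom_coords)]
    return PolymerResidue(
        chain_id=chain_id,
        ordinal=ordinal,
        author_number=author_number if author_number is not None else ordinal + 1,
        insertion_code="",
        code=code,
        raw_name="",
        heavy_atoms=atoms,
    )


def make_complex(protein_spec, rna_spec, pdb_id="TEST"):
    """Build a ComplexStructure from {chain: [(code, coords), ...]} dicts."""
    entry = ManifestEntry(
        set_id="fixture",
        pdb_id=pdb_id,
        protein_chains=tuple(protein_spec),
        rna_chains=tuple(rna_spec),
        organism="fixture",
        group="other",
    )
    protein = {
        cid: [make_residue(cid, i, code, coords) for i, (code, coords) in enumerate(residues)]
        for cid, residues in protein_spec.items()
    }
    rna = {
        cid: [
            make_residue(cid, i, code, coords, kind="rna")
            for i, (code, coords) in enumerate(residues)
        ]
        for cid, residues in rna_spec.items()
    }
    return ComplexStructure(entry=entry, protein=protein, rna=rna)


def brute_force_contacts(complex_, cutoff=3.5):
    """All-pairs O(n^2) contact oracle: {(pchain, pord, rchain, rord): min_dist}."""
    pairs = {}
    for pres in complex_.residues("protein"):
        pc = pres.coords()
        for rres in complex_.residues("rna"):
            d = float(cdist(pc, rres.coords()).min())
            if d < cutoff:
                pairs[(pres.chain_id, pres.ordinal, rres.chain_id, rres.ordinal)] = d
    return pairs


def runs_by_regex(flag_string):
    """Independent run-length oracle: lengths of maximal '1' stretches."""
    import re

    return [len(m.group()) for m in re.finditer("1+", flag_string)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_complex():
    """3-residue protein vs 2-nucleotide RNA with one designed contact."""
    return make_complex(
        {
            "A": [
                ("R", [(0.0, 0.0, 0.0)]),
                ("G", [(0.0, 0.0, 10.0)]),
                ("K", [(0.0, 0.0, 20.0)]),
            ]
        },
        {
            "B": [
                ("A", [(0.0, 0.0, 3.0)]),
                ("U", [(50.0, 0.0, 0.0)]),
            ]
        },
    )
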