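"""Structure parsing, altloc/hydrogen handling and PDB round-trips."""

import numpy as np
import pytest

from rnaiface.alphabets import UNKNOWN, map_modified_components
from rnaiface.errors import DatasetCriteriaError, ManifestError, StructureError
from rnaiface.structure_io import (
    DatasetCriteriaWarning,
    ManifestEntry,
    load_complex,
    load_manifest,
    write_structure,
)
from rnaiface.synthetic import SyntheticSpec, generate_complex

ENTRY = ManifestEntry(
    set_id="t", pdb_id="SYN0", protein_chains=("A",), rna_chains=("B",), group="other"
)

ALTLOC_PDB = """\
ATOM      1  N  AARG A   1       0.000   0.000   0.000  0.60 20.00           N
ATOM      2  CA AARG A   1       1.000   0.000   0.000  0.60 20.00           C
ATOM      3  N  BARG A   1       0.000   5.000   0.000  0.40 20.00           N
ATOM      4  CA BARG A   1       1.000   5.000   0.000  0.40 20.00           C
ATOM      5  N   GLY A   2       3.000   0.000   0.000  1.00 20.00           N
ATOM      6  H   GLY A   2       3.500   0.000   0.000  1.00 20.00           H
TER
ATOM      7  P     U B   1       0.000   0.000   9.000  1.00 20.00           P
ATOM      8  P     A B   2       6.000   0.000   9.000  1.00 20.00           P
ATOM      9  P     C B   3      12.000   0.000   9.000  1.00 20.00           P
ATOM     10  P     G B   4      18.000   0.000   9.000  1.00 20.00           G
HETATM   11  O   HOH B   5      40.000   0.000   9.000  1.00 20.00           O
END
"""


@pytest.fixture
def altloc_file(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


class TestLoadComplex:
    def test_altloc_keeps_highest_occupancy_conformer(self, altloc_file):
        with pytest.warns(DatasetCriteriaWarning):
            cx = load_complex(altloc_file, ENTRY)
        arg = cx.protein["A"][0]
        assert len(arg.heavy_atoms) == 2  # exactly one conformer retained
        assert all(a.xyz[1] == 0.0 for a in arg.heavy_atoms)  # the 0.60 one

    def test_hydrogens_and_waters_discarded(self, altloc_file):
        with pytest.warns(DatasetCriteriaWarning):
            cx = load_complex(altloc_file, ENTRY)
        gly = cx.protein["A"][1]
        assert [a.name for a in gly.heavy_atoms] == ["N"]
        assert len(cx.rna["B"]) == 4  # water dropped

    def test_short_polymers_warn_by_default_raise_when_strict(self, altloc_file):
        with pytest.warns(DatasetCriteriaWarning, match="dataset criteria"):
            load_complex(altloc_file, ENTRY)
        with pytest.raises(DatasetCriteriaError):
            load_complex(altloc_file, ENTRY, strict_criteria=True)

    def test_missing_chain_names_the_chain(self, altloc_file):
        entry = ManifestEntry(
            set_id="t", pdb_id="SYN0", protein_chains=("Z",), rna_chains=("B",)
        )
        with pytest.raises(ManifestError, match="'Z'"):
            load_complex(altloc_file, entry)

    def test_ordinals_strictly_increasing(self, altloc_file):
        with pytest.warns(DatasetCriteriaWarning):
            cx = load_complex(altloc_file, ENTRY)
        for kind in ("protein", "rna"):
            for chain in cx.chains(kind).values():
                ords = [r.ordinal for r in chain]
                assert ords == sorted(set(ords))


class TestModifiedComponents:
    @pytest.mark.parametrize(
        "raw, kind, expected",
        [
            ("PSU", "rna", "U"),
            ("1MA", "rna", "A"),
            ("5MC", "rna", "C"),
            ("7MG", "rna", "G"),
            ("MSE", "protein", "M"),
            ("XYZ", "rna", UNKNOWN),
            ("XYZ", "protein", UNKNOWN),
            ("ALA", "protein", "A"),
            ("U", "rna", "U"),
        ],
    )
    def test_parent_mapping(self, raw, kind, expected):
        assert map_modified_components(raw, kind) == expected


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(20))
    def test_write_then_load_preserves_everything(self, tmp_path, seed):
        spec = SyntheticSpec(n_residues=50, n_nucleotides=10, seed=seed)
        cx, _ = generate_complex(spec)
        path = write_structure(cx, tmp_path / f"rt{seed}.pdb")
        cx2 = load_complex(path, cx.entry)
        for kind in ("protein", "rna"):
            orig = list(cx.residues(kind))
            back = list(cx2.residues(kind))
            assert [r.code for r in orig] == [r.code for r in back]
            assert [r.ordinal for r in orig] == [r.ordinal for r in back]
            assert [r.author_number for r in orig] == [r.author_number for r in back]
            for a, b in zip(orig, back):
                assert np.abs(a.coords() - b.coords()).max() < 1e-3

    def test_two_loads_identical(self, tmp_path):
        cx, _ = generate_complex(SyntheticSpec(n_residues=40, n_nucleotides=8, seed=3))
        path = write_structure(cx, tmp_path / "det.pdb")
        a = load_complex(path, cx.entry)
        b = load_complex(path, cx.entry)
        for ra, rb in zip(a.residues("protein"), b.residues("protein")):
            assert ra.code == rb.code and np.array_equal(ra.coords(), rb.coords())

    def test_no_hydrogen_survives_loading(self, altloc_file):
        with pytest.warns(DatasetCriteriaWarning):
            cx = load_complex(altloc_file, ENTRY)
        for kind in ("protein", "rna"):
            for res in cx.residues(kind):
                assert all(a.element not in ("H", "D") for a in res.heavy_atoms)

    def test_empty_chain_refused(self, tmp_path):
        cx, _ = generate_complex(SyntheticSpec(n_residues=40, n_nucleotides=8, seed=1))
        cx.rna["B"] = []
        with pytest.raises(StructureError):
            write_structure(cx, tmp_path / "bad.pdb")

    def test_nonfinite_coordinate_refused(self, tmp_path):
        cx, _ = generate_complex(SyntheticSpec(n_residues=40, n_nucleotides=8, seed=1))
        res = cx.protein["A"][0]
        res.heavy_atoms[0] = res.heavy_atoms[0]._replace(xyz=(np.nan, 0.0, 0.0))
        with pytest.raises(StructureError):
            write_structure(cx, tmp_path / "bad.pdb")


class TestManifest:
    def test_tsv_and_json_agree(self, tmp_path):
        tsv = tmp_path / "m.tsv"
        tsv.write_text(
            "set_id\tpdb_id\tprotein_chains\trna_chains\torganism\tgroup\n"
            "asprs\t1IL2\tA\tB,C\tEscherichia coli\tecoli\n"
        )
        js = tmp_path / "m.json"
        js.write_text(
            '[{"set_id": "asprs", "pdb_id": "1IL2", "protein_chains": ["A"],'
            ' "rna_chains": ["B", "C"], "organism": "Escherichia coli", "group": "ecoli"}]'
        )
        assert load_manifest(tsv) == load_manifest(js)

    def test_overlapping_chain_lists_rejected(self):
        with pytest.raises(ManifestError):
            ManifestEntry(set_id="s", pdb_id="XXXX", protein_chains=("A",), rna_chains=("A",))

    def test_empty_chain_list_rejected(self):
        with pytest.raises(ManifestError):
            ManifestEntry(set_id="s", pdb_id="XXXX", protein_chains=(), rna_chains=("B",))
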