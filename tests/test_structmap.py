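"""Structure reading, chain mapping, distance computation and viz output."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xlsurf.classify import ResidueLink
from xlsurf.simulate import simulate_structure
from xlsurf.structmap import (
    ChainMapping,
    MappingError,
    SATISFIED,
    UNRESOLVED,
    VIOLATED,
    ca_distance,
    distance_report,
    map_links,
    read_structure,
    resolve_mapping,
    write_viz_script,
)


@pytest.fixture(scope="module")
def toy_structure(tmp_path_factory):
    links = [
        ResidueLink("P1", 194, "P2", 305),
        ResidueLink("P1", 196, "P2", 330),
        ResidueLink("P1", 10, "P1", 30),
    ]
    distances = [38.5, 12.0, 19.9]
    model, mappings, pdb_text = simulate_structure(links, distances, seed=3)
    path = tmp_path_factory.mktemp("struct") / "toy.pdb"
    path.write_text(pdb_text)
    return links, distances, model, mappings, path


class TestCaDistance:
    def test_three_four_five(self):
        assert ca_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_identity(self):
        assert ca_distance((1.5, -2.0, 9.0), (1.5, -2.0, 9.0)) == 0.0

    @given(
        st.lists(st.floats(-500, 500), min_size=6, max_size=6)
    )
    def test_against_explicit_formula(self, coords):
        p, q = coords[:3], coords[3:]
        expected = sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5
        assert ca_distance(p, q) == pytest.approx(expected, abs=1e-9)
        assert ca_distance(q, p) == pytest.approx(ca_distance(p, q), abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ca_distance((0, 0, float("nan")), (1, 1, 1))


class TestReadStructure:
    def test_round_trip_of_generated_pdb(self, toy_structure):
        _, _, model, _, path = toy_structure
        disk = read_structure(path)
        assert sorted(disk.chains) == sorted(model.chains)
        for chain_id, residues in model.chains.items():
            read_back = disk.chains[chain_id]
            assert [r.number for r in read_back] == [r.number for r in residues]
            assert [r.name for r in read_back] == [r.name for r in residues]
            for a, b in zip(residues, read_back):
                # PDB coordinate fields carry 3 decimals (parsed as float32).
                assert np.allclose(a.ca, b.ca, atol=1e-4)

    def test_residue_without_ca_kept(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  N   ALA A   2       3.800   0.000   0.000"
            "  1.00  0.00           N\n"
            "END\n"
        )
        model = read_structure(path)
        residues = model.chains["A"]
        assert [r.number for r in residues] == [1, 2]
        assert residues[0].ca is not None and residues[1].ca is None

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")


class TestResolveMapping:
    def test_offset_mapping_recovered(self, toy_structure):
        _, _, model, _, _ = toy_structure
        chain_seq = model.chain_sequence("A")
        # Protein whose positions 101.. correspond to the chain.
        protein = "G" * 100 + chain_seq
        mapping = resolve_mapping("P1", protein, model)
        assert mapping.source == "alignment"
        assert mapping.chain_id == "A"
        first_author = model.chains["A"][0].number
        assert mapping.author_number(101) == first_author

    def test_explicit_hint_used_verbatim(self, toy_structure):
        _, _, model, _, _ = toy_structure
        hint = ChainMapping("P1", "B", offset=0)
        assert resolve_mapping("P1", "IRRELEVANT", model, hint=hint) is hint

    def test_homodimer_tie_raises(self, toy_structure):
        _, _, model, _, _ = toy_structure
        duplicated = type(model)(
            {"X": model.chains["A"], "Y": model.chains["A"]}
        )
        with pytest.raises(MappingError, match="X.*Y"):
            resolve_mapping("P1", model.chain_sequence("A"), duplicated)

    def test_unalignable_sequence_raises(self, toy_structure):
        _, _, model, _, _ = toy_structure
        with pytest.raises(MappingError):
            resolve_mapping("P1", "WWWWWWWW", model)


class TestMapLinks:
    def test_planted_distances_and_statuses(self, toy_structure):
        links, distances, model, mappings, _ = toy_structure
        records = map_links(links, model, mappings, threshold=20.0)
        by_link = {r.link: r for r in records}
        for link, expected in zip(links, distances):
            record = by_link[link.canonical()]
            assert record.ca_distance == pytest.approx(expected, abs=1e-6)
            assert record.status == (SATISFIED if expected < 20 else VIOLATED)
        report = distance_report(records)
        assert report["max_violated_distance"] == pytest.approx(38.5, abs=1e-6)

    def test_threshold_monotonicity(self, toy_structure):
        links, _, model, mappings, _ = toy_structure
        loose = map_links(links, model, mappings, threshold=40.0)
        tight = map_links(links, model, mappings, threshold=10.0)
        for loose_rec, tight_rec in zip(loose, tight):
            if loose_rec.status == VIOLATED:
                assert tight_rec.status == VIOLATED

    def test_unmapped_accession_unresolved(self, toy_structure):
        _, _, model, mappings, _ = toy_structure
        ghost = [ResidueLink("P9", 5, "P1", 10)]
        (record,) = map_links(ghost, model, mappings, threshold=20.0)
        assert record.status == UNRESOLVED
        assert record.ca_distance is None

    def test_absent_residue_unresolved(self, toy_structure):
        _, _, model, mappings, _ = toy_structure
        beyond = [ResidueLink("P1", 9999, "P1", 10)]
        (record,) = map_links(beyond, model, mappings, threshold=20.0)
        assert record.status == UNRESOLVED


class TestVizScript:
    def test_pymol_tokens_golden(self, toy_structure, tmp_path):
        links, _, model, mappings, _ = toy_structure
        records = map_links(links, model, mappings, threshold=20.0)
        out = tmp_path / "links.pml"
        write_viz_script(records, out, dialect="pymol")
        lines = out.read_text().splitlines()
        assert len(lines) == 6  # 3 resolved links x (distance + color)
        assert sum(line.startswith("color red") for line in lines) == 1
        assert sum(line.startswith("color green") for line in lines) == 2
        assert lines[0].startswith("distance xl001,")

    def test_chimerax_dialect(self, toy_structure, tmp_path):
        links, _, model, mappings, _ = toy_structure
        records = map_links(links, model, mappings, threshold=20.0)
        out = tmp_path / "links.cxc"
        write_viz_script(records, out, dialect="chimerax")
        content = out.read_text()
        assert "@CA" in content and "color red" in content

    def test_empty_records_valid_script(self, tmp_path):
        out = tmp_path / "empty.pml"
        write_viz_script([], out, dialect="pymol")
        assert out.read_text() == ""

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_viz_script([], tmp_path / "x", dialect="vmd")


class TestSimulateStructure:
    def test_inconsistent_constraints_rejected(self):
        links = [
            ResidueLink("P1", 1, "P1", 2),
            ResidueLink("P1", 1, "P1", 2),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            simulate_structure(links, [10.0, 20.0], seed=0)

    def test_distance_count_mismatch(self):
        with pytest.raises(ValueError):
            simulate_structure([ResidueLink("P1", 1, "P1", 2)], [], seed=0)

    def test_shared_anchor_chain(self):
        links = [
            ResidueLink("P1", 1, "P1", 5),
            ResidueLink("P1", 5, "P1", 9),
        ]
        model, mappings, _ = simulate_structure(links, [10.0, 15.0], seed=0)
        records = map_links(links, model, mappings, threshold=20.0)
        assert [r.ca_distance for r in records] == pytest.approx([10.0, 15.0])
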