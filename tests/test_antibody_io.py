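"""PDB backbone reading, definitions tables, torso extraction, dihedral tables."""

import dataclasses

import numpy as np
import pytest

from hcdr3torso import antibody_io
from hcdr3torso.antibody_io import (
    ChainNotFoundError,
    DefinitionError,
    HCDR3Definition,
    TorsoExtractionError,
    extract_torso,
    locate_hcdr3_imgt,
    read_backbone,
    read_definitions,
    torso_dihedrals,
)
from hcdr3torso.fixtures import (
    TORSO_CHAIN_DEFINITION,
    BackboneSpec,
    ResidueSpec,
    build_backbone,
    torso_chain_spec,
    write_pdb,
)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {name[0]:>2s}"
    )


def _tripeptide_pdb():
    lines = []
    serial = 1
    for i, resname in enumerate(["GLY", "ALA", "SER"], start=1):
        for j, name in enumerate(["N", "CA", "C"]):
            lines.append(
                _pdb_line(serial, name, resname, "H", i + 10, 3.8 * i + j, 0.5 * j, 0.0)
            )
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def test_read_backbone_renumbers_from_one():
    chain = read_backbone(_tripeptide_pdb(), "H", source_id="toy")
    assert len(chain) == 3
    assert [r.index for r in chain.residues] == [1, 2, 3]
    assert chain.sequence == "GAS"


def test_read_backbone_altloc_keeps_highest_occupancy():
    lines = [
        _pdb_line(1, "N", "ALA", "H", 1, 0.0, 0.0, 0.0),
        _pdb_line(2, "CA", "ALA", "H", 1, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
        _pdb_line(3, "CA", "ALA", "H", 1, 9.0, 9.0, 9.0, occ=0.4, altloc="B"),
        _pdb_line(4, "C", "ALA", "H", 1, 2.0, 1.0, 0.0),
        _pdb_line(5, "N", "GLY", "H", 2, 3.0, 1.0, 0.0),
        _pdb_line(6, "CA", "GLY", "H", 2, 4.0, 1.0, 0.0),
        _pdb_line(7, "C", "GLY", "H", 2, 5.0, 2.0, 0.0),
    ]
    chain = read_backbone("\n".join(lines) + "\nEND\n", "H")
    assert chain.residue(1).ca == pytest.approx([1.0, 0.0, 0.0])


def test_read_backbone_drops_incomplete_residue(caplog):
    lines = [
        _pdb_line(1, "N", "ALA", "H", 1, 0.0, 0.0, 0.0),
        _pdb_line(2, "CA", "ALA", "H", 1, 1.0, 0.0, 0.0),
        _pdb_line(3, "C", "ALA", "H", 1, 2.0, 1.0, 0.0),
        _pdb_line(4, "CA", "GLY", "H", 2, 4.0, 1.0, 0.0),  # CA-only
        _pdb_line(5, "N", "SER", "H", 3, 6.0, 1.0, 0.0),
        _pdb_line(6, "CA", "SER", "H", 3, 7.0, 1.0, 0.0),
        _pdb_line(7, "C", "SER", "H", 3, 8.0, 2.0, 0.0),
    ]
    with caplog.at_level("WARNING"):
        chain = read_backbone("\n".join(lines) + "\nEND\n", "H")
    assert chain.sequence == "AS"
    assert [r.index for r in chain.residues] == [1, 2]
    assert any("dropped" in rec.message for rec in caplog.records)


def test_read_backbone_missing_chain_errors():
    with pytest.raises(ChainNotFoundError):
        read_backbone(_tripeptide_pdb(), "L")


def test_roundtrip_through_pdb_serialization(extended_chain):
    text = write_pdb(extended_chain)
    back = read_backbone(text, "A", source_id="rt")
    assert len(back) == len(extended_chain)
    for i in range(1, len(back) + 1):
        assert back.residue(i).ca == pytest.approx(
            extended_chain.residue(i).ca, abs=1e-3
        )


def test_read_definitions_basic_and_header():
    text = "pdb_file,chain_id,start,end\n1UYW.pdb,H,95,112\nx.pdb,A,50,60\n"
    defs = read_definitions(text)
    assert defs[0] == HCDR3Definition("1UYW.pdb", "H", 95, 112)
    assert len(defs) == 2


@pytest.mark.parametrize(
    "row",
    [
        "x.pdb,H,100,99",  # end before start
        "x.pdb,H,1,20",  # no preceding residue for phi(T1)
        "x.pdb,H,100,105",  # shorter than 8
        "first.pdb,H,95,ZZ",  # non-integer after data started
    ],
)
def test_read_definitions_row_errors(row):
    text = "a.pdb,H,95,112\n" + row + "\n"
    with pytest.raises(DefinitionError):
        read_definitions(text)
    assert len(read_definitions(text, strict=False)) == 1


def test_locate_hcdr3_by_anchor_motif():
    spec = BackboneSpec(
        residues=tuple(ResidueSpec(aa=c) for c in "SSCARDYWGQGTL")
    )
    chain = build_backbone(spec)
    located = locate_hcdr3_imgt(chain)
    assert located is not None
    start, end = located
    assert chain.sequence[start - 1 : end] == "ARDY"


def test_locate_hcdr3_no_motif_is_nocall():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec(aa=c) for c in "SSCARDYAGQGTL"))
    )
    assert locate_hcdr3_imgt(chain) is None


def test_locate_hcdr3_last_cys_wins():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec(aa=c) for c in "CTTCARDYWGQGT"))
    )
    start, end = locate_hcdr3_imgt(chain)
    assert chain.sequence[start - 1 : end] == "ARDY"


def test_extract_torso_indexing():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec() for _ in range(20)))
    )
    frag = extract_torso(chain, HCDR3Definition("t.pdb", "A", 5, 15))  # L=11
    assert [r.index for r in frag.t] == [5, 6, 7, 12, 13, 14, 15]
    # L=8: torso residues contiguous, T3 successor is T4
    frag8 = extract_torso(chain, HCDR3Definition("t.pdb", "A", 5, 12))
    assert [r.index for r in frag8.t] == [5, 6, 7, 9, 10, 11, 12]
    assert frag8.n_after_t3 == pytest.approx(chain.residue(8).n)


def test_extract_torso_boundary_errors():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec() for _ in range(20)))
    )
    with pytest.raises(DefinitionError):
        HCDR3Definition("t.pdb", "A", 5, 11)  # length 7
    with pytest.raises(TorsoExtractionError):
        extract_torso(chain, HCDR3Definition("t.pdb", "A", 12, 20))  # no FR4


def test_torso_dihedral_roundtrip_uniform_angles():
    angles = {p: {"phi": -120.0, "psi": 130.0} for p in
              ("T1", "T2", "T3", "T4", "T5", "T6", "T7")}
    chain = build_backbone(torso_chain_spec(angles))
    frag = extract_torso(chain, TORSO_CHAIN_DEFINITION)
    measured = torso_dihedrals(frag)
    for pos in measured:
        assert measured[pos]["phi"] == pytest.approx(-120.0, abs=1e-6)
        assert measured[pos]["psi"] == pytest.approx(130.0, abs=1e-6)


def test_torso_dihedral_roundtrip_per_position_angles(bulged_profile):
    angles = {
        p: {"phi": bulged_profile.phi[p].mean, "psi": bulged_profile.psi[p].mean}
        for p in ("T1", "T2", "T3", "T4", "T5", "T6", "T7")
    }
    chain = build_backbone(torso_chain_spec(angles))
    frag = extract_torso(chain, TORSO_CHAIN_DEFINITION)
    measured = torso_dihedrals(frag)
    for pos, expected in angles.items():
        assert measured[pos]["phi"] == pytest.approx(expected["phi"], abs=1e-6)
        assert measured[pos]["psi"] == pytest.approx(expected["psi"], abs=1e-6)


def test_missing_fr4_nitrogen_drops_only_psi_t7(caplog):
    angles = {p: {"phi": -120.0, "psi": 130.0} for p in
              ("T1", "T2", "T3", "T4", "T5", "T6", "T7")}
    chain = build_backbone(torso_chain_spec(angles))
    frag = extract_torso(chain, TORSO_CHAIN_DEFINITION)
    broken = dataclasses.replace(frag, fr4_n=None)
    with caplog.at_level("WARNING"):
        measured = torso_dihedrals(broken)
    assert measured["T7"]["psi"] is None
    present = [v for pos in measured for v in measured[pos].values() if v is not None]
    assert len(present) == 13


def test_renumbering_idempotent():
    chain = read_backbone(_tripeptide_pdb(), "H", source_id="toy")
    text = write_pdb(chain)
    again = read_backbone(text, "H", source_id="toy")
    assert [r.index for r in again.residues] == [r.index for r in chain.residues]
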