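"""Read antibody backbones from PDB files, apply HCDR3 definitions, extract torsos.

The HCDR3 is delimited (IMGT convention) by the conserved V-gene Cys and the
J-gene Trp of the W-G-x-G framework-4 motif: the loop starts immediately
after the Cys and ends immediately before the Trp. The torso is its first
three (T1-T3) and last four (T4-T7) residues; everything between is the head.

Residues are renumbered sequentially from 1 per chain, so definition tables
(pdb_file, chain_id, start, end) refer to this sequential numbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

_WGXG = re.compile(r"WG.G")


class ChainNotFoundError(ValueError):
    pass


class DefinitionError(ValueError):
    pass


class TorsoExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneResidue:
    """One residue's backbone: N/CA/C (O optional) plus identity and index."""

    aa: str
    index: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None = None

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"residue index {self.index} < 1")


@dataclass(frozen=True)
class ChainBackbone:
    source_id: str
    chain_id: str
    residues: tuple[BackboneResidue, ...]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def residue(self, index: int) -> BackboneResidue:
        """1-based sequential lookup."""
        return self.residues[index - 1]


@dataclass(frozen=True)
class HCDR3Definition:
    """One row of a definitions table: sequential 1-based inclusive bounds."""

    pdb_file: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start + 1 < 8:
            raise DefinitionError(
                f"{self.pdb_file}:{self.chain_id} HCDR3 {self.start}-{self.end} "
                "shorter than 8 residues"
            )
        if self.start <= 1:
            raise DefinitionError(
                f"{self.pdb_file}:{self.chain_id} start {self.start} leaves no "
                "preceding residue for phi(T1)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TorsoFragment:
    """Torso residues T1..T7 with the flanking atoms needed for all 14 dihedrals.

    Flanking atoms: C of the residue preceding T1 (for phi(T1)), N of the
    residue after T3 (for psi(T3)), C of the residue before T4 (for phi(T4)),
    and N/CA of the first framework-4 residue (for psi(T7) and the base
    pseudo-angles). For an 8-residue HCDR3 the head is empty and T3/T4 are
    adjacent.
    """

    source_id: str
    t: tuple[BackboneResidue, ...]  # exactly 7, T1..T7
    c_before_t1: np.ndarray
    n_after_t3: np.ndarray
    c_before_t4: np.ndarray
    fr4_n: np.ndarray
    fr4_ca: np.ndarray

    def __post_init__(self):
        if len(self.t) != 7:
            raise ValueError(f"torso needs 7 residues, got {len(self.t)}")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.t)


def _pick_altloc(atoms) -> gemmi.Atom | None:
    """Highest occupancy wins; ties go to the first-seen altloc."""
    best = None
    for atom in atoms:
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_backbone(pdb: str, chain_id: str, source_id: str = "") -> ChainBackbone:
    """Parse ATOM records of one chain into a sequentially renumbered backbone.

    Residues missing any of N/CA/C are dropped with a warning; altlocs are
    resolved by occupancy; HETATM records and waters are ignored.
    """
    if "\n" in pdb or pdb.lstrip().startswith(("ATOM", "HEADER", "MODEL", "REMARK")):
        structure = gemmi.read_pdb_string(pdb)
    else:
        structure = gemmi.read_pdb(pdb)
    if not source_id:
        source_id = structure.name or "unknown"
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"{source_id}: chain {chain_id!r} not found")
    residues = []
    index = 0
    for res in chain:
        if res.het_flag != "A":
            continue
        coords = {}
        for name in ("N", "CA", "C", "O"):
            atom = _pick_altloc([a for a in res if a.name == name])
            if atom is not None:
                coords[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if any(k not in coords for k in ("N", "CA", "C")):
            logger.warning(
                "%s:%s residue %s %s dropped: incomplete backbone",
                source_id, chain_id, res.seqid, res.name,
            )
            continue
        index += 1
        info = gemmi.find_tabulated_residue(res.name)
        aa = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
        residues.append(
            BackboneResidue(
                aa=aa if aa.isalpha() else "X",
                index=index,
                n=coords["N"],
                ca=coords["CA"],
                c=coords["C"],
                o=coords.get("O"),
            )
        )
    if not residues:
        raise ChainNotFoundError(
            f"{source_id}: chain {chain_id!r} has no complete backbone residues"
        )
    return ChainBackbone(source_id=source_id, chain_id=chain_id, residues=tuple(residues))


def read_definitions(csv_text: str, strict: bool = True) -> list[HCDR3Definition]:
    """Parse a comma-separated definitions table: pdb_file, chain_id, start, end.

    A leading header row (non-numeric start/end) is skipped. Other invalid
    rows raise :class:`DefinitionError` naming the row number, or are logged
    and skipped when ``strict`` is false.
    """
    definitions = []
    errors = []
    rows = [line.strip() for line in csv_text.splitlines()]
    first_data_row_seen = False
    for lineno, line in enumerate(rows, start=1):
        if not line:
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 4:
            errors.append(f"row {lineno}: expected 4 fields, got {len(fields)}")
            continue
        pdb_file, chain_id, start_s, end_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            if not first_data_row_seen:
                continue  # header
            errors.append(f"row {lineno}: non-integer start/end {start_s!r},{end_s!r}")
            continue
        first_data_row_seen = True
        try:
            definitions.append(HCDR3Definition(pdb_file, chain_id, start, end))
        except DefinitionError as exc:
            errors.append(f"row {lineno}: {exc}")
    if errors:
        if strict:
            raise DefinitionError("; ".join(errors))
        for err in errors:
            logger.warning("definitions: %s", err)
    return definitions


def locate_hcdr3_imgt(chain: ChainBackbone) -> tuple[int, int] | None:
    """Locate the HCDR3 by the conserved Cys ... Trp-Gly-x-Gly anchors.

    Returns 1-based sequential (start, end) = (Cys index + 1, Trp index - 1),
    where the Trp is the first residue of a W-G-x-G motif and the Cys is the
    last one before it. Returns None (an explicit no-call) when the anchors
    are absent or ambiguous; callers then need an explicit definition.
    """
    seq = chain.sequence
    candidates = []
    for m in _WGXG.finditer(seq):
        trp_pos = m.start()  # 0-based
        cys_pos = seq.rfind("C", 0, trp_pos)
        if cys_pos == -1 or trp_pos - cys_pos < 2:
            continue
        candidates.append((cys_pos + 2, trp_pos))  # 1-based start, end
    if not candidates:
        return None
    if len(set(candidates)) > 1:
        logger.warning(
            "%s:%s ambiguous HCDR3 anchors (%d candidates); no-call",
            chain.source_id, chain.chain_id, len(set(candidates)),
        )
        return None
    return candidates[0]


def extract_torso(chain: ChainBackbone, defn: HCDR3Definition) -> TorsoFragment:
    """Pull T1-T3 and T4-T7 plus flanking atoms from a renumbered chain."""
    if defn.end > len(chain):
        raise TorsoExtractionError(
            f"{chain.source_id}: HCDR3 end {defn.end} beyond chain ({len(chain)} residues)"
        )
    if defn.end + 1 > len(chain):
        raise TorsoExtractionError(
            f"{chain.source_id}: no framework-4 residue after HCDR3 end {defn.end}"
        )
    t123 = [chain.residue(i) for i in range(defn.start, defn.start + 3)]
    t4567 = [chain.residue(i) for i in range(defn.end - 3, defn.end + 1)]
    prev = chain.residue(defn.start - 1)
    after_t3 = chain.residue(defn.start + 3)
    before_t4 = chain.residue(defn.end - 4)
    fr4 = chain.residue(defn.end + 1)
    return TorsoFragment(
        source_id=f"{chain.source_id}:{chain.chain_id}",
        t=tuple(t123 + t4567),
        c_before_t1=prev.c,
        n_after_t3=after_t3.n,
        c_before_t4=before_t4.c,
        fr4_n=fr4.n,
        fr4_ca=fr4.ca,
    )


def torso_dihedrals(frag: TorsoFragment) -> dict[str, dict[str, float | None]]:
    """Measure phi and psi for T1..T7; unmeasurable angles come back as None.

    phi(Ti) = dihedral over C(i-1), N(i), CA(i), C(i);
    psi(Ti) = dihedral over N(i), CA(i), C(i), N(i+1). The successor of T3 is
    the first head residue (T4 itself for an 8-residue HCDR3) and the
    successor of T7 is the first framework-4 residue.
    """
    from .geometry import GeometryError, dihedral

    t = frag.t
    prev_c = [frag.c_before_t1, t[0].c, t[1].c, frag.c_before_t4, t[3].c, t[4].c, t[5].c]
    next_n = [t[1].n, t[2].n, frag.n_after_t3, t[4].n, t[5].n, t[6].n, frag.fr4_n]
    out: dict[str, dict[str, float | None]] = {}
    for i, res in enumerate(t):
        pos = f"T{i + 1}"
        angles: dict[str, float | None] = {}
        try:
            angles["phi"] = dihedral(prev_c[i], res.n, res.ca, res.c)
        except (GeometryError, TypeError):
            logger.warning("%s %s: phi unmeasurable", frag.source_id, pos)
            angles["phi"] = None
        try:
            angles["psi"] = dihedral(res.n, res.ca, res.c, next_n[i])
        except (GeometryError, TypeError):
            logger.warning("%s %s: psi unmeasurable", frag.source_id, pos)
            angles["psi"] = None
        out[pos] = angles
    return out


def torso_coordinates(frag: TorsoFragment, include_o: bool = True) -> np.ndarray:
    """Concatenated backbone coordinates of T1-T3 + T4-T7 for clustering.

    Uses N, CA, C per residue, plus O when present on every residue.
    """
    use_o = include_o and all(r.o is not None for r in frag.t)
    rows = []
    for r in frag.t:
        rows.extend([r.n, r.ca, r.c])
        if use_o:
            rows.append(r.o)
    return np.asarray(rows, dtype=float)
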