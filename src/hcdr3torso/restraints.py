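"""Circular-harmonic dihedral restraints in Rosetta constraint-file format.

A torso profile is turned into one restraint per non-excluded (position,
angle): the target x0 is the class circular mean and the width sigma the
class approximate std (floored at ``min_sigma`` so a degenerate single-member
class cannot emit a zero-width restraint). For a bulged torso this yields 13
restraints: 7 phi + 6 psi, psi(T4) omitted because it is bimodal within the
class. Serialization is one line per restraint:

    Dihedral <a1> <r1> <a2> <r2> <a3> <r3> <a4> <r4> CIRCULARHARMONIC <x0> <sigma>

with x0 and sigma in radians at 6 decimal places, directly consumable by the
external modelling engine. The penalty semantics are (delta/sigma)^2 with
delta the circular difference, continuous across the +-180 branch cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import wrap_degrees
from .profiles import POSITIONS, TorsoProfile

_BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class AtomRef:
    name: str  # N | CA | C
    residue: int

    def __post_init__(self):
        if self.name not in _BACKBONE_ATOMS:
            raise ValueError(f"atom {self.name!r} not a backbone atom")


@dataclass(frozen=True)
class DihedralRestraint:
    atoms: tuple[AtomRef, AtomRef, AtomRef, AtomRef]
    x0: float  # radians, (-pi, pi]
    sigma: float  # radians, > 0
    form: str = "CIRCULARHARMONIC"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (-math.pi < self.x0 <= math.pi + 1e-12):
            raise ValueError(f"x0 {self.x0} outside (-pi, pi]")
        names = tuple(a.name for a in self.atoms)
        if names not in (("C", "N", "CA", "C"), ("N", "CA", "C", "N")):
            raise ValueError(f"atom quadruple {names} matches neither phi nor psi")

    @property
    def kind(self) -> str:
        """'phi' or 'psi', inferred from the atom template."""
        return "phi" if self.atoms[0].name == "C" else "psi"

    @property
    def central_residue(self) -> int:
        """Residue whose phi/psi this restraint constrains."""
        return self.atoms[1].residue if self.kind == "phi" else self.atoms[0].residue


@dataclass(frozen=True)
class RestraintSet:
    restraints: tuple[DihedralRestraint, ...]
    provenance: str = field(default="", compare=False)

    def __len__(self) -> int:
        return len(self.restraints)


def derive_restraints(
    profile: TorsoProfile,
    hcdr3_start: int,
    hcdr3_length: int,
    min_sigma: float = 1.0,
) -> RestraintSet:
    """Map a torso profile onto target residue numbering and emit restraints.

    T1..T3 map to hcdr3_start .. hcdr3_start+2 and T4..T7 to the last four
    HCDR3 residues; ``min_sigma`` is a degrees floor on the width. Ordering
    is T1 through T7, phi before psi within a position.
    """
    if hcdr3_length < 8:
        raise ValueError(f"HCDR3 length {hcdr3_length} < 8: torso undefined")
    if hcdr3_start < 2:
        raise ValueError(f"HCDR3 start {hcdr3_start} leaves no residue for phi(T1)")
    end = hcdr3_start + hcdr3_length - 1
    residue_of = {
        "T1": hcdr3_start,
        "T2": hcdr3_start + 1,
        "T3": hcdr3_start + 2,
        "T4": end - 3,
        "T5": end - 2,
        "T6": end - 1,
        "T7": end,
    }
    restraints = []
    for pos in POSITIONS:
        res = residue_of[pos]
        for angle in ("phi", "psi"):
            if profile.is_excluded(pos, angle):
                continue
            summ = profile.summary(pos, angle)
            if summ is None or not math.isfinite(summ.mean):
                raise ValueError(f"profile {profile.label}: missing {pos} {angle}")
            if angle == "phi":
                atoms = (
                    AtomRef("C", res - 1),
                    AtomRef("N", res),
                    AtomRef("CA", res),
                    AtomRef("C", res),
                )
            else:
                atoms = (
                    AtomRef("N", res),
                    AtomRef("CA", res),
                    AtomRef("C", res),
                    AtomRef("N", res + 1),
                )
            # 6 decimal places in radians, matching the serialized precision,
            # so write -> parse is an exact identity
            restraints.append(
                DihedralRestraint(
                    atoms=atoms,
                    x0=round(math.radians(wrap_degrees(summ.mean)), 6),
                    sigma=round(math.radians(max(summ.std, min_sigma)), 6),
                )
            )
    return RestraintSet(
        restraints=tuple(restraints),
        provenance=f"profile={profile.label} start={hcdr3_start} length={hcdr3_length} "
        f"min_sigma={min_sigma}",
    )


def write_rosetta_constraints(rs: RestraintSet) -> str:
    """Serialize a RestraintSet to Rosetta constraint-file text."""
    lines = []
    for r in rs.restraints:
        atom_fields = " ".join(f"{a.name} {a.residue}" for a in r.atoms)
        lines.append(f"Dihedral {atom_fields} {r.form} {r.x0:.6f} {r.sigma:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_rosetta_constraints(text: str) -> RestraintSet:
    """Parse constraint-file text written by :func:`write_rosetta_constraints`."""
    restraints = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] != "Dihedral" or len(fields) != 12:
            raise ValueError(f"line {lineno}: not a Dihedral constraint: {line!r}")
        atoms = tuple(
            AtomRef(fields[1 + 2 * i], int(fields[2 + 2 * i])) for i in range(4)
        )
        form = fields[9]
        restraints.append(
            DihedralRestraint(
                atoms=atoms, x0=float(fields[10]), sigma=float(fields[11]), form=form
            )
        )
    return RestraintSet(restraints=tuple(restraints))


def restraint_penalty(
    rs: RestraintSet, measured: dict[tuple[int, str], float]
) -> float:
    """Sum of (circular deviation / sigma)^2 over all restraints.

    ``measured`` maps (residue index, 'phi'|'psi') to the measured angle in
    degrees. Zero when every angle sits exactly at its target.
    """
    missing = []
    total = 0.0
    for r in rs.restraints:
        key = (r.central_residue, r.kind)
        if key not in measured or measured[key] is None:
            missing.append(key)
            continue
        delta_deg = wrap_degrees(measured[key] - math.degrees(r.x0))
        total += (math.radians(delta_deg) / r.sigma) ** 2
    if missing:
        raise ValueError(f"missing measured angles for restraints: {missing}")
    return total
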