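"""Synthetic test inputs with known ground truth.

Backbones are built from internal coordinates (torsion-driven chain
extension, the NeRF construction) with standard ideal bond lengths and
angles, so measured phi/psi of the result equal the requested values to
numerical precision. On top of the builder sit class-conditional torso
samplers (wrapped-normal dihedrals around a profile, with the bimodal
psi(T4) drawn from a 50/50 mixture of modes 180 degrees apart) and decoy-set
generators with a controlled linear score-RMSD relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antibody_io import BackboneResidue, ChainBackbone, HCDR3Definition, TorsoFragment, extract_torso
from .geometry import wrap_degrees
from .profiles import POSITIONS, TorsoProfile

# Ideal backbone internal geometry (Engh-Huber-style standard values).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: Extended beta-strand dihedrals used for head/framework filler residues.
EXTENDED_PHI = -139.0
EXTENDED_PSI = 135.0


@dataclass(frozen=True)
class ResidueSpec:
    aa: str = "A"
    phi: float = EXTENDED_PHI  # ignored for the first residue
    psi: float = EXTENDED_PSI  # ignored for the last residue
    omega: float = 180.0  # peptide bond to the next residue


@dataclass(frozen=True)
class BackboneSpec:
    residues: tuple[ResidueSpec, ...]
    source_id: str = "synthetic"
    chain_id: str = "A"

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("backbone spec needs at least 2 residues")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: BackboneSpec) -> ChainBackbone:
    """Realize a backbone in 3D from per-residue phi/psi/omega.

    phi of the first residue and psi/omega of the last are unused. Measured
    dihedrals of the result match the spec to ~1e-6 degrees.
    """
    res = spec.residues
    # Seed the first residue in a canonical frame.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms = [[n0, ca0, c0]]
    for i in range(len(res) - 1):
        n_prev, ca_prev, c_prev = atoms[-1]
        n_new = place_atom(n_prev, ca_prev, c_prev,
                           BOND_C_N, ANGLE_CA_C_N, res[i].psi)
        ca_new = place_atom(ca_prev, c_prev, n_new,
                            BOND_N_CA, ANGLE_C_N_CA, res[i].omega)
        c_new = place_atom(c_prev, n_new, ca_new,
                           BOND_CA_C, ANGLE_N_CA_C, res[i + 1].phi)
        atoms.append([n_new, ca_new, c_new])
    residues = tuple(
        BackboneResidue(aa=res[i].aa, index=i + 1, n=a[0], ca=a[1], c=a[2])
        for i, a in enumerate(atoms)
    )
    return ChainBackbone(source_id=spec.source_id, chain_id=spec.chain_id,
                         residues=residues)


def wrapped_normal(rng: np.random.Generator, mean: float, std: float,
                   size: int | None = None):
    """Draw from a normal in degrees and wrap onto (-180, 180]."""
    draws = rng.normal(mean, std, size=size)
    if size is None:
        return wrap_degrees(float(draws))
    return np.array([wrap_degrees(float(d)) for d in draws])


# Layout used when realizing sampled torsos as 3D chains: one framework
# residue, T1-T3, a 9-residue extended head, T4-T7, one framework-4 residue.
_HEAD_LEN = 9
TORSO_CHAIN_DEFINITION = HCDR3Definition(
    pdb_file="synthetic", chain_id="A", start=2, end=2 + 3 + _HEAD_LEN + 4 - 1
)


def torso_chain_spec(angles: dict[str, dict[str, float]],
                     sequence: str = "ARDGYEY",
                     source_id: str = "synthetic") -> BackboneSpec:
    """BackboneSpec realizing the given torso phi/psi inside a filler chain."""
    specs = [ResidueSpec(aa="G")]  # preceding framework residue
    for i, pos in enumerate(("T1", "T2", "T3")):
        specs.append(ResidueSpec(aa=sequence[i], phi=angles[pos]["phi"],
                                 psi=angles[pos]["psi"]))
    specs.extend(ResidueSpec(aa="G") for _ in range(_HEAD_LEN))
    for i, pos in enumerate(("T4", "T5", "T6", "T7")):
        specs.append(ResidueSpec(aa=sequence[3 + i], phi=angles[pos]["phi"],
                                 psi=angles[pos]["psi"]))
    specs.append(ResidueSpec(aa="G"))  # first framework-4 residue
    return BackboneSpec(residues=tuple(specs), source_id=source_id)


def sample_class_torsos(profile: TorsoProfile, n: int, seed: int,
                        sequence: str = "ARDGYEY") -> list[TorsoFragment]:
    """Sample n torso fragments from a class profile, realized as 3D backbones.

    Non-excluded angles are independent wrapped normals at the profile's
    (mean, std); the excluded bimodal psi(T4) is a 50/50 mixture of the
    profile mode and the mode 180 degrees away.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    fragments = []
    for k in range(n):
        angles: dict[str, dict[str, float]] = {}
        for pos in POSITIONS:
            angles[pos] = {}
            for angle in ("phi", "psi"):
                summ = profile.summary(pos, angle)
                mean = summ.mean
                if profile.is_excluded(pos, angle) and rng.random() < 0.5:
                    mean = wrap_degrees(mean + 180.0)
                angles[pos][angle] = wrapped_normal(rng, mean, summ.std)
        spec = torso_chain_spec(angles, sequence=sequence,
                                source_id=f"{profile.label}-{k}")
        chain = build_backbone(spec)
        fragments.append(extract_torso(chain, TORSO_CHAIN_DEFINITION))
    return fragments


@dataclass(frozen=True)
class DecoySet:
    native: ChainBackbone
    decoys: tuple[ChainBackbone, ...]
    scores: pd.DataFrame  # columns: model_id, score
    true_rmsd16: dict[str, float] = field(default_factory=dict)
    loop: tuple[int, int] = (0, 0)


def make_decoy_set(
    native_spec: BackboneSpec,
    loop: tuple[int, int],
    n: int,
    noise_deg: float,
    score_slope: float = 1.0,
    score_intercept: float = -20.0,
    score_noise: float = 0.5,
    seed: int = 0,
) -> DecoySet:
    """Generate loop decoys by perturbing loop dihedrals of an ideal native.

    Each decoy perturbs phi/psi of the loop residues by wrapped-normal noise
    of width ``noise_deg``; its score is
    ``score_slope * rmsd16 + score_intercept + N(0, score_noise)``, so the
    true score-RMSD relationship is known exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .evalmetrics import loop_rmsd, rmsd16 as _rmsd16

    rng = np.random.default_rng(seed)
    native = build_backbone(native_spec)
    start, end = loop
    loop_len = end - start + 1
    decoys = []
    rows = []
    truth = {}
    for k in range(n):
        residues = []
        for i, rs in enumerate(native_spec.residues, start=1):
            if start <= i <= end and noise_deg > 0:
                residues.append(ResidueSpec(
                    aa=rs.aa,
                    phi=wrapped_normal(rng, rs.phi, noise_deg),
                    psi=wrapped_normal(rng, rs.psi, noise_deg),
                    omega=rs.omega,
                ))
            else:
                residues.append(rs)
        model_id = f"decoy_{k:04d}"
        decoy = build_backbone(BackboneSpec(residues=tuple(residues),
                                            source_id=model_id))
        r = loop_rmsd(decoy, native, loop)
        r16 = _rmsd16(r, loop_len)
        score = score_slope * r16 + score_intercept + rng.normal(0.0, score_noise)
        decoys.append(decoy)
        truth[model_id] = r16
        rows.append({"model_id": model_id, "score": score})
    return DecoySet(
        native=native,
        decoys=tuple(decoys),
        scores=pd.DataFrame(rows),
        true_rmsd16=truth,
        loop=loop,
    )


def write_pdb(chain: ChainBackbone) -> str:
    """Serialize a backbone as PDB ATOM records (N, CA, C per residue)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR", "X": "UNK",
    }
    lines = []
    serial = 1
    for res in chain.residues:
        resname = three.get(res.aa, "UNK")
        for name, coord in (("N", res.n), ("CA", res.ca), ("C", res.c), ("O", res.o)):
            if coord is None:
                continue
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {resname:>3s} {chain.chain_id}"
                f"{res.index:4d}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
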