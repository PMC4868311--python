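"""Classify torsos as bulged / non-bulged, base pseudo-angles, motif statistics.

The two torso classes are separated most cleanly by the psi angle at T6
(about -30 degrees in bulged torsos, where the C-terminal beta-strand pairing
is broken, versus about +129 in non-bulged). The classifier here scores a
torso against each class profile with a std-scaled circular RMS deviation
over all non-excluded measurable angles, then accepts the nearer class only
if the observed psi(T6) falls within ``sigma_mult`` standard deviations of
that class's psi(T6) mean; otherwise the torso is called indeterminate.
This closed-form rule is a deterministic stand-in for re-clustering a new
structure against the curated set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .antibody_io import TorsoFragment
from .geometry import dihedral, planar_angle, wrap_degrees
from .profiles import POSITIONS, TorsoProfile

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Classification:
    label: str  # "bulged" | "non-bulged" | "indeterminate"
    distances: dict[str, float]
    reason: str = ""


@dataclass(frozen=True)
class TorsoBaseGeometry:
    """Pseudo-angles over Calpha atoms at the torso base.

    alpha101: pseudodihedral over Calpha of T5, T6, T7 and the first
    framework-4 residue; tau101: planar pseudo-angle over Calpha of T6, T7
    and the first framework-4 residue.
    """

    alpha101: float
    tau101: float


@dataclass(frozen=True)
class BulgedWindow:
    """Reference windows (mean, sigma) for tau101/alpha101 membership tests.

    The reference means and sigmas are external literature values and must be
    supplied explicitly; there are no defaults.
    """

    tau_mean: float
    tau_sigma: float
    alpha_mean: float
    alpha_sigma: float
    multiplier: float = 3.0


@dataclass(frozen=True)
class MotifReport:
    frequencies: pd.DataFrame  # 7 positions x 20 residues, fractions
    frac_rk_t2: float
    frac_d_t6: float
    frac_both: float
    n: int


def _class_distance(measured, profile: TorsoProfile) -> float | None:
    """Std-scaled circular RMS deviation over non-excluded measurable angles."""
    devs = []
    for pos in POSITIONS:
        for angle in ("phi", "psi"):
            if profile.is_excluded(pos, angle):
                continue
            value = measured.get(pos, {}).get(angle)
            if value is None:
                continue
            summ = profile.summary(pos, angle)
            sigma = max(summ.std, 1e-9)
            devs.append((wrap_degrees(value - summ.mean) / sigma) ** 2)
    if not devs:
        return None
    return float(np.sqrt(np.mean(devs)))


def classify_torso(
    measured: dict[str, dict[str, float | None]],
    bulged: TorsoProfile,
    non_bulged: TorsoProfile,
    sigma_mult: float = 3.0,
) -> Classification:
    """Label a torso by its measured dihedrals against the two class profiles.

    ``measured`` maps position (T1..T7) to {"phi": deg, "psi": deg}; angles
    offset by multiples of 360 are handled. Requires a measured psi(T6).
    """
    psi_t6 = measured.get("T6", {}).get("psi")
    if psi_t6 is None:
        return Classification(
            label="indeterminate", distances={}, reason="psi(T6) not measured"
        )
    distances = {}
    for profile in (bulged, non_bulged):
        d = _class_distance(measured, profile)
        if d is not None:
            distances[profile.label] = d
    winner = min(distances, key=lambda k: distances[k])
    win_profile = bulged if winner == bulged.label else non_bulged
    gate = win_profile.psi["T6"]
    if abs(wrap_degrees(psi_t6 - gate.mean)) <= sigma_mult * gate.std:
        return Classification(label=winner, distances=distances)
    return Classification(
        label="indeterminate",
        distances=distances,
        reason=f"psi(T6) outside {sigma_mult} sigma of {winner} mean",
    )


def base_geometry(frag: TorsoFragment) -> TorsoBaseGeometry:
    """Compute alpha101/tau101 from Calpha atoms of T5, T6, T7 and FR4."""
    if frag.fr4_ca is None:
        raise ValueError(f"{frag.source_id}: framework-4 Calpha missing")
    t5, t6, t7 = frag.t[4].ca, frag.t[5].ca, frag.t[6].ca
    return TorsoBaseGeometry(
        alpha101=dihedral(t5, t6, t7, frag.fr4_ca),
        tau101=planar_angle(t6, t7, frag.fr4_ca),
    )


def in_bulged_window(g: TorsoBaseGeometry, window: BulgedWindow) -> bool:
    """True iff tau101 and alpha101 both lie in mean +- multiplier*sigma.

    Intervals are closed; the alpha101 comparison is circular.
    """
    if window is None:
        raise ValueError("bulged-window reference means/sigmas are required")
    tau_ok = abs(g.tau101 - window.tau_mean) <= window.multiplier * window.tau_sigma
    alpha_ok = (
        abs(wrap_degrees(g.alpha101 - window.alpha_mean))
        <= window.multiplier * window.alpha_sigma
    )
    return bool(tau_ok and alpha_ok)


def motif_stats(sequences: list[str]) -> MotifReport:
    """Position frequencies and Arg/Lys(T2)-Asp(T6) motif fractions.

    Each sequence must be 7 letters over the standard amino-acid alphabet;
    'X' is allowed but excluded from per-position denominators.
    """
    if not sequences:
        raise ValueError("no torso sequences supplied")
    for i, seq in enumerate(sequences):
        if len(seq) != 7:
            raise ValueError(f"sequence {i} ({seq!r}) is not 7 residues")
        bad = set(seq.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"sequence {i} ({seq!r}): invalid letters {sorted(bad)}")
    seqs = [s.upper() for s in sequences]
    counts = np.zeros((7, len(AMINO_ACIDS)), dtype=int)
    for seq in seqs:
        for pos, aa in enumerate(seq):
            if aa != "X":
                counts[pos, AMINO_ACIDS.index(aa)] += 1
    denom = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(denom > 0, counts / denom, 0.0)
    frame = pd.DataFrame(freqs, index=list(POSITIONS), columns=list(AMINO_ACIDS))

    t2_known = [s for s in seqs if s[1] != "X"]
    t6_known = [s for s in seqs if s[5] != "X"]
    both_known = [s for s in seqs if s[1] != "X" and s[5] != "X"]
    frac_rk = sum(s[1] in "RK" for s in t2_known) / len(t2_known) if t2_known else 0.0
    frac_d = sum(s[5] == "D" for s in t6_known) / len(t6_known) if t6_known else 0.0
    frac_both = (
        sum(s[1] in "RK" and s[5] == "D" for s in both_known) / len(both_known)
        if both_known
        else 0.0
    )
    return MotifReport(
        frequencies=frame,
        frac_rk_t2=frac_rk,
        frac_d_t6=frac_d,
        frac_both=frac_both,
        n=len(seqs),
    )
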