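"""Per-position dihedral profiles for the HCDR3 torso classes.

A :class:`TorsoProfile` holds, for each of the seven torso positions T1..T7,
a circular summary of the phi and psi angles observed in a torso class
(bulged or non-bulged), plus the set of measurements excluded from restraint
derivation and classification. By default psi(T4) is excluded: it is bimodal
within both torso classes, with the two sub-conformations roughly 180 degrees
apart, so a single mean/std pair misrepresents it.

The module ships reference profiles derived from clustering curated human and
mouse antibody crystal structures at a 2 A radius: 218 bulged and 38
non-bulged torsos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .circstats import CircularSummary

POSITIONS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7")

#: (position, angle) measurements excluded by default (bimodal psi at T4).
DEFAULT_EXCLUDED = frozenset({("T4", "psi")})


@dataclass(frozen=True)
class TorsoProfile:
    """Class-conditional phi/psi circular summaries for torso positions T1..T7."""

    label: str
    phi: dict[str, CircularSummary]
    psi: dict[str, CircularSummary]
    excluded: frozenset[tuple[str, str]] = field(default=DEFAULT_EXCLUDED)

    def __post_init__(self):
        for table, name in ((self.phi, "phi"), (self.psi, "psi")):
            missing = [p for p in POSITIONS if p not in table]
            if missing:
                raise ValueError(f"{self.label}: missing {name} for {missing}")
        bad = [e for e in self.excluded if e[0] not in POSITIONS or e[1] not in ("phi", "psi")]
        if bad:
            raise ValueError(f"{self.label}: invalid exclusions {bad}")

    def summary(self, position: str, angle: str) -> CircularSummary:
        if angle == "phi":
            return self.phi[position]
        if angle == "psi":
            return self.psi[position]
        raise KeyError(angle)

    def is_excluded(self, position: str, angle: str) -> bool:
        return (position, angle) in self.excluded

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per position with mean/std/n for phi and psi."""
        rows = []
        for p in POSITIONS:
            rows.append(
                {
                    "position": p,
                    "phi_mean": self.phi[p].mean,
                    "phi_std": self.phi[p].std,
                    "psi_mean": self.psi[p].mean,
                    "psi_std": self.psi[p].std,
                    "n": self.phi[p].n,
                }
            )
        return pd.DataFrame(rows)


def profile_from_table(
    label: str,
    rows: dict[str, tuple[float, float, float, float]],
    n: int,
    excluded: frozenset[tuple[str, str]] = DEFAULT_EXCLUDED,
) -> TorsoProfile:
    """Build a TorsoProfile from (phi_mean, phi_std, psi_mean, psi_std) rows."""
    phi = {}
    psi = {}
    for pos, (pm, ps, qm, qs) in rows.items():
        phi[pos] = CircularSummary(mean=pm, resultant_length=float("nan"), std=ps, n=n,
                                   label=f"{label}/{pos}/phi")
        psi[pos] = CircularSummary(mean=qm, resultant_length=float("nan"), std=qs, n=n,
                                   label=f"{label}/{pos}/psi")
    return TorsoProfile(label=label, phi=phi, psi=psi, excluded=excluded)


# Reference consensus measurements (degrees): phi mean, phi std, psi mean,
# psi std per torso position, from 2 A clustering of curated antibody
# crystal structures.
_BULGED_ROWS = {
    "T1": (-145.0, 9.0, 148.0, 12.0),
    "T2": (-101.0, 22.0, 142.0, 13.0),
    "T3": (-107.0, 32.0, 137.0, 33.0),
    "T4": (-121.0, 49.0, 161.0, 48.0),
    "T5": (-95.0, 35.0, 98.0, 26.0),
    "T6": (-87.0, 18.0, -30.0, 26.0),
    "T7": (-126.0, 14.0, 134.0, 10.0),
}
_NON_BULGED_ROWS = {
    "T1": (-146.0, 12.0, 145.0, 16.0),
    "T2": (-109.0, 20.0, 136.0, 26.0),
    "T3": (-119.0, 44.0, 138.0, 51.0),
    "T4": (-82.0, 49.0, 3.0, 59.0),
    "T5": (-126.0, 43.0, 136.0, 53.0),
    "T6": (-118.0, 34.0, 129.0, 24.0),
    "T7": (-125.0, 19.0, 136.0, 11.0),
}

BULGED_N = 218
NON_BULGED_N = 38


def reference_profile(label: str) -> TorsoProfile:
    """The shipped consensus profile for ``"bulged"`` or ``"non-bulged"``."""
    if label == "bulged":
        return profile_from_table("bulged", _BULGED_ROWS, BULGED_N)
    if label in ("non-bulged", "non_bulged", "nonbulged"):
        return profile_from_table("non-bulged", _NON_BULGED_ROWS, NON_BULGED_N)
    raise KeyError(f"unknown torso class {label!r}")


def profile_to_csv(profile: TorsoProfile) -> str:
    """Serialize a profile as CSV (position, phi mean/std, psi mean/std, n)."""
    return profile.to_frame().to_csv(index=False)


def profile_from_csv(text: str, label: str,
                     excluded: frozenset[tuple[str, str]] = DEFAULT_EXCLUDED) -> TorsoProfile:
    """Read a profile CSV written by :func:`profile_to_csv`."""
    import io

    df = pd.read_csv(io.StringIO(text))
    rows = {
        r.position: (float(r.phi_mean), float(r.phi_std), float(r.psi_mean), float(r.psi_std))
        for r in df.itertuples()
    }
    n = int(df["n"].iloc[0]) if "n" in df else 0
    return profile_from_table(label, rows, n, excluded=excluded)
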