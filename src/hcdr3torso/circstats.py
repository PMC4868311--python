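"""Circular mean and approximate circular standard deviation for dihedral samples.

Backbone dihedrals live on the circle, so the arithmetic mean fails across the
+-180 branch cut (the mean of 170 and -170 is 180, not 0). The mean direction
is taken as atan2(sum sin a_n, sum cos a_n); dispersion comes from the mean
resultant length R of the unit vectors (sin a_n, cos a_n): the default
approximate standard deviation is sqrt(2(1 - R)), with the asymptotically
equivalent sqrt(-2 ln R) available as a variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: R below which the mean direction is treated as undefined (uniform sample).
UNIFORM_RESULTANT_TOL = 1e-9


class UndefinedMeanError(ValueError):
    """The sample's resultant vector is (numerically) zero: no mean direction."""


@dataclass(frozen=True)
class AngleSample:
    """A labelled sample of angles in degrees.

    The canonical range is (-180, 180]; angles offset by full turns are
    accepted and equivalent, since all statistics go through sin/cos.
    """

    label: str
    angles: tuple[float, ...]

    def __post_init__(self):
        if len(self.angles) < 1:
            raise ValueError(f"{self.label}: empty angle sample")
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))
        for a in self.angles:
            if not np.isfinite(a):
                raise ValueError(f"{self.label}: non-finite angle {a}")

    @property
    def n(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class CircularSummary:
    """Circular mean, mean resultant length R, approximate std, sample size."""

    mean: float
    resultant_length: float
    std: float
    n: int
    label: str = field(default="", compare=False)


def _resultant(angles_deg: np.ndarray) -> tuple[float, float, float]:
    rad = np.radians(angles_deg)
    s = float(np.sum(np.sin(rad)))
    c = float(np.sum(np.cos(rad)))
    r = float(np.hypot(s, c) / len(angles_deg))
    return s, c, r


def circ_mean(sample: AngleSample) -> float:
    """Circular mean direction in degrees, in (-180, 180].

    Raises
    ------
    UndefinedMeanError
        If the mean resultant length is numerically zero (a uniform or
        perfectly antipodal sample has no preferred direction).
    """
    arr = np.asarray(sample.angles, dtype=float)
    s, c, r = _resultant(arr)
    if r < UNIFORM_RESULTANT_TOL:
        raise UndefinedMeanError(
            f"{sample.label}: resultant length {r:.2e} below "
            f"{UNIFORM_RESULTANT_TOL}; circular mean undefined"
        )
    mean = np.degrees(np.arctan2(s, c))
    from .geometry import wrap_degrees

    return wrap_degrees(float(mean))


def circ_std_approx(sample: AngleSample, method: str = "approx") -> float:
    """Approximate circular standard deviation in degrees.

    ``method="approx"`` uses sqrt(2(1 - R)); ``method="log"`` the
    asymptotically equivalent sqrt(-2 ln R). Both vanish as R -> 1 and are
    monotonically decreasing in R.
    """
    arr = np.asarray(sample.angles, dtype=float)
    _, _, r = _resultant(arr)
    if method == "approx":
        std_rad = np.sqrt(max(0.0, 2.0 * (1.0 - r)))
    elif method == "log":
        std_rad = np.sqrt(-2.0 * np.log(r)) if r > 0 else np.inf
    else:
        raise ValueError(f"unknown std method {method!r}")
    return float(np.degrees(std_rad))


def summarize(sample: AngleSample, method: str = "approx") -> CircularSummary:
    """Bundle circular mean, resultant length, approximate std and n."""
    arr = np.asarray(sample.angles, dtype=float)
    _, _, r = _resultant(arr)
    return CircularSummary(
        mean=circ_mean(sample),
        resultant_length=r,
        std=circ_std_approx(sample, method=method),
        n=sample.n,
        label=sample.label,
    )
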