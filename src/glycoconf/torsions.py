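"""Glycosidic dihedral time series and circular statistics.

Angles are degrees wrapped to (−180, 180] under the IUPAC sign
convention (cis = 0°, clockwise positive looking from the second atom
toward the third).  Averages and spreads use directional statistics so
that series straddling ±180° are handled correctly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "TorsionSeries",
    "CircularStats",
    "wrap_angles",
    "dihedral",
    "dihedral_trajectory",
    "extract_linkage_torsions",
    "circular_mean_sd",
]


def wrap_angles(angles) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class TorsionSeries:
    """A dihedral time series for one torsion of one linkage."""

    name: str  # e.g. "A:2(1->4)A:1/psi"
    values: np.ndarray  # degrees in (-180, 180]
    frame_interval_ps: float

    def __post_init__(self):
        object.__setattr__(self, "values", wrap_angles(self.values))

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def total_time_us(self) -> float:
        return self.n_frames * self.frame_interval_ps * 1e-6


def dihedral_trajectory(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral (degrees) for stacked position quadruples.

    Accepts arrays of shape (..., 3); broadcasting over leading axes.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    bad = (
        (np.linalg.norm(b1, axis=-1) < 1e-10)
        | (b2n < 1e-10)
        | (np.linalg.norm(b3, axis=-1) < 1e-10)
        | (np.linalg.norm(n1, axis=-1) < 1e-10)
        | (np.linalg.norm(n2, axis=-1) < 1e-10)
    )
    if np.any(bad):
        raise ValueError(
            "degenerate dihedral geometry (coincident or collinear atoms) "
            f"at frame index {np.argwhere(bad).ravel()[:5]}"
        )
    x = np.einsum("...k,...k->...", n1, n2)
    y = np.einsum("...k,...k->...", np.cross(n1, n2), b2 / b2n[..., None])
    return wrap_angles(np.degrees(np.arctan2(y, x)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, degrees in (−180, 180]."""
    return float(dihedral_trajectory(p1, p2, p3, p4))


def extract_linkage_torsions(
    trajectory: np.ndarray,
    topology,
    frame_interval_ps: float = 10.0,
) -> dict[str, TorsionSeries]:
    """One :class:`TorsionSeries` per torsion quadruple of every linkage.

    Parameters
    ----------
    trajectory : (n_frames, n_atoms, 3) array
        Coordinates in the structure's atom order, Å.
    topology : GlycanTopology
        Resolved linkage definitions.
    frame_interval_ps : float
        Time between stored frames (the trajectory stride), ps.
    """
    coords = np.asarray(trajectory, dtype=float)
    if coords.ndim != 3 or coords.shape[-1] != 3:
        raise ValueError(f"expected (n_frames, n_atoms, 3), got {coords.shape}")
    out: dict[str, TorsionSeries] = {}
    for link in topology.linkages:
        for torsion_name in link.torsions:
            idx = topology.torsion_indices(link, torsion_name)
            if max(idx) >= coords.shape[1]:
                raise ValueError(
                    f"torsion {torsion_name} of {link.linkage_id} refers to "
                    f"atom index {max(idx)} outside the trajectory "
                    f"({coords.shape[1]} atoms)"
                )
            values = dihedral_trajectory(
                coords[:, idx[0]], coords[:, idx[1]],
                coords[:, idx[2]], coords[:, idx[3]],
            )
            if np.any(~np.isfinite(values)):
                raise ValueError(
                    f"non-finite dihedral in {link.linkage_id}/{torsion_name}"
                )
            key = f"{link.linkage_id}/{torsion_name}"
            out[key] = TorsionSeries(
                name=key, values=values, frame_interval_ps=frame_interval_ps
            )
    return out


class CircularStats(NamedTuple):
    mean: float  # degrees in (-180, 180]; NaN when undefined
    sd: float    # circular standard deviation, degrees
    defined: bool


def circular_mean_sd(series, resultant_tol: float = 1e-12) -> CircularStats:
    """Circular mean and standard deviation of angles in degrees.

    The mean is the direction of the resultant of unit vectors; the
    spread is the directional SD ``sqrt(−2 ln R̄)`` (in degrees).  A
    vanishing resultant (e.g. a uniform distribution) leaves the mean
    undefined and sets the flag accordingly.
    """
    a = np.radians(np.asarray(series, dtype=float))
    if a.size == 0:
        raise ValueError("empty angle series")
    s = np.sin(a).mean()
    c = np.cos(a).mean()
    rbar = math.hypot(s, c)
    if rbar < resultant_tol:
        return CircularStats(math.nan, math.nan, False)
    mean = float(wrap_angles(math.degrees(math.atan2(s, c))))
    sd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(rbar))))
    return CircularStats(mean, sd, True)
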