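"""Cremer–Pople puckering coordinates and canonical conformer naming.

Six-membered ring shapes are described by the Cremer–Pople (CP) triple
``(Q, theta, phi)``: a total puckering amplitude ``Q`` (Å), a polar angle
``theta`` (0–180°, chairs at the poles) and an azimuthal phase ``phi``
(0–360°, boats and skew-boats around the equator).  The CP mean plane is
the plane through the ring's geometric centre for which the out-of-plane
displacements carry no m=1 Fourier component; the m=2 component gives
``(q2, phi)`` and the alternating m=3 component gives ``q3``, with
``Q² = q2² + q3²`` and ``theta = arccos(q3/Q)``.

Canonical conformers (2 chairs, 6 boats, 6 skew-boats, 12 envelopes,
12 half-chairs) are named from the signs of the out-of-plane
displacements of their ideal geometries — ring atoms above the mean
plane become superscript locants and atoms below become subscripts — so
the familiar ⁴C₁ / ¹C₄ / ²C₅ conventions emerge from the ring's own atom
labels rather than from a hard-coded lookup keyed to one sugar family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "PLANARITY_Q",
    "D_PYRANOSE_LABELS",
    "L_FUCOSE_LABELS",
    "NEUAC_LABELS",
    "PuckerCoordinates",
    "CanonicalPucker",
    "cremer_pople",
    "cremer_pople_trajectory",
    "invert_cremer_pople",
    "canonical_puckers",
    "assign_canonical_name",
    "assign_theta_region",
    "convergence_monitor",
]

#: amplitude below which theta/phi are meaningless (coordinate-chart pole)
PLANARITY_Q = 0.05

#: per-position name locants for the common ring circuits
D_PYRANOSE_LABELS = ("O", "1", "2", "3", "4", "5")  # O5-C1-C2-C3-C4-C5
L_FUCOSE_LABELS = D_PYRANOSE_LABELS  # same circuit, L-configuration
NEUAC_LABELS = ("O", "2", "3", "4", "5", "6")  # O6-C2-C3-C4-C5-C6

# ideal polar angles of the canonical vertices (degrees)
_THETA_E = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...
_THETA_H = 50.84

_N = 6
_J = np.arange(_N)
_W_SIN = np.sin(2.0 * np.pi * _J / _N)
_W_COS = np.cos(2.0 * np.pi * _J / _N)
_W2_COS = np.cos(4.0 * np.pi * _J / _N)
_W2_SIN = np.sin(4.0 * np.pi * _J / _N)
_ALT = (-1.0) ** _J


class DegenerateRingError(ValueError):
    """The six positions do not define a usable mean plane."""


@dataclass(frozen=True)
class PuckerCoordinates:
    """Cremer–Pople coordinates of one ring in one frame.

    ``theta``/``phi`` are NaN (and ``planar`` is True) when ``Q`` falls
    below :data:`PLANARITY_Q`.
    """

    Q: float
    theta: float
    phi: float
    q2: float
    q3: float
    planar: bool = False


@dataclass(frozen=True)
class CanonicalPucker:
    """One of the 38 canonical ring shapes, named for a specific ring circuit."""

    name: str
    family: str  # C, B, SB, E, HC
    ideal_theta: float
    ideal_phi: float
    above: tuple[str, ...]  # superscript locants
    below: tuple[str, ...]  # subscript locants


def _mean_plane_displacements(coords: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j w.r.t. the CP mean plane.

    Works on (..., 6, 3) stacks; the normal is R' × R'' with
    R' = Σ x_j sin(2πj/6), R'' = Σ x_j cos(2πj/6), which makes the m=1
    Fourier sums of z vanish identically.
    """
    centred = coords - coords.mean(axis=-2, keepdims=True)
    rp = np.einsum("...jk,j->...k", centred, _W_SIN)
    rpp = np.einsum("...jk,j->...k", centred, _W_COS)
    normal = np.cross(rp, rpp)
    norm = np.linalg.norm(normal, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise DegenerateRingError(
            "ring projection has zero area; cannot orient the mean plane"
        )
    return np.einsum("...jk,...k->...j", centred, normal / norm)


def _cp_from_z(z: np.ndarray):
    q2cos = math.sqrt(2.0 / _N) * np.einsum("...j,j->...", z, _W2_COS)
    q2sin = -math.sqrt(2.0 / _N) * np.einsum("...j,j->...", z, _W2_SIN)
    q2 = np.hypot(q2cos, q2sin)
    q3 = math.sqrt(1.0 / _N) * np.einsum("...j,j->...", z, _ALT)
    big_q = np.hypot(q2, q3)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(q3 / big_q, -1.0, 1.0)))
        phi = np.degrees(np.arctan2(q2sin, q2cos)) % 360.0
    return big_q, theta, phi, q2, q3


def cremer_pople(ring_coords: np.ndarray) -> PuckerCoordinates:
    """Cremer–Pople coordinates of a single 6-atom ring.

    Parameters
    ----------
    ring_coords : (6, 3) array
        Positions in Å, ordered along the puckering circuit (e.g.
        O5–C1–C2–C3–C4–C5 for a d-pyranose).

    Raises
    ------
    DegenerateRingError
        If the projected ring has zero area (collinear/coincident atoms).
    """
    coords = np.asarray(ring_coords, dtype=float)
    if coords.shape != (_N, 3):
        raise ValueError(f"expected (6, 3) coordinates, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("ring coordinates must be finite")
    z = _mean_plane_displacements(coords)
    big_q, theta, phi, q2, q3 = _cp_from_z(z)
    planar = bool(big_q < PLANARITY_Q)
    if planar:
        theta = math.nan
        phi = math.nan
    return PuckerCoordinates(
        Q=float(big_q), theta=float(theta), phi=float(phi),
        q2=float(q2), q3=float(q3), planar=planar,
    )


def cremer_pople_trajectory(ring_coords: np.ndarray):
    """Vectorised CP transform over a trajectory.

    Parameters
    ----------
    ring_coords : (n_frames, 6, 3) array

    Returns
    -------
    Q, theta, phi, planar : arrays of shape (n_frames,)
        ``theta``/``phi`` are NaN where ``planar`` is set.
    """
    coords = np.asarray(ring_coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != (_N, 3):
        raise ValueError(f"expected (n, 6, 3) coordinates, got {coords.shape}")
    z = _mean_plane_displacements(coords)
    big_q, theta, phi, _, _ = _cp_from_z(z)
    planar = big_q < PLANARITY_Q
    theta = np.where(planar, np.nan, theta)
    phi = np.where(planar, np.nan, phi)
    return big_q, theta, phi, planar


def _ideal_z(theta_deg: float, phi_deg: float, big_q: float) -> np.ndarray:
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    q2 = big_q * math.sin(th)
    q3 = big_q * math.cos(th)
    return (math.sqrt(2.0 / _N) * q2 * np.cos(ph + 4.0 * np.pi * _J / _N)
            + math.sqrt(1.0 / _N) * q3 * _ALT)


def invert_cremer_pople(
    Q: float, theta: float, phi: float, ring_radius: float = 1.45
) -> np.ndarray:
    """Build an idealised 6-atom ring with prescribed CP coordinates.

    The ring is a regular hexagon of radius ``ring_radius`` in the mean
    plane plus the exact CP out-of-plane pattern, so the forward
    transform recovers ``(Q, theta, phi)`` to machine precision.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    if ring_radius <= 0:
        raise ValueError("ring_radius must be positive")
    z = _ideal_z(theta, phi, Q)
    alpha = -2.0 * np.pi * _J / _N  # clockwise placement keeps the normal +z
    return np.column_stack(
        [ring_radius * np.cos(alpha), ring_radius * np.sin(alpha), z]
    )


# ---------------------------------------------------------------------------
# canonical conformer naming


def _locant_sort_key(locant: str):
    # numeric locants ascend, the ring oxygen sorts last ("3,OB", "B3,O")
    return (1, 0) if locant == "O" else (0, int(locant))


def _carbon_rank(locants: Sequence[str]) -> int:
    nums = [int(l) for l in locants if l != "O"]
    return min(nums) if nums else 99


def _format_name(above: Sequence[str], family_letter: str,
                 below: Sequence[str]) -> str:
    sup = ",".join(sorted(above, key=_locant_sort_key))
    sub = ",".join(sorted(below, key=_locant_sort_key))
    return f"{sup}{family_letter}{sub}"


def _name_vertex(theta: float, phi: float, labels: tuple[str, ...]):
    """Derive the conformer name at one canonical vertex from z signs."""
    z = _ideal_z(theta, phi, 1.0)
    order = np.argsort(np.abs(z))[::-1]
    if theta in (0.0, 180.0):
        # chair: alternating displacements; name by the para pair that
        # contains the lowest-numbered carbon (IUPAC reference-plane rule)
        pairs = [(j, (j + 3) % _N) for j in range(3)]
        best = min(
            pairs,
            key=lambda p: _carbon_rank([labels[p[0]], labels[p[1]]]),
        )
        up = [j for j in best if z[j] > 0]
        down = [j for j in best if z[j] < 0]
        return "C", [labels[j] for j in up], [labels[j] for j in down]
    if theta == 90.0:
        # boat: para pair at |z|max, four at half-amplitude opposite side;
        # skew-boat: four at |z|max (two up, two down), two in plane
        if np.min(np.abs(z)) > 0.1 * np.max(np.abs(z)):
            j1, j2 = sorted(order[:2])
            locs = [labels[j1], labels[j2]]
            if z[j1] > 0:
                return "B", locs, []
            return "B", [], locs
        # skew-boat: two above, two below, two in plane; the name pair
        # flanks an in-plane atom and contains the lowest-numbered carbon
        in_plane = sorted(order[-2:])
        candidates = []
        for j in in_plane:
            prev, nxt = (j - 1) % _N, (j + 1) % _N
            up = prev if z[prev] > 0 else nxt
            down = nxt if up == prev else prev
            candidates.append((up, down))
        up, down = min(
            candidates,
            key=lambda p: _carbon_rank([labels[p[0]], labels[p[1]]]),
        )
        return "S", [labels[up]], [labels[down]]
    if abs(theta - _THETA_E) < 2.0 or abs(theta - (180.0 - _THETA_E)) < 2.0:
        j = order[0]  # envelope: a single dominant exoplanar atom
        if z[j] > 0:
            return "E", [labels[j]], []
        return "E", [], [labels[j]]
    # half-chair: adjacent dominant pair on opposite sides
    j1, j2 = order[:2]
    up, down = (j1, j2) if z[j1] > 0 else (j2, j1)
    return "H", [labels[up]], [labels[down]]


_FAMILY_OF_LETTER = {"C": "C", "B": "B", "S": "SB", "E": "E", "H": "HC"}


@lru_cache(maxsize=16)
def canonical_puckers(labels: tuple[str, ...] = D_PYRANOSE_LABELS
                      ) -> tuple[CanonicalPucker, ...]:
    """The 38 canonical conformers for a ring circuit with given locants.

    Parameters
    ----------
    labels : 6-tuple of str
        Name locant for each position of the puckering circuit, e.g.
        ``("O","1","2","3","4","5")`` for O5–C1–…–C5 or
        ``("O","2","3","4","5","6")`` for the NeuAc circuit.
    """
    if len(labels) != _N or len(set(labels)) != _N:
        raise ValueError("labels must be 6 unique locants")
    vertices: list[tuple[float, float]] = [(0.0, 0.0), (180.0, 0.0)]
    for k in range(6):
        vertices.append((90.0, 60.0 * k))          # boats
        vertices.append((90.0, 30.0 + 60.0 * k))   # skew-boats
        vertices.append((_THETA_E, 60.0 * k))            # envelopes N
        vertices.append((180.0 - _THETA_E, 60.0 * k))    # envelopes S
        vertices.append((_THETA_H, 30.0 + 60.0 * k))         # half-chairs N
        vertices.append((180.0 - _THETA_H, 30.0 + 60.0 * k))  # half-chairs S
    out = []
    for theta, phi in vertices:
        letter, above, below = _name_vertex(theta, phi, labels)
        out.append(
            CanonicalPucker(
                name=_format_name(above, letter, below),
                family=_FAMILY_OF_LETTER[letter],
                ideal_theta=theta,
                ideal_phi=phi % 360.0,
                above=tuple(above),
                below=tuple(below),
            )
        )
    assert len(out) == 38
    return tuple(out)


def _great_circle_deg(t1, p1, t2, p2) -> float:
    t1, p1, t2, p2 = map(math.radians, (t1, p1, t2, p2))
    c = (math.sin(t1) * math.sin(t2) * math.cos(p1 - p2)
         + math.cos(t1) * math.cos(t2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def assign_canonical_name(
    pucker: PuckerCoordinates | tuple[float, float],
    labels: tuple[str, ...] = D_PYRANOSE_LABELS,
) -> CanonicalPucker:
    """Nearest canonical conformer on the (theta, phi) sphere.

    Ties between envelope and half-chair vertices break toward the
    envelope.  Raises for planar (undefined) puckers.
    """
    if isinstance(pucker, PuckerCoordinates):
        if pucker.planar:
            raise ValueError("pucker is planar; no conformer name is defined")
        theta, phi = pucker.theta, pucker.phi
    else:
        theta, phi = pucker
    if not (0.0 <= theta <= 180.0):
        raise ValueError(f"theta out of range: {theta}")
    table = canonical_puckers(tuple(labels))
    pref = {"E": 0, "HC": 1}  # tie-break toward envelope
    return min(
        table,
        key=lambda c: (
            round(_great_circle_deg(theta, phi, c.ideal_theta, c.ideal_phi), 9),
            pref.get(c.family, 2),
        ),
    )


_REGION_NAMES = ("C(north)", "E/HC(north)", "B/SB", "E/HC(south)", "C(south)")


def assign_theta_region(theta: float) -> str:
    """Coarse conformational region of a polar angle.

    Band edges sit on the 15° binning grid: chairs [0,30) and (150,180],
    envelope/half-chair buffers [30,60) and (120,150], boat/skew-boat
    core [60,120].
    """
    if not (0.0 <= theta <= 180.0):
        raise ValueError(f"theta out of range: {theta}")
    if theta < 30.0:
        return _REGION_NAMES[0]
    if theta < 60.0:
        return _REGION_NAMES[1]
    if theta <= 120.0:
        return _REGION_NAMES[2]
    if theta <= 150.0:
        return _REGION_NAMES[3]
    return _REGION_NAMES[4]


def assign_theta_regions(theta: np.ndarray) -> np.ndarray:
    """Vectorised :func:`assign_theta_region`."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 180)):
        raise ValueError("theta out of range [0, 180]")
    idx = np.digitize(theta, [30.0, 60.0, 120.0, 150.0], right=False)
    # digitize puts 120 in the upper band; the B/SB band is closed at 120
    idx = np.where(theta == 120.0, 2, idx)
    idx = np.where(theta == 150.0, 3, idx)
    return np.asarray(_REGION_NAMES, dtype=object)[idx]


def convergence_monitor(theta_series: np.ndarray) -> np.ndarray:
    """Running mean of cos(theta), the sampling-convergence monitor.

    The final element equals the arithmetic mean of cos(theta) over the
    whole series; drifts signal unconverged pucker populations.
    """
    theta = np.asarray(theta_series, dtype=float)
    if theta.size == 0:
        raise ValueError("empty theta series")
    c = np.cos(np.radians(theta))
    return np.cumsum(c) / np.arange(1, theta.size + 1)
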