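"""Synthetic glycan trajectories with known ground truth.

Real μs explicit-solvent trajectories are enormous and never shipped
with analysis code, so every test input here is generated: discrete
pucker/torsion states exchange as a first-order Markov chain at the
trajectory frame interval (10 ps by default, the typical recording
stride of μs simulations), with wrapped-Gaussian within-state noise.
Stated equilibrium populations and exchange-event rates are converted
to a frame-interval transition matrix through the matrix exponential of
the underlying rate matrix, so the generator's ground truth — the
populations, pair rates and ΔG it emits alongside every trajectory —
is exact rather than nominal.

Emission widths default to 8° for pucker angles and 15° for torsions,
which gives basin widths comparable to solution-simulation free-energy
surfaces of small glycans.  One seed governs every stochastic draw:
the chain path is sampled first, then the angular noise, from a single
``numpy.random.default_rng(seed)`` stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import MDAnalysis as mda
import numpy as np
from scipy.linalg import expm

from . import io as _io
from .pucker import (
    D_PYRANOSE_LABELS,
    canonical_puckers,
    invert_cremer_pople,
)
from .thermo import DEFAULT_TEMPERATURE_K, KB_KCAL_PER_MOL_K
from .torsions import wrap_angles

__all__ = [
    "MarkovState",
    "SyntheticTrajectorySpec",
    "MarkovSimulation",
    "two_state_pucker_spec",
    "simulate_markov_series",
    "build_ideal_ring",
    "emit_ring_trajectory",
    "emit_solvated_snapshot",
    "make_universe",
    "write_system",
    "sialyl_lewis_mock",
]

PUCKER_WIDTH_DEG = 8.0
TORSION_WIDTH_DEG = 15.0


@dataclass(frozen=True)
class MarkovState:
    """One conformational state: a centre on (θ, φ) or (φ, ψ) plus noise width."""

    label: str
    center: tuple[float, ...]
    width: tuple[float, ...]  # per-coordinate Gaussian SD, degrees

    @staticmethod
    def make(label, center, width):
        center = tuple(float(c) for c in np.atleast_1d(center))
        width = np.atleast_1d(width).astype(float)
        if width.size == 1:
            width = np.repeat(width, len(center))
        return MarkovState(label, center, tuple(width))


@dataclass
class SyntheticTrajectorySpec:
    """Ground truth for a Markov-switching conformational trajectory.

    ``pair_rates`` maps unordered state-label pairs to total exchange
    events per μs (both directions combined); detailed balance against
    ``populations`` fixes the underlying rate matrix, and the
    frame-interval transition matrix is its exact matrix exponential.
    """

    states: tuple[MarkovState, ...]
    populations: tuple[float, ...]
    pair_rates: dict[frozenset, float] = field(default_factory=dict)
    frame_interval_ps: float = 10.0
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self):
        self.states = tuple(self.states)
        p = np.asarray(self.populations, dtype=float)
        if p.size != len(self.states):
            raise ValueError("one population per state required")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be >= 0 and sum to 1")
        self.populations = tuple(p)
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        self.pair_rates = {
            frozenset(k): float(v) for k, v in self.pair_rates.items()
        }
        for pair, rate in self.pair_rates.items():
            if rate < 0:
                raise ValueError("exchange rates must be >= 0")
            if not pair <= set(labels):
                raise ValueError(f"unknown state in rate pair {set(pair)}")
        # validate the induced transition matrix
        t = self.transition_matrix()
        if np.any(t < -1e-12):
            raise ValueError("infeasible rates: negative transition probability")
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows do not sum to 1")
        pi = np.asarray(self.populations)
        if np.max(np.abs(pi @ t - pi)) > 1e-9:
            raise ValueError("transition matrix does not hold the populations stationary")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def n_dims(self) -> int:
        return len(self.states[0].center)

    def rate_matrix_per_us(self) -> np.ndarray:
        """Generator matrix K (μs⁻¹): off-diagonal k_ij = flux_ij / p_i."""
        n = len(self.states)
        p = np.asarray(self.populations)
        k = np.zeros((n, n))
        index = {s.label: i for i, s in enumerate(self.states)}
        for pair, rate in self.pair_rates.items():
            a, b = sorted(pair)
            i, j = index[a], index[b]
            flux = rate / 2.0  # events per μs in each direction
            if p[i] > 0:
                k[i, j] = flux / p[i]
            if p[j] > 0:
                k[j, i] = flux / p[j]
        np.fill_diagonal(k, -k.sum(axis=1))
        return k

    def transition_matrix(self) -> np.ndarray:
        """Frame-interval transition matrix P = exp(K Δt)."""
        dt_us = self.frame_interval_ps * 1e-6
        return expm(self.rate_matrix_per_us() * dt_us)

    @property
    def total_time_us(self) -> float:
        return self.n_frames * self.frame_interval_ps * 1e-6

    def ground_truth(self, temperature_K: float = DEFAULT_TEMPERATURE_K) -> dict:
        """Machine-readable record of what the trajectory should recover."""
        p = np.asarray(self.populations)
        ref = int(np.argmax(p))
        kt = KB_KCAL_PER_MOL_K * temperature_K
        with np.errstate(divide="ignore"):
            dg = kt * (np.log(p[ref]) - np.log(p))
        return {
            "states": [
                {"label": s.label, "center": list(s.center),
                 "width_deg": list(s.width)}
                for s in self.states
            ],
            "populations": list(map(float, p)),
            "pair_rates_per_us": {
                "|".join(sorted(pair)): rate
                for pair, rate in self.pair_rates.items()
            },
            "deltaG_kcal_per_mol": [float(x) for x in dg],
            "reference_state": self.states[ref].label,
            "temperature_K": temperature_K,
            "frame_interval_ps": self.frame_interval_ps,
            "n_frames": self.n_frames,
            "seed": self.seed,
        }


def two_state_pucker_spec(
    p_major: float = 0.95,
    rate_per_us: float = 0.5,
    n_frames: int = 1_000_000,
    frame_interval_ps: float = 10.0,
    seed: int = 0,
    width_deg: float = PUCKER_WIDTH_DEG,
    theta_major: float = 10.0,
    theta_minor: float = 170.0,
) -> SyntheticTrajectorySpec:
    """Chair-inversion ground truth: two θ states with symmetric exchange."""
    return SyntheticTrajectorySpec(
        states=(
            MarkovState.make("C(north)", (theta_major, 30.0),
                             (width_deg, 40.0)),
            MarkovState.make("C(south)", (theta_minor, 210.0),
                             (width_deg, 40.0)),
        ),
        populations=(p_major, 1.0 - p_major),
        pair_rates={frozenset({"C(north)", "C(south)"}): rate_per_us},
        frame_interval_ps=frame_interval_ps,
        n_frames=n_frames,
        seed=seed,
    )


@dataclass
class MarkovSimulation:
    """A sampled chain with its emissions and the generating spec."""

    spec: SyntheticTrajectorySpec
    state_indices: np.ndarray  # (n_frames,)
    angles: np.ndarray         # (n_frames, n_dims), degrees
    ground_truth: dict

    @property
    def state_labels(self) -> np.ndarray:
        return np.asarray(self.spec.labels, dtype=object)[self.state_indices]

    def n_chain_transitions(self) -> int:
        s = self.state_indices
        return int(np.sum(s[1:] != s[:-1]))


def _sample_chain(spec: SyntheticTrajectorySpec, rng) -> np.ndarray:
    """Exact DTMC path via dwell (geometric) jump-chain sampling."""
    t = spec.transition_matrix()
    n_states = t.shape[0]
    stay = np.clip(np.diag(t), 0.0, 1.0)
    jump = t.copy()
    np.fill_diagonal(jump, 0.0)
    rowsum = jump.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(rowsum[:, None] > 0, jump / rowsum[:, None], 0.0)
    n = spec.n_frames
    state = int(rng.choice(n_states, p=np.asarray(spec.populations)))
    segments: list[tuple[int, int]] = []
    filled = 0
    while filled < n:
        leave = 1.0 - stay[state]
        if leave <= 1e-15:
            dwell = n - filled
        else:
            dwell = int(rng.geometric(leave))
        dwell = min(dwell, n - filled)
        segments.append((state, dwell))
        filled += dwell
        if filled < n:
            state = int(rng.choice(n_states, p=jump[state]))
    states = np.concatenate(
        [np.full(d, s, dtype=np.intp) for s, d in segments]
    )
    return states


def simulate_markov_series(spec: SyntheticTrajectorySpec) -> MarkovSimulation:
    """Sample the chain and its wrapped-Gaussian angular emissions.

    Bit-reproducible for a fixed spec seed.  The first angular
    coordinate of pucker-style states (θ) is reflected into [0, 180];
    all other coordinates wrap into (−180, 180] relative to nothing —
    i.e. torus coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    states = _sample_chain(spec, rng)
    centers = np.asarray([s.center for s in spec.states])
    widths = np.asarray([s.width for s in spec.states])
    noise = rng.standard_normal((spec.n_frames, spec.n_dims))
    angles = centers[states] + noise * widths[states]
    return MarkovSimulation(
        spec=spec,
        state_indices=states,
        angles=angles,
        ground_truth=spec.ground_truth(),
    )


def _reflect_theta(theta: np.ndarray) -> np.ndarray:
    """Fold onto [0, 180] by reflection at the poles."""
    t = np.abs(theta) % 360.0
    return np.where(t > 180.0, 360.0 - t, t)


def build_ideal_ring(
    pucker,
    labels: tuple[str, ...] = D_PYRANOSE_LABELS,
    Q: float = 0.55,
    ring_radius: float = 1.45,
) -> np.ndarray:
    """Idealised 6-atom ring at a canonical conformer or CP coordinates.

    ``pucker`` is either a canonical name valid for ``labels`` (e.g.
    "4C1", "2SO") or a ``(Q, theta, phi)`` triple.
    """
    if isinstance(pucker, str):
        table = {c.name: c for c in canonical_puckers(tuple(labels))}
        if pucker not in table:
            raise ValueError(
                f"unknown conformer {pucker!r} for labels {labels}"
            )
        vertex = table[pucker]
        return invert_cremer_pople(Q, vertex.ideal_theta, vertex.ideal_phi,
                                   ring_radius)
    q, theta, phi = pucker
    return invert_cremer_pople(q, theta, phi, ring_radius)


def emit_ring_trajectory(
    spec: SyntheticTrajectorySpec,
    labels: tuple[str, ...] = D_PYRANOSE_LABELS,
    Q: float = 0.55,
    ring_radius: float = 1.45,
):
    """Per-frame 6-atom ring coordinates from a (θ, φ) Markov spec.

    Returns ``(coords, simulation)`` where coords is (n_frames, 6, 3)
    and the simulation carries the latent states and angles.
    """
    sim = simulate_markov_series(spec)
    theta = _reflect_theta(sim.angles[:, 0])
    phi = sim.angles[:, 1] % 360.0
    coords = np.empty((spec.n_frames, 6, 3))
    for f in range(spec.n_frames):
        coords[f] = invert_cremer_pople(Q, theta[f], phi[f], ring_radius)
    return coords, sim


def emit_solvated_snapshot(
    n_solvent: int,
    box,
    profile: str | tuple = "uniform",
    ref_point=None,
    seed: int = 0,
    rng=None,
) -> np.ndarray:
    """Solvent point cloud with a declared radial density profile.

    ``profile`` is ``"uniform"`` or ``("shell", r0, sigma)`` — a
    Gaussian radial shell of mean radius r0 (Å) around ``ref_point``
    (box centre by default).
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    if n_solvent == 0:
        return np.empty((0, 3))
    if profile == "uniform":
        return rng.uniform(0.0, box, size=(n_solvent, 3))
    kind, r0, sigma = profile
    if kind != "shell":
        raise ValueError(f"unknown profile {profile!r}")
    center = box / 2.0 if ref_point is None else np.asarray(ref_point, float)
    direction = rng.standard_normal((n_solvent, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = np.abs(rng.normal(r0, sigma, size=n_solvent))
    return center + direction * radius[:, None]


def make_universe(
    atom_names: Sequence[str],
    resnames: Sequence[str],
    resids: Sequence[int],
    chain: str = "A",
) -> mda.Universe:
    """In-memory Universe for writing synthetic systems."""
    atom_names = list(atom_names)
    resids_per_atom = list(resids)
    unique_resids = sorted(set(resids_per_atom))
    resindex = [unique_resids.index(r) for r in resids_per_atom]
    res_names = []
    for r in unique_resids:
        res_names.append(resnames[resids_per_atom.index(r)])
    u = mda.Universe.empty(
        n_atoms=len(atom_names),
        n_residues=len(unique_resids),
        atom_resindex=resindex,
        residue_segindex=[0] * len(unique_resids),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atom_names)
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", unique_resids)
    u.add_TopologyAttr("segids", [chain])
    u.add_TopologyAttr("chainIDs", [chain] * len(atom_names))
    u.add_TopologyAttr("elements", [n[0] for n in atom_names])
    return u


def write_system(
    universe: mda.Universe,
    frames: np.ndarray,
    out_pdb,
    out_dcd=None,
) -> None:
    """Write a synthetic system as multi-model PDB (+ optional DCD)."""
    _io.write_trajectory(universe, frames, out_pdb, out_dcd)


# ---------------------------------------------------------------------------
# integration fixture: a four-ring sialyl-Lewis-like mock glycan


@dataclass
class MockGlycan:
    """Synthetic stand-in for a sialylated, fucosylated tetrasaccharide.

    Four idealised rings (GlcNAc-, Gal-, NeuAc- and Fuc-like) joined by
    three glycosidic linkages, plus single-site waters: enough
    structure for every pipeline stage to run end-to-end, with no
    pretence of force-field realism.
    """

    universe: mda.Universe
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    box: np.ndarray             # (3,)
    topology_config: dict
    frame_interval_ps: float = 10.0


def _place_ring(base: np.ndarray, offset, rotation_deg: float = 0.0):
    th = math.radians(rotation_deg)
    rot = np.array(
        [[math.cos(th), -math.sin(th), 0.0],
         [math.sin(th), math.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    return base @ rot.T + np.asarray(offset, dtype=float)


def sialyl_lewis_mock(
    n_frames: int = 40,
    n_waters: int = 500,
    seed: int = 0,
    box_edge: float = 30.0,
) -> MockGlycan:
    """Build the 4-ring mock system used for end-to-end pipeline runs.

    Rings sit at fixed offsets with per-frame puckering noise (5° SD on
    θ/φ) and 0.02 Å positional jitter; waters are uniform in the box.
    All randomness comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray([box_edge] * 3, dtype=float)
    ring_specs = [
        # (resid, resname, ring atom names, labels, pole theta)
        (1, "NAG", ("O5", "C1", "C2", "C3", "C4", "C5"),
         D_PYRANOSE_LABELS, 5.0),
        (2, "GAL", ("O5", "C1", "C2", "C3", "C4", "C5"),
         D_PYRANOSE_LABELS, 5.0),
        (3, "SIA", ("O6", "C2", "C3", "C4", "C5", "C6"),
         ("O", "2", "3", "4", "5", "6"), 175.0),
        (4, "FUC", ("O5", "C1", "C2", "C3", "C4", "C5"),
         D_PYRANOSE_LABELS, 175.0),
    ]
    extra_atoms = {1: ("O4", "O3"), 2: ("O3",)}  # bridge oxygens
    offsets = {1: (12.0, 12.0, 12.0), 2: (12.0, 17.0, 12.0),
               3: (12.0, 22.0, 12.0), 4: (16.5, 12.0, 14.0)}

    names, resnames, resids = [], [], []
    base_frame = []
    for resid, resname, atoms, labels, theta0 in ring_specs:
        ring = invert_cremer_pople(0.55, theta0, 30.0)
        placed = _place_ring(ring, offsets[resid],
                             rotation_deg=25.0 * resid)
        for name, pos in zip(atoms, placed):
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            base_frame.append(pos)
        centroid = placed.mean(axis=0)
        for extra in extra_atoms.get(resid, ()):
            names.append(extra)
            resnames.append(resname)
            resids.append(resid)
            # bridge oxygens poke outward from the ring centroid
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            base_frame.append(centroid + 1.9 * direction)
    n_solute = len(names)
    waters = emit_solvated_snapshot(n_waters, box, "uniform", rng=rng)
    for w in range(n_waters):
        names.append("OW")
        resnames.append("WAT")
        resids.append(100 + w)
        base_frame.append(waters[w])
    base_frame = np.asarray(base_frame)

    frames = np.empty((n_frames, base_frame.shape[0], 3))
    for f in range(n_frames):
        jitter = 0.02 * rng.standard_normal(base_frame.shape)
        frame = base_frame + jitter
        # re-pucker the rings with angular noise for non-trivial series
        cursor = 0
        for resid, resname, atoms, labels, theta0 in ring_specs:
            theta = float(np.clip(theta0 + 5.0 * rng.standard_normal(),
                                  0.5, 179.5))
            phi = 30.0 + 5.0 * rng.standard_normal()
            ring = invert_cremer_pople(0.55, theta, phi)
            placed = _place_ring(ring, offsets[resid],
                                 rotation_deg=25.0 * resid)
            frame[cursor:cursor + 6] = placed + 0.02 * rng.standard_normal(
                (6, 3))
            cursor += 6 + len(extra_atoms.get(resid, ()))
        frames[f] = frame

    config = {
        "rings": [
            {"residue": f"A:{resid}", "atoms": list(atoms),
             "labels": list(labels)}
            for resid, _, atoms, labels, _ in ring_specs
        ],
        "linkages": [
            {"donor": "A:2", "acceptor": "A:1", "kind": "1->4"},
            {"donor": "A:4", "acceptor": "A:1", "kind": "1->3"},
            {"donor": "A:3", "acceptor": "A:2", "kind": "2->3"},
        ],
    }
    universe = make_universe(names, resnames, resids)
    universe.dimensions = np.array(
        [box[0], box[1], box[2], 90.0, 90.0, 90.0]
    )
    return MockGlycan(
        universe=universe, frames=frames, box=box, topology_config=config
    )
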