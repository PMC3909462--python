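"""Thin trajectory I/O wrappers around MDAnalysis.

Structures are PDB (multi-model accepted); trajectories DCD, XTC or the
multi-model PDB itself.  Coordinates are returned as plain
(n_frames, n_atoms, 3) arrays in Å so analysis code never touches
reader state.
"""

from __future__ import annotations

from pathlib import Path

import MDAnalysis as mda
import numpy as np

__all__ = ["read_trajectory", "write_trajectory"]


def read_trajectory(structure: str | Path, trajectory: str | Path | None = None):
    """Load coordinates for all frames.

    Returns ``(coords, frame_interval_ps)`` where the interval falls
    back to 10 ps when the file carries no time information.
    """
    if trajectory is None:
        u = mda.Universe(str(structure))
    else:
        u = mda.Universe(str(structure), str(trajectory))
    coords = np.stack([ts.positions.copy() for ts in u.trajectory]).astype(float)
    dt = getattr(u.trajectory, "dt", None)
    if not dt or not np.isfinite(dt) or dt <= 0:
        dt = 10.0
    return coords, float(dt)


def write_trajectory(
    universe: mda.Universe,
    frames: np.ndarray,
    out_pdb: str | Path,
    out_dcd: str | Path | None = None,
) -> None:
    """Write frames as a multi-model PDB and, optionally, a DCD."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need at least one (n_atoms, 3) frame")
    writers = [mda.Writer(str(out_pdb), multiframe=True,
                          n_atoms=universe.atoms.n_atoms)]
    if out_dcd is not None:
        writers.append(mda.Writer(str(out_dcd),
                                  n_atoms=universe.atoms.n_atoms))
    try:
        for pos in frames:
            universe.atoms.positions = pos
            for w in writers:
                w.write(universe.atoms)
    finally:
        for w in writers:
            w.close()
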