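"""Hydration-shell analysis: radial distribution functions and occupancies.

Distances use the minimum-image convention in orthorhombic boxes.  The
RDF normalises pair counts by the spherical-shell volume and the mean
target density, so an ideal-gas solvent gives g(r) = 1.  Shell
occupancies count, per frame, targets whose *minimum* distance to any
reference atom falls inside a range — the natural observable for "how
many waters sit in the first hydration shell of these oxygens".
Default shells are 1.0–2.5 Å (first) and 3.0–5.0 Å (second).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_SHELLS",
    "RDFResult",
    "rdf",
    "shell_occupancy",
]

DEFAULT_SHELLS = ((1.0, 2.5), (3.0, 5.0))
DEFAULT_BIN_WIDTH = 0.05


def _minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _check_inputs(ref, target, box, r_max):
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    box = np.asarray(box, dtype=float)
    if ref.ndim == 2:
        ref = ref[None]
    if target.ndim == 2:
        target = target[None]
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive orthorhombic edges")
    if r_max is not None and r_max > box.min() / 2 + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the shortest box edge "
            f"({box.min() / 2:.3f})"
        )
    if ref.shape[0] != target.shape[0]:
        raise ValueError("reference and target frame counts differ")
    return ref, target, box


@dataclass
class RDFResult:
    """g(r) on a fixed grid plus per-shell occupancy summaries."""

    r: np.ndarray           # bin centres, Å
    g: np.ndarray           # radial distribution function
    bin_width: float
    counts: np.ndarray      # raw pair counts per bin (all frames)
    shell_volumes: np.ndarray  # exact per-bin shell volumes, Å^3
    n_frames: int
    n_ref: int
    density: float          # mean target number density, Å^-3

    def coordination_number(self, r_lo: float, r_hi: float) -> float:
        """∫ g(r)·4πr²ρ dr over [r_lo, r_hi), per reference atom."""
        sel = (self.r >= r_lo) & (self.r < r_hi)
        return float(np.sum(self.g[sel] * self.shell_volumes[sel])
                     * self.density)


def rdf(
    ref,
    target,
    box,
    r_max: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> RDFResult:
    """Radial distribution function between two atom sets.

    Parameters
    ----------
    ref, target : (n_frames, n_atoms, 3) arrays (a single frame is fine)
    box : (3,) orthorhombic box edges, Å
    r_max : float
        Histogram range; must not exceed half the shortest box edge.
    bin_width : float
        Radial bin spacing (default 0.05 Å).
    """
    ref, target, box = _check_inputs(ref, target, box, r_max)
    n_frames, n_ref = ref.shape[:2]
    n_tgt = target.shape[1]
    if n_ref == 0 or n_tgt == 0:
        raise ValueError("empty atom selection")
    # bins are centred on multiples of the bin width: a distance of
    # exactly 3.00 A falls in [2.975, 3.025) at the default spacing
    n_bins = int(round(r_max / bin_width))
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in range(n_frames):
        delta = _minimum_image(
            target[f][None, :, :] - ref[f][:, None, :], box
        )
        d = np.linalg.norm(delta, axis=-1).ravel()
        d = d[d > 1e-9]
        idx = np.floor(d / bin_width + 0.5).astype(np.intp)
        sel = idx < n_bins
        counts += np.bincount(idx[sel], minlength=n_bins)[:n_bins]
    centers = bin_width * np.arange(n_bins)
    lower = np.maximum(centers - bin_width / 2.0, 0.0)
    upper = centers + bin_width / 2.0
    shell_vol = 4.0 / 3.0 * np.pi * (upper**3 - lower**3)
    density = n_tgt / float(np.prod(box))
    expected = n_frames * n_ref * density * shell_vol
    g = counts / expected
    return RDFResult(
        r=centers, g=g, bin_width=bin_width, counts=counts,
        shell_volumes=shell_vol, n_frames=n_frames, n_ref=n_ref,
        density=density,
    )


def shell_occupancy(
    ref,
    target,
    box,
    ranges: Sequence[tuple[float, float]] = DEFAULT_SHELLS,
) -> dict[tuple[float, float], float]:
    """Mean per-frame count of targets inside each distance range.

    A target's distance is its minimum image distance to the *nearest*
    reference atom; ranges must not overlap.
    """
    ranges = [tuple(map(float, r)) for r in ranges]
    for i, (lo_a, hi_a) in enumerate(ranges):
        if hi_a <= lo_a:
            raise ValueError(f"empty shell range ({lo_a}, {hi_a})")
        for lo_b, hi_b in ranges[i + 1:]:
            if lo_a < hi_b and lo_b < hi_a:
                raise ValueError("shell ranges overlap")
    ref, target, box = _check_inputs(ref, target, box, None)
    n_frames = ref.shape[0]
    totals = {r: 0.0 for r in ranges}
    for f in range(n_frames):
        if target.shape[1] == 0:
            continue
        delta = _minimum_image(
            target[f][None, :, :] - ref[f][:, None, :], box
        )
        dmin = np.linalg.norm(delta, axis=-1).min(axis=0)
        for lo, hi in ranges:
            totals[(lo, hi)] += float(np.sum((dmin >= lo) & (dmin <= hi)))
    return {r: totals[r] / n_frames for r in ranges}
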