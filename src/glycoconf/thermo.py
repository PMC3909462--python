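"""Boltzmann inversion of binned conformer populations.

Relative free energies follow ΔG_i = kT ln(p_ref / p_i) with the modal
bin as the zero reference, k in kcal/(mol·K) and T defaulting to 298 K.
Pucker profiles use 15° θ bins, linkage surfaces 10° (φ, ψ) bins; bins
are left-closed/right-open.  Uncertainties come from a circular block
bootstrap over frames — a generic stand-in for trajectory-correlation
aware error estimation, labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE_K",
    "FreeEnergyProfile",
    "FreeEnergySurface",
    "histogram_angles",
    "histogram_angles_2d",
    "free_energy_profile",
    "free_energy_surface",
    "delta_g",
    "bootstrap_errors",
]

KB_KCAL_PER_MOL_K = 1.9872041e-3
DEFAULT_TEMPERATURE_K = 298.0

THETA_DOMAIN = (0.0, 180.0)
TORSION_DOMAIN = (-180.0, 180.0)


def _bin_index(values: np.ndarray, lo: float, hi: float, width: float,
               circular: bool) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if circular:
        v = lo + (v - lo) % (hi - lo)
    elif np.any((v < lo) | (v > hi)):
        raise ValueError(f"values outside domain [{lo}, {hi}]")
    idx = np.floor((v - lo) / width).astype(np.intp)
    n_bins = int(round((hi - lo) / width))
    return np.minimum(idx, n_bins - 1)  # hi itself joins the last bin


def histogram_angles(values, width: float, domain=THETA_DOMAIN,
                     circular: bool | None = None):
    """Counts per left-closed/right-open angular bin.

    ``width`` must divide the domain span exactly.  Returns
    ``(counts, edges)``.  Circular domains (span 360°) wrap incoming
    values; by default circularity is inferred from the span.
    """
    lo, hi = domain
    span = hi - lo
    n_bins = span / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {width} does not divide span {span}")
    n_bins = int(round(n_bins))
    if circular is None:
        circular = abs(span - 360.0) < 1e-9
    idx = _bin_index(values, lo, hi, width, circular)
    counts = np.bincount(idx, minlength=n_bins)
    edges = lo + width * np.arange(n_bins + 1)
    return counts, edges


def histogram_angles_2d(x, y, width: float, domain_x=TORSION_DOMAIN,
                        domain_y=TORSION_DOMAIN):
    """2D angular histogram (e.g. (φ, ψ) in 10° increments).

    Returns ``(counts, edges_x, edges_y)`` with counts shaped
    (n_bins_x, n_bins_y).
    """
    cx, ex = histogram_angles(x, width, domain_x)
    nx, ny = cx.size, None
    lo_x, hi_x = domain_x
    lo_y, hi_y = domain_y
    circ_x = abs((hi_x - lo_x) - 360.0) < 1e-9
    circ_y = abs((hi_y - lo_y) - 360.0) < 1e-9
    ix = _bin_index(x, lo_x, hi_x, width, circ_x)
    iy = _bin_index(y, lo_y, hi_y, width, circ_y)
    ny = int(round((hi_y - lo_y) / width))
    counts = np.bincount(ix * ny + iy, minlength=nx * ny).reshape(nx, ny)
    ey = lo_y + width * np.arange(ny + 1)
    return counts, ex, ey


def delta_g(counts: np.ndarray, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """ΔG_i = kT ln(p_ref/p_i) with the modal bin as reference.

    Empty bins are +inf (unvisited, not zero).  Returns
    ``(deltaG, populations, reference_index)`` where the reference index
    is flat for multi-dimensional count grids.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all histogram bins are empty")
    p = counts / total
    ref = int(np.argmax(counts))
    p_ref = p.flat[ref]
    kt = KB_KCAL_PER_MOL_K * temperature_K
    with np.errstate(divide="ignore"):
        dg = kt * (np.log(p_ref) - np.log(p))
    return dg, p, ref


@dataclass
class FreeEnergyProfile:
    """1D binned populations converted to relative free energies."""

    bin_edges: np.ndarray  # degrees, length n_bins + 1
    populations: np.ndarray
    deltaG: np.ndarray  # kcal/mol; +inf for empty bins
    reference_bin: int
    temperature_K: float
    k: float = KB_KCAL_PER_MOL_K
    errors: np.ndarray | None = None  # kcal/mol, block-bootstrap SD

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FreeEnergySurface:
    """2D binned populations (φ, ψ) or (θ, φ) as relative free energies."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    populations: np.ndarray  # (nx, ny)
    deltaG: np.ndarray  # (nx, ny); +inf for empty bins
    reference_bin: tuple[int, int]
    temperature_K: float
    k: float = KB_KCAL_PER_MOL_K
    contour_levels: tuple[float, ...] = (2.0, 4.0, 6.0)


def free_energy_profile(
    values, width: float = 15.0, domain=THETA_DOMAIN,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    burn_in_frames: int = 0,
) -> FreeEnergyProfile:
    """Histogram an angle series and Boltzmann-invert it."""
    values = np.asarray(values, dtype=float)[burn_in_frames:]
    counts, edges = histogram_angles(values, width, domain)
    dg, p, ref = delta_g(counts, temperature_K)
    return FreeEnergyProfile(
        bin_edges=edges, populations=p, deltaG=dg, reference_bin=ref,
        temperature_K=temperature_K,
    )


def free_energy_surface(
    x, y, width: float = 10.0, domain_x=TORSION_DOMAIN,
    domain_y=TORSION_DOMAIN,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    burn_in_frames: int = 0,
) -> FreeEnergySurface:
    """2D histogram of two angle series Boltzmann-inverted to a surface."""
    x = np.asarray(x, dtype=float)[burn_in_frames:]
    y = np.asarray(y, dtype=float)[burn_in_frames:]
    counts, ex, ey = histogram_angles_2d(x, y, width, domain_x, domain_y)
    dg, p, ref = delta_g(counts, temperature_K)
    ref2d = np.unravel_index(ref, counts.shape)
    return FreeEnergySurface(
        edges_x=ex, edges_y=ey, populations=p, deltaG=dg,
        reference_bin=(int(ref2d[0]), int(ref2d[1])),
        temperature_K=temperature_K,
    )


def _circular_block_indices(n: int, block_length: int, rng) -> np.ndarray:
    n_blocks = -(-n // block_length)
    starts = rng.integers(0, n, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_length)[None, :]) % n
    return idx.ravel()[:n]


def bootstrap_errors(
    values,
    block_length: int,
    n_boot: int = 50,
    seed: int = 0,
    width: float = 15.0,
    domain=THETA_DOMAIN,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> np.ndarray:
    """Per-bin ΔG standard deviation from a circular block bootstrap.

    Whole blocks of ``block_length`` consecutive frames are resampled
    (wrapping at the series end) to respect serial correlation; each
    replicate is re-binned and re-inverted against the full-data modal
    bin.  Deterministic for a fixed ``seed``.  Bins that are empty in a
    replicate contribute nothing to that replicate's spread; bins with
    fewer than two finite replicates get NaN.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if block_length >= n:
        raise ValueError("block_length must be smaller than the series")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    counts, _ = histogram_angles(values, width, domain)
    _, _, ref = delta_g(counts, temperature_K)
    kt = KB_KCAL_PER_MOL_K * temperature_K
    rng = np.random.default_rng(seed)
    reps = np.full((n_boot, counts.size), np.nan)
    for b in range(n_boot):
        idx = _circular_block_indices(n, block_length, rng)
        c, _ = histogram_angles(values[idx], width, domain)
        if c[ref] == 0:
            continue
        with np.errstate(divide="ignore"):
            reps[b] = kt * (np.log(c[ref]) - np.log(c))
    reps[~np.isfinite(reps)] = np.nan
    finite = np.sum(np.isfinite(reps), axis=0)
    sd = np.full(counts.size, np.nan)
    enough = finite >= 2
    if np.any(enough):
        sd[enough] = np.nanstd(reps[:, enough], axis=0, ddof=1)
    return sd
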