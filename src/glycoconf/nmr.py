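"""Back-calculated NMR observables from conformational ensembles.

Three families of observables connect trajectories to solution NMR:

* vicinal ³J(H,H) couplings from H–C–C–H dihedrals through a
  substituent-adjusted Karplus equation, averaged *per frame* (J is
  averaged, never the dihedral, because the Karplus curve is nonlinear);
* inter-ring centroid distances (ring stacking);
* generalised order parameters S² from isotropic reorientational
  eigenmode dynamics (iRED): the covariance matrix of rank-2 vector
  orientations is eigendecomposed and the small "internal" modes —
  everything past the five largest, overall-reorientation modes — carry
  the internal disorder: S²_i = 1 − Σ_internal λ_m |m_i|².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import curve_fit

__all__ = [
    "KarplusParameters",
    "JCouplingResult",
    "JTableComparison",
    "OrderParameterResult",
    "load_karplus_parameters",
    "karplus_3jhh",
    "ensemble_j",
    "compare_j_tables",
    "ring_centroid_distance",
    "ired_order_parameters",
]


@dataclass(frozen=True)
class KarplusParameters:
    """Coefficients and substituent terms of the generalised Karplus curve.

    ``substituents`` lists ``(dchi, xi)`` pairs: relative group
    electronegativity and orientation factor (±1) for each
    non-hydrogen substituent of the H–C–C–H fragment.
    """

    P1: float
    P2: float
    P3: float
    P4: float = 0.0
    P5: float = 0.0
    P6: float = 0.0
    substituents: tuple[tuple[float, int], ...] = ()

    def __post_init__(self):
        for dchi, xi in self.substituents:
            if xi not in (+1, -1):
                raise ValueError(f"orientation factor must be ±1, got {xi}")


def load_karplus_parameters(
    substituents: Sequence[tuple[str, int]],
    source: str | None = None,
) -> KarplusParameters:
    """Build parameters from the shipped (or a user) coefficient file.

    ``substituents`` is a sequence of ``(group, xi)`` with group one of
    the electronegativity table keys (C, N, OH, OR, ...) and xi = ±1.
    The coefficient set is chosen by the substituent count.
    """
    if source is None:
        ref = resources.files("glycoconf.data") / "karplus_haasnoot.yaml"
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    n = len(substituents)
    key = {2: "two_substituents", 3: "three_substituents",
           4: "four_substituents"}.get(n)
    if key is None or key not in doc["coefficients"]:
        raise ValueError(f"no coefficient set for {n} substituents")
    coeff = doc["coefficients"][key]
    chi = doc["electronegativities"]
    subs = []
    for group, xi in substituents:
        if group not in chi:
            raise ValueError(f"no electronegativity entry for {group!r}")
        subs.append((float(chi[group]), int(xi)))
    return KarplusParameters(
        P1=coeff["P1"], P2=coeff["P2"], P3=coeff["P3"], P4=coeff["P4"],
        P5=coeff["P5"], P6=coeff["P6"], substituents=tuple(subs),
    )


def karplus_3jhh(theta_hh, params: KarplusParameters):
    """³J(H,H) in Hz for an H–H dihedral (degrees); vectorised.

    J = P1 cos²θ + P2 cosθ + P3 + Σ_i Δχ_i [P4 + P5 cos²(ξ_i θ + P6 |Δχ_i|)]
    """
    t = np.radians(np.asarray(theta_hh, dtype=float))
    c = np.cos(t)
    j = params.P1 * c**2 + params.P2 * c + params.P3
    for dchi, xi in params.substituents:
        arg = xi * t + math.radians(params.P6 * abs(dchi))
        j = j + dchi * (params.P4 + params.P5 * np.cos(arg) ** 2)
    if np.ndim(theta_hh) == 0:
        return float(j)
    return j


@dataclass(frozen=True)
class JCouplingResult:
    pair_id: str
    mean_hz: float
    per_frame_hz: np.ndarray | None = None


def ensemble_j(
    theta_series, params: KarplusParameters, pair_id: str = "",
    keep_series: bool = False,
) -> JCouplingResult:
    """Ensemble ³J: the Karplus curve evaluated per frame, then averaged."""
    theta = np.asarray(theta_series, dtype=float)
    if theta.size == 0:
        raise ValueError("empty dihedral series")
    j = karplus_3jhh(theta, params)
    return JCouplingResult(
        pair_id=pair_id,
        mean_hz=float(np.mean(j)),
        per_frame_hz=j if keep_series else None,
    )


@dataclass(frozen=True)
class JTableComparison:
    n_within: int
    n_total: int
    deviations_hz: Mapping[str, float]  # calculated − experimental
    tolerance_hz: float
    unmatched_calculated: tuple[str, ...]
    unmatched_experimental: tuple[str, ...]


def compare_j_tables(
    calculated: Mapping[str, float],
    experimental: Mapping[str, float],
    tolerance_hz: float = 2.0,
) -> JTableComparison:
    """Count matched proton pairs agreeing within ±tolerance.

    Mirrors the "m of n couplings within ±2.0 Hz" comparison style;
    signed deviations (calculated − experimental) are reported per pair
    and unmatched ids on either side are listed.
    """
    shared = sorted(set(calculated) & set(experimental))
    dev = {pid: float(calculated[pid] - experimental[pid]) for pid in shared}
    n_within = sum(abs(d) <= tolerance_hz for d in dev.values())
    return JTableComparison(
        n_within=n_within,
        n_total=len(shared),
        deviations_hz=dev,
        tolerance_hz=tolerance_hz,
        unmatched_calculated=tuple(sorted(set(calculated) - set(experimental))),
        unmatched_experimental=tuple(sorted(set(experimental) - set(calculated))),
    )


def ring_centroid_distance(coords_a, coords_b):
    """Per-frame distance between unweighted 6-atom ring centroids.

    Parameters are (n_frames, 6, 3) stacks in Å; returns
    ``(mean, sd, series)`` with the population SD (ddof=0).
    """
    a = np.asarray(coords_a, dtype=float).mean(axis=-2)
    b = np.asarray(coords_b, dtype=float).mean(axis=-2)
    series = np.linalg.norm(a - b, axis=-1)
    return float(series.mean()), float(series.std()), series


# ---------------------------------------------------------------------------
# iRED order parameters


@dataclass(frozen=True)
class OrderParameterResult:
    vector_id: str
    S2: float
    tau_fast_ps: float
    tau_slow_ps: float
    amplitude_fast: float
    fit_rmsd: float
    fit_converged: bool


def _p2_matrix(vectors: np.ndarray, chunk: int = 2000) -> np.ndarray:
    """M_ij = ⟨P2(μ_i·μ_j)⟩ accumulated over frames."""
    n_frames, n_vec, _ = vectors.shape
    acc = np.zeros((n_vec, n_vec))
    for start in range(0, n_frames, chunk):
        x = vectors[start:start + chunk]
        g = np.einsum("tik,tjk->tij", x, x)
        acc += np.sum(g * g, axis=0)
    return 1.5 * acc / n_frames - 0.5


def _p2_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """P2 autocorrelation of one unit-vector series via FFT.

    C(t) = (3/2) Σ_ab ⟨μ_a(0)μ_b(0) μ_a(t)μ_b(t)⟩ − 1/2 over the six
    unique components of the outer product μμᵀ.
    """
    n = x.shape[0]
    comps = []
    weights = []
    for a in range(3):
        for b in range(a, 3):
            comps.append(x[:, a] * x[:, b])
            weights.append(1.0 if a == b else 2.0)
    comps = np.asarray(comps)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(comps, n=nfft, axis=1)
    acf = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :max_lag + 1]
    acf /= (n - np.arange(max_lag + 1))[None, :]
    return 1.5 * np.einsum("c,ct->t", np.asarray(weights), acf) - 0.5


def _fit_double_exponential(t: np.ndarray, c: np.ndarray,
                            t_max: float):
    """A·exp(−t/τf) + (1−A)·exp(−t/τs); 3 fixed starts, best kept."""

    def model(t, a, tau_f, tau_s):
        return a * np.exp(-t / tau_f) + (1 - a) * np.exp(-t / tau_s)

    t_lo = max(t[1] if t.size > 1 else 1.0, 1e-6)
    bounds = ([0.0, t_lo * 1e-3, t_lo * 1e-3], [1.0, t_max * 10, t_max * 10])
    starts = [
        (0.5, t_lo, t_max * 0.1),
        (0.8, t_lo * 5, t_max * 0.5),
        (0.2, t_lo * 0.5, t_max),
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(model, t, c, p0=p0, bounds=bounds,
                                maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rmsd = float(np.sqrt(np.mean((model(t, *popt) - c) ** 2)))
        if best is None or rmsd < best[1]:
            best = (popt, rmsd)
    if best is None:
        return math.nan, math.nan, math.nan, math.nan, False
    (a, tau_f, tau_s), rmsd = best
    if tau_f > tau_s:
        tau_f, tau_s, a = tau_s, tau_f, 1 - a
    return float(a), float(tau_f), float(tau_s), rmsd, True


def ired_order_parameters(
    vectors,
    n_overall_modes: int = 5,
    frame_interval_ps: float = 10.0,
    vector_ids: Sequence[str] | None = None,
    fit_correlations: bool = True,
    max_lag_fraction: float = 0.25,
) -> list[OrderParameterResult]:
    """Generalised order parameters from the iRED covariance analysis.

    Parameters
    ----------
    vectors : (n_frames, n_vectors, 3) array of unit vectors
    n_overall_modes : int
        Number of largest eigenmodes attributed to overall
        reorientation and excluded from the internal sum (default 5,
        the dimensionality of the rank-2 overall-tumbling space).
    fit_correlations : bool
        Also fit each vector's P2 autocorrelation to a double
        exponential; non-convergent fits are flagged with NaN times.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected (n_frames, n_vectors, 3), got {x.shape}")
    n_frames, n_vec, _ = x.shape
    if n_vec < 2:
        raise ValueError("iRED requires at least 2 vectors")
    if n_frames < 100:
        raise ValueError("iRED requires at least 100 frames")
    norms = np.linalg.norm(x, axis=2)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("vectors must be unit-normalised")

    m = _p2_matrix(x)
    evals, evecs = np.linalg.eigh(m)  # ascending
    internal = slice(0, max(0, n_vec - n_overall_modes))
    lam = evals[internal]
    vec = evecs[:, internal]
    s2 = 1.0 - np.einsum("m,im->i", lam, vec**2)
    s2 = np.clip(s2, 0.0, 1.0)

    ids = list(vector_ids) if vector_ids is not None else [
        f"v{i}" for i in range(n_vec)
    ]
    out = []
    max_lag = max(2, int(n_frames * max_lag_fraction))
    t = np.arange(max_lag + 1) * frame_interval_ps
    for i in range(n_vec):
        if fit_correlations:
            c = _p2_autocorrelation(x[:, i, :], max_lag)
            a, tf, ts, rmsd, ok = _fit_double_exponential(
                t, c, t_max=n_frames * frame_interval_ps
            )
        else:
            a = tf = ts = rmsd = math.nan
            ok = False
        out.append(
            OrderParameterResult(
                vector_id=ids[i], S2=float(s2[i]), tau_fast_ps=tf,
                tau_slow_ps=ts, amplitude_fast=a, fit_rmsd=rmsd,
                fit_converged=ok,
            )
        )
    return out
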