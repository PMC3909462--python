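# Methods

This note documents the models and numerical choices behind
`glycoconf`, what the synthetic-data generator does and does not
emulate, and the limitations a user should know about.

## Ring puckering

Six-membered ring shape is parameterised by the Cremer–Pople
coordinates. Positions are centred on the geometric mean; the mean
plane is the plane whose out-of-plane displacements `z_j` carry no
m = 1 Fourier component (normal ∝ R′ × R″ with
R′ = Σ xⱼ sin(2πj/6), R″ = Σ xⱼ cos(2πj/6)). Then

* q₂ cos φ₂ = √(2/6) Σ zⱼ cos(4πj/6), q₂ sin φ₂ = −√(2/6) Σ zⱼ sin(4πj/6)
* q₃ = √(1/6) Σ (−1)ʲ zⱼ
* Q² = q₂² + q₃², θ = arccos(q₃/Q), φ = φ₂ ∈ [0, 360)

**Planarity.** Below Q < 0.05 Å the polar chart degenerates and
θ/φ are reported as undefined (NaN, `planar` flag). The threshold is a
package choice, not a literature constant; it only matters for rings
flattened far beyond carbohydrate geometries.

**Inverse transform.** `invert_cremer_pople` builds a regular hexagon
(default radius 1.45 Å, a typical pyranose bond length) plus the exact
CP displacement pattern, placed clockwise so the CP normal is +z. The
forward transform recovers the inputs to machine precision; the
generator and all round-trip tests rely on this.

**Conformer naming.** The 38 canonical forms (2 chairs, 6 boats,
6 skew-boats, 12 envelopes, 12 half-chairs) live at fixed vertices:
θ = 0/180° (C), θ = 90° with φ = 60k° (B) and 30° + 60k° (S),
θ = 54.7°/125.3° (E, arccos(±1/√3)) and θ = 50.8°/129.2° (H).
Names are *derived* from the ideal displacement pattern at each vertex
rather than hard-coded: atoms above the mean plane become superscript
locants, atoms below subscripts. Selection rules follow the standard
reference-plane conventions — chairs use the para pair containing the
lowest-numbered carbon; skew-boats use the exoplanar pair flanking an
in-plane atom, again choosing the pair containing the lowest-numbered
carbon; envelopes take the single dominant atom, half-chairs the
dominant adjacent pair. With the d-pyranose circuit (O5–C1–…–C5) this
reproduces ⁴C₁ at θ ≈ 0 and ¹C₄ at θ ≈ 180, and the published equator
layout (³,OB at φ = 0 through OS₂ at φ = 330). With the NeuAc circuit
(O6–C2–…–C6) the same rule places the favoured ²C₅ chair at θ ≈ 180°
and the inverted ⁵C₂ at θ ≈ 0 — a direct consequence of NeuAc's ring
numbering, worth knowing when reading θ histograms.

Classification of an observed (θ, φ) is by nearest canonical vertex in
great-circle distance; exact ties between an envelope and a half-chair
break toward the envelope (deterministic and documented, nothing
deeper). A useful invariant encoded in the tests: cyclically
relabelling the ring start atom by k positions shifts φ by 120°·k and
mirrors θ for odd k, while the displacement-sign name is unchanged.

**Regions.** θ bands aligned to the 15° binning grid: chair [0, 30)
and (150, 180], envelope/half-chair [30, 60) and (120, 150],
boat/skew-boat [60, 120]. The band edges are a package choice.

## Torsions and circular statistics

Dihedrals use the atan2 construction with the IUPAC sign convention
(cis = 0°, clockwise positive viewed from the second toward the third
atom), wrapped to (−180, 180]. Default glycosidic quadruples:
φ = O5–C1–O–Cn, ψ = C1–O–Cn–C(n−1) for (1→n); φ = O6–C2–O–C3 and
ψ = C2(donor)–O–C3–C2(acceptor) for (2→3); ω = O6–C6–C5–C4 for (1→6),
with the alternative O6–C6–C5–O5 convention available per linkage
(`omega_style: O5`). The printed (2→3) ψ atom labels are ambiguous
across residues; the donor/acceptor reading above is a documented
choice. Circular mean is the resultant direction; spread is
√(−2 ln R̄) in degrees; a vanishing resultant flags the mean undefined.

## Free energies

ΔG_i = kT ln(p_ref/p_i) with the modal bin as reference,
k = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹, T default 298 K (configurable).
Binning is left-closed/right-open, 15° for 1D θ profiles and 10° for
2D (φ, ψ) surfaces; empty bins are +∞ (unvisited, not degenerate) and
render as blank in exports; surface contours default to 2/4/6
kcal/mol. A configurable burn-in discards initial frames (default 0
for synthetic data, where there is no equilibration transient).

**Errors.** A circular block bootstrap over frames: whole blocks of
consecutive frames are resampled with wrap-around, each replicate is
re-binned and re-inverted against the full-data modal bin, and the
per-bin SD across replicates is reported. This is a standard stand-in
for correlation-aware error estimation, not a claim about any
particular published protocol, and outputs are labelled accordingly.
The block length must exceed the slowest dwell scale in the series to
be honest — for the two-state demonstration (minor dwells ≈ 0.2 μs)
the examples use 1 μs blocks (10⁵ frames). Rarer states get larger
error bars, reproducing the familiar error-vs-ΔG growth.

## Exchange kinetics

States are assigned by hysteresis: a frame's label is the core most
recently *entered*, so excursions that leave a core but fail to reach
another are not counted as transitions (recrossing suppression). The
default pucker cores are the chair bands θ < 30° / θ > 150° and the
boat/skew band 60–120°, with the E/HC bands as unassigned buffer;
torsion states use circular ±30° windows around declared (φ, ψ)
centres. Both the core geometry and the hysteresis rule are package
choices — transition-counting protocols in the literature are rarely
specified at this level of detail.

Rates are transition counts divided by total time (μs⁻¹) with exact
Garwood (χ²-based) Poisson 95% intervals. Dwell times are contiguous
residences; first and last segments only see one boundary and are
flagged censored. Counting is invariant to refining the frame interval
of the same path.

## NMR observables

**³J(H,H).** The substituent-adjusted Karplus form
J = P₁cos²θ + P₂cosθ + P₃ + Σᵢ Δχᵢ·[P₄ + P₅cos²(ξᵢθ + P₆|Δχᵢ|)] with
per-substituent relative electronegativities Δχ and orientation
factors ξ = ±1. Coefficients ship as a versioned YAML
(`glycoconf/data/karplus_haasnoot.yaml`) holding the standard
empirical sets for 2/3/4 non-hydrogen substituents; the engine is
value-agnostic and validated on limiting cases (Δχ = 0 reduces exactly
to the classic 3-term curve). Ensemble couplings average J per frame —
never the dihedral — because the curve is nonlinear; table comparison
counts |Δ| ≤ tolerance (default 2 Hz, boundary inclusive) and reports
signed deviations and unmatched pairs.

**Centroid distances.** Per-frame distance between unweighted 6-atom
ring centroids; mean and population SD.

**iRED order parameters.** M_ij = ⟨P₂(μᵢ·μⱼ)⟩ over frames is
eigendecomposed; the five largest eigenmodes are attributed to overall
reorientation (the dimensionality of the rank-2 tumbling space,
configurable) and S²ᵢ = 1 − Σ_internal λ_m m²ᵢ over the rest. Limits:
rigidly co-rotating vectors give S² → 1 (M has rank ≤ 5); independent
isotropic vectors give S² → n_overall/N, a finite-size floor — with N
vectors and finite sampling, per-vector S² in the fully disordered
limit scatters around ≈ 5/N and can individually reach ~0.1, so
disorder statements should be made on the ensemble mean. Per-vector P₂
autocorrelations (FFT-based) are fit to A·exp(−t/τ_f) +
(1−A)·exp(−t/τ_s) by bounded nonlinear least squares from three fixed
starts; non-convergent fits are flagged with NaN times. The
mode-exclusion count and the fitting protocol are standard-practice
defaults, not reconstructions of any specific published pipeline.

## Hydration shells

RDFs use minimum-image distances in orthorhombic boxes (triclinic out
of scope), r_max ≤ half the shortest edge, and 0.05 Å bins *centred*
on multiples of the width (a distance of exactly 3.00 Å falls in
[2.975, 3.025)). Normalisation by exact shell volume and mean target
density gives g(r) = 1 for an ideal gas. Shell occupancy counts
targets whose minimum distance to *any* reference atom lies in a range
(defaults 1.0–2.5 Å and 3.0–5.0 Å) — per-target-minimum for
occupancies, per-pair for g(r), matching the two distinct uses of
these observables. Integrating g·4πr²ρ over a shell reproduces the
direct count for a single reference atom.

## Conformer clustering

Frames (default stride 50) are compared by best-fit RMSD after
optimal superposition (Kabsch); the distance matrix is clustered
agglomeratively with average linkage by default (the criterion is a
package choice), cut either at a distance or to k clusters, and each
cluster is represented by its medoid. Hydrogens are excluded by
default in the CLI. For idealised rings, distinct canonical conformers
sit 0.3–0.45 Å apart after superposition, so cutoffs around 0.2 Å
separate them cleanly at small noise.

## Synthetic trajectories

The generator emulates what a μs trajectory looks like *to the
analyses*: a first-order Markov chain over conformational states at
the frame interval (default 10 ps, the typical recording stride),
with wrapped-Gaussian within-state angular noise (defaults 8° for
pucker coordinates, 15° for torsions — basin widths comparable to
small-glycan free-energy surfaces). Stated populations πᵢ and
pair-exchange rates r (total events per μs per unordered pair) define
a detailed-balance generator K with k_ij = (r/2)/πᵢ, and the
transition matrix is the exact exponential P = exp(KΔt), so rows sum
to 1 and π is stationary to 1e-9 by construction. Chains are sampled
by exact dwell (geometric) jump-chain sampling; one
`numpy.random.default_rng(seed)` stream drives first the chain, then
the emissions, making runs bit-reproducible. Ground truth
(populations, rates, ΔG at the configured temperature) is emitted
alongside every trajectory.

θ coordinates are reflected into [0, 180°], other angles wrap. Ring
trajectories are produced by pushing the latent (θ, φ) series through
the inverse CP transform at fixed Q (default 0.55 Å); a 4-ring
sialyl-Lewis-like mock (three linkages, single-site waters, per-frame
pucker noise) exercises the full pipeline end-to-end.

What the generator does **not** emulate: force-field energetics,
barrier shapes (within-state noise is Gaussian, not Boltzmann over a
potential), correlated multi-ring motion, real water structure, or
experimental noise in couplings. Passing recovery tests therefore
demonstrates that the *analysis machinery* is correct and unbiased on
data with known answers — not that any simulation protocol is
accurate.

## Problem sizes used in validation

Demonstration and validation runs use 10 μs-equivalents (10⁶ frames at
10 ps) for free-energy and rate recovery, 20 seeded replicates per
rate for CI coverage, 200 vectors × 2000 frames for the iRED cone
model, and a few hundred frames of a few thousand uniform points for
RDF flatness. These sizes make the statistical tolerances meaningful
(e.g. per-bin g(r) counts large enough that ±0.02 is a several-σ
band) while keeping full runs around a minute.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Furanose (5-ring) puckering and pseudorotation conventions are out
  of scope; rings are exactly six atoms.
* No reweighting/WHAM/MBAR — direct counting assumes unbiased
  sampling.
* The bootstrap and iRED fitting protocols are documented stand-ins
  (see above); absolute error bars depend on the chosen block length.
* Karplus coefficient sets are shipped as data; fitting coefficients
  to experiment is out of scope.
* PDB/DCD/XTC I/O goes through MDAnalysis; exotic topologies (altloc
  handling, insertion codes) inherit its behaviour.
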