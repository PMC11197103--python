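# Methods

`nmrconf` implements three connected pieces of machinery for the
conformational analysis of fluorinated alkanes by NMR: (i) quantum-mechanical
time-domain simulation of strongly coupled ¹H/¹⁹F spin systems in a
restricted Liouville space, (ii) least-squares extraction of chemical shifts
and scalar couplings from second-order spectra, and (iii) conformer-ensemble
statistics (Boltzmann populations with uncertainty propagation, ensemble
J-averaging, %antiperiplanar scoring and the J-vs-%app correlation).

## Spin-system model

A system is an ordered set of spin-1/2 nuclei (¹H, ¹⁹F), one chemical shift
per spin (ppm), a symmetric scalar-coupling matrix (Hz), the spectrometer's
¹H Larmor frequency (MHz), and optional permutation-symmetry groups
(a methyl rotor carries the symmetric group S₃; two rotors compose to
S₃ × S₃ with 36 operations).  Rotating-frame frequencies are
`shift_ppm × base_MHz × γ/γ_H`, so mixed ¹H/¹⁹F offsets combine correctly.
The high-field Hamiltonian is

    H = Σᵢ ωᵢ Iz(i) + 2π Σ_{i<j} J_ij · T_ij,

with the full `Iᵢ·Iⱼ` coupling between same-isotope spins (required because
the two fluorines of a 1,3-difluoroalkane share one chemical shift and are
strongly coupled) and the secular `Iz Iz` truncation between different
isotopes.  No relaxation superoperators, chemical exchange, shaped pulses or
quadrupolar nuclei are modelled; experimental broadband decoupling is
idealized as zeroing the heteronuclear couplings.

## Restricted Liouville state space

For n spins the Liouville space has dimension 4ⁿ (≈ 4.3 × 10⁹ at n = 16),
but a pulse-acquire experiment populates only a small corner of it.  The
basis is a product basis of unit-Frobenius-norm irreducible spherical
tensors {E, T₁₀, T₁₊₁, T₁₋₁} per spin, reduced in stages:

1. **Correlation-order cap.**  Only states involving at most K spins are
   generated.  Optionally, generation is further restricted to states whose
   non-identity spins form a connected cluster of the J-coupling graph
   (edge threshold 0.01 Hz by default).  The cluster rule is a documented,
   togglable approximation: the exact screening used to produce published
   intermediate dimensions for these molecules lives in prior work, and
   this package does not attempt to reproduce those intermediate counts —
   reduction reports assert monotonicity of the cascade, not specific
   values.
2. **Conservation-law filters.**  At high field the total projection
   quantum number of each isotope is conserved: homonuclear couplings
   conserve the isotope's total m, heteronuclear zz couplings conserve
   every individual m.  The detected isotope starts in L₊ and is filtered
   to total m = +1; every undetected isotope is filtered to total m = 0.
   Both filters are exact for the detected signal, which dense-oracle tests
   confirm at the 10⁻¹² level.  The stricter longitudinal filter (every
   undetected spin restricted to {E, T₁₀}) is also implemented; numerical
   experiments show it is exact only when the undetected spins are mutually
   J-uncoupled or magnetically equivalent, and visibly distorts the
   detected signal otherwise.  The default pipeline therefore uses the
   coherence filters; the longitudinal filter is available as an opt-in
   stronger reduction for topologies where it is valid.
3. **Symmetry adaptation.**  For liquid-state observables only the fully
   symmetric irreducible representation of the equivalent-spin permutation
   group is needed.  The projector is built by orbit averaging: each orbit
   of basis states under the group contributes one symmetric combination
   with coefficients 1/√|orbit|, so the projector columns are orthonormal
   and P = BBᵀ is idempotent to machine precision.  Orbit counting follows
   Burnside's lemma (e.g. 20 symmetric combinations of the 64-state basis
   of one three-spin rotor).  Symmetrization requires the basis to be
   closed under the group; an incompatible truncation raises an error.

Every reduction stage appends `(stage, dimension)` to a provenance record;
`reduction_report` renders the cascade, which is monotone non-increasing by
construction.  For the 16-spin difluoroheptane template with a
correlation-order cap of 4, cluster screening, both coherence filters and
symmetry adaptation, the cascade is 4¹⁶ → 23,188 → 5,002 → 1,390 → 942.

## Liouvillian assembly and propagation

The commutation superoperator L = [H, ·] is assembled directly in the
product basis without forming 2ⁿ × 2ⁿ matrices: each one- or two-spin
Hamiltonian term has a small (4×4 or 16×16) superoperator block computed in
the single- or two-spin tensor basis, which is scattered over the big basis
by vectorized base-4 code arithmetic; components leaving the restricted
basis are dropped.  In the orthonormal tensor basis L is Hermitian, so each
dwell-time step `exp(−iLτ)·v` is computed by a short-recurrence Lanczos
(Krylov) approximation — default subspace dimension 16, full
reorthogonalization, a posteriori error estimate with recursive step
halving at tolerance 10⁻¹⁰ per step — with no dense factorization of L.
Detection is `⟨coil|v⟩` per step with the coil equal to the initial state
(unit coefficient on each single-spin T₁₊₁ state of the detected isotope,
norm √n_detected).

Spectra are produced by exponential apodization (rate chosen so an undamped
line acquires the requested Lorentzian full width at half height, default
0.5 Hz — the shimming criterion of the emulated experiments), zero-filling,
and FFT.  The detected +1 coherence evolves as `exp(−iωt)`; the FID is
conjugated before the transform so resonances land at +offset, and the real
part is then absorption-mode with no phase correction (ideal pulse, zero
dead time).  No first-point scaling is applied, so Parseval's identity
holds exactly for unapodized data; the resulting constant baseline offset
is absorbed by the fit's baseline nuisance parameter.

A dense Hilbert-space route (eigendecomposition of the 2ⁿ Hamiltonian →
transition table → FID synthesized by index-doubling powers → identical
apodization/FFT) serves as the independent oracle for n ≤ 12 spins (the
hard cap; above it only the restricted route is allowed) and as the fast
forward model during fitting.  Transitions below 10⁻⁹ of the strongest
amplitude are dropped; generation and fitting share the same cutoff, so
synthetic round trips are bit-exact.  The two routes agree to better than
10⁻⁹ relative on strongly coupled test systems, and the filters and
symmetry projection change restricted-route spectra by less than 10⁻¹⁰.

## Spectral fitting

Second-order multiplets cannot be read off peak positions, so parameters
are recovered by least squares against simulation.  The objective sums,
over the simultaneously fitted ¹H and ¹⁹F spectra, the squared pointwise
difference between scaled simulated and observed absorption intensities,
each normalized by the observed energy so both nuclei contribute
comparably.  Per-spectrum scale and constant baseline are free nuisance
parameters; they enter linearly and are profiled out in closed form inside
the objective.  Simulated spectra are aligned to the observed axis by
linear interpolation when the grids differ.  Symmetry ties (rotor groups
plus declared whole-molecule permutations, orbits enumerated by brute
force) reduce the free parameters to unique shifts and unique couplings.

The minimizer is the Nelder–Mead simplex, run in a scaled space where all
coordinates are in Hz, with adaptive simplex coefficients above 10
parameters and at most 2 × 10⁴ evaluations per descent.  Two numerical
choices matter:

- **Explicit initial simplex.**  The default simplex (5% of each
  coordinate) would take ~100 Hz steps on absolute shift coordinates and
  lose the basin; the simplex is instead seeded with a fixed physical step
  per stage (≈0.4 × the stage broadening, minimum 0.25 Hz).
- **Multi-resolution schedule.**  A few-Hz parameter displacement moves
  0.5 Hz-wide lines by many linewidths, leaving the native objective almost
  flat ("completely dissimilar spectrum") and full of local minima.  The
  descent therefore first matches both sides under extra Lorentzian
  broadening (default stages 8 → 2 → 0 Hz; the observed spectra are
  re-apodized through their inverse transform), which smooths the error
  surface enough for the simplex to track the global basin, then refines at
  native resolution with tolerances tighter than the reporting precision
  (10⁻⁴ ppm on shifts, 10⁻² Hz on couplings).

Stability is verified by restarting from parameter vectors uniformly
perturbed by ±0.2 Hz (J) and ±0.005 ppm (shifts) — magnitudes well under a
linewidth, so restarts descend at native resolution only — and requiring
all restarts to agree with the best solution within 0.01 Hz.  Accuracy is
verified independently by simulating decoupled spectra from the fitted
parameters and comparing with decoupled observations; a deliberately
swapped J assignment reproduces the coupled spectra it was fitted to but
fails this check.  A single-nucleus fit is demonstrably degenerate: with
two chemically equivalent fluorines, exchanging which fluorine carries a
proton's large vs small coupling leaves the ¹H spectrum identical (< 10⁻¹³)
while changing the ¹⁹F spectrum completely — hence the simultaneous fit.

On twenty seeded noiseless synthetic cases (3–6 spins, mixed ¹H/¹⁹F,
same-isotope shift gaps of 5–30 Hz against couplings of 3–45 Hz, initial
guesses perturbed by up to ±0.5 Hz in J and ±0.01 ppm in shifts) the fit
recovers every coupling to well within ±0.1 Hz — the precision at which
ensemble-averaged couplings extracted this way can be treated as exact.

## Conformer statistics

Populations follow `p_k = g_k exp(−E_k/RT)/Z` with explicit integer
degeneracies (R = 8.31446 J mol⁻¹ K⁻¹, default T = 298 K); they are
invariant under a uniform energy shift, and the stored energies are gauged
to min E = 0.  Treating all energies as relative to E_k with a common
standard deviation σ_E, first-order propagation gives
`∂p_k/∂E_n = p_k p_n/RT` for n ≠ k, hence

    σ_{p_k} = (σ_E/RT) · p_k · sqrt(Σ_{n≠k} p_n²)
            ≤ (σ_E/RT) · p_k · (1 − p_k),

the upper bound avoiding the sum over other probabilities.  This algebra
was re-derived from the distribution itself and is verified against a
10⁵-sample Monte-Carlo perturbation oracle (energies jittered normally,
populations renormalized): agreement is within 5% at the default
σ_E = 0.42 kJ/mol (an energy-difference error estimated by comparing
dissimilar electronic-structure methods on the same torsional scan;
1.1 kJ/mol is the worst-case figure, from noncovalent-interaction
benchmarks).  At σ_E/RT ≈ 0.17 the first-order linearization is accurate
to ~1–2%; the 5% agreement band leaves room for the Monte-Carlo sampling
noise.

Ensemble-averaged couplings are Boltzmann- and degeneracy-weighted sums
`⟨J⟩ = Σ J_n w_n / Σ w_n`, the discrete form of the unbiased Monte-Carlo
estimate of the dihedral-space integral.  Staggered conformers are
enumerated over the alphabet {a, g, g⁻} (3ⁿ labels: 9 for two dihedrals,
81 for four); 9 × 9 population grids condense to 3 × 3 marginals over the
inner (central) or outer dihedral pair with the grand total preserved.
%app for an atom pair is the summed population of conformers classified
antiperiplanar for that pair — classification by dihedral within ±30° of
180°, since energy-minimum structures deviate from perfect staggering but
stay within their well.  The J-vs-%app association is an ordinary
least-squares line with R² from `scipy.stats.linregress`.  Capital/lower
case distinctions between backbone CC–CC and CC–CF dihedral labels are
metadata, not separate types.  Conformer energies and dipoles are consumed
as inputs — no electronic-structure computation is performed — and no
Karplus-based inversion of populations from measured J is attempted.

## Synthetic fixtures

The generators provide every test input with known ground truth:

- **Karplus curves** `J(θ) = A cos²θ + B cosθ + C`, with default
  coefficient sets per family (H–H: 7.8, −1.0, 1.4 Hz, J(180°) ≈ 10.2 Hz;
  H–F: 25.0, −8.0, 3.0 Hz, J(180°) = 36 Hz — the much larger ³J(H,F)
  amplitude).  These are configuration defaults, not fitted constants.
- **Rotamer models**: staggered wells at 180°/±60° with per-dihedral well
  energies (default: anti 0, gauche 2.7 kJ/mol), a 12 kJ/mol penalty for
  adjacent g/g⁻ pairs (syn-pentane-like clash), and a harmonic within-well
  term whose width (12°) is the room-temperature angular standard
  deviation.  Clash screening runs on an idealized tetrahedral chain
  (1.53 Å bonds) and rejects geometries with backbone atoms ≥ 4 bonds
  apart closer than 2.5 Å; the real screening this emulates used full 3-D
  structures, and only the statistical role (a stable ~60% survival,
  reproducible under seed) is reproduced.  Grid-scan integration of ⟨J⟩
  over the continuous torsional surface agrees with the Monte-Carlo
  estimate within its standard error, mirroring the convergence check of
  the emulated procedure.
- **Synthetic spin systems** for fitting: mixed ¹H/¹⁹F systems (one
  fluorine below five spins, two at five and above) with same-isotope shift
  gaps of 5–30 Hz (strong coupling regime: differences comparable to J) or
  150–600 Hz (weak regime), all pairs coupled (H–H 3–12 Hz, H–F 6–45 Hz,
  F–F 4–15 Hz), 0.5 Hz linewidth, sweeps auto-sized to hold every
  multiplet.  Default grids are 2,048 complex points zero-filled to 4,096 —
  a deliberately scaled-down analogue of the 131,072/262,144-point
  experimental grids, chosen because the fit accuracy is set by the
  continuous forward model, not the digital resolution; the acceptance
  script uses 1,024/2,048 for the same reason.  All randomness is
  seed-controlled and bit-reproducible.

What passing these tests shows — and does not show — about real data: the
synthetic spectra are noiseless, perfectly phased, baseline-free and
generated by the same forward model that fits them, so the ±0.1 Hz
recovery demonstrates the correctness and conditioning of the machinery,
not robustness to instrumental artefacts.  Noise injection at a chosen
signal-to-noise ratio is available but no claim about noisy-data precision
is made.  The representative compound templates (1,3-difluoropropane,
2,4-difluoropentanes, 3,5-difluoroheptanes) carry plausible
literature-style parameters authored from the molecular topology; they are
synthetic stand-ins for schema examples and qualitative tests (e.g. the
mirror-asymmetric ¹⁹F multiplet of the 16-spin heptane), not measured
values.

## Numerical choices and limitations

- Krylov subspace 16, per-step tolerance 10⁻¹⁰, recursive halving on
  failure; a step too large for the operator norm raises rather than
  returning silently degraded results.
- Basis states are ordered lexicographically by correlation order then
  label tuple, so sparse patterns and provenance are deterministic.
- Dense simulation refuses above 12 spins; transition amplitudes below
  10⁻⁹ relative are dropped.
- The undetected isotope's carrier has no effect on the detected signal
  (its total Sz commutes with the Hamiltonian); the mean shift is used.
- Tie maps require exact value agreement (10⁻⁹) between tied parameters at
  load time; inconsistent declared ties are an error, not a warning.
- Fits assume absorption-only objectives; dispersion components and
  spectral-region weighting are not modelled.  Initial guesses are
  supplied by the caller (in the emulated workflow they come from quantum
  chemistry, which is out of scope) — there is no automatic peak picking.
- The multi-resolution schedule is a convexification heuristic: a
  sufficiently bad initial guess (multiplets not overlapping even at 8 Hz
  broadening) can still converge to a wrong basin; the stability restarts
  and decoupling validation are the guards against silently accepting such
  a fit.
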