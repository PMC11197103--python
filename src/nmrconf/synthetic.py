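"""Synthetic ground-truth generators for tests and worked examples.

Everything here is seed-controlled and exists to play the statistical role
of real inputs: rotamer ensembles whose J values follow a Karplus curve,
Monte-Carlo dihedral sampling with clash screening on an idealized
tetrahedral chain, strongly coupled mixed ¹H/¹⁹F spin systems with known
parameters, and representative spin-system templates for the
1,3-difluoroalkane family.  The templates carry plausible literature-style
shifts and couplings authored from the molecular topology; they are
synthetic stand-ins, not measured values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .conformers import (
    ConformerEnsemble,
    TOKENS,
    ensemble_average_J,
    is_antiperiplanar,
)
from .fitting import FitParameters, ParamMapping
from .simulator import Spectrum, simulate_spectrum
from .spin_system import AcquisitionParams, SpinSystem, SymmetryGroup

__all__ = [
    "KarplusCurve",
    "HH_KARPLUS",
    "HF_KARPLUS",
    "RotamerModel",
    "karplus_J",
    "sample_dihedrals",
    "build_truth_ensemble",
    "SyntheticCase",
    "make_synthetic_case",
    "perturbed_guess",
    "difluoropropane_system",
    "difluoropentane_system",
    "difluoroheptane_system",
]

WELL_CENTERS = {"a": 180.0, "g": 60.0, "g-": -60.0}


@dataclass(frozen=True)
class KarplusCurve:
    """Vicinal coupling model J(θ) = A·cos²θ + B·cosθ + C (Hz)."""

    A: float
    B: float
    C: float

    def __call__(self, theta_deg) -> np.ndarray | float:
        c = np.cos(np.deg2rad(theta_deg))
        return self.A * c * c + self.B * c + self.C


def karplus_J(curve: KarplusCurve, theta_deg) -> np.ndarray | float:
    """Evaluate a Karplus curve at a dihedral angle in degrees."""
    return curve(theta_deg)


#: default coefficient sets per coupling family; the H–F family has the
#: much larger amplitude characteristic of ³J(H,F)
HH_KARPLUS = KarplusCurve(7.8, -1.0, 1.4)    # J(180°) ≈ 10.2 Hz
HF_KARPLUS = KarplusCurve(25.0, -8.0, 3.0)   # J(180°) = 36.0 Hz


# ---------------------------------------------------------------------- #
# rotamer model with clash screening on an idealized chain
# ---------------------------------------------------------------------- #

_BOND_A = 1.53
_TETRA_DEG = 109.47


@dataclass
class RotamerModel:
    """Staggered rotamer wells on an idealized tetrahedral carbon chain.

    ``well_energies`` holds one {token: kJ/mol} map per dihedral;
    ``pair_penalty_kj`` is added for each adjacent (g, g-) or (g-, g)
    dihedral pair (syn-pentane-like clash); ``clash_min_a`` is the minimum
    allowed distance (Å) between backbone atoms four or more bonds apart.
    """

    n_dihedrals: int
    well_energies: list[dict[str, float]] | None = None
    well_width_deg: float = 12.0
    pair_penalty_kj: float = 12.0
    clash_min_a: float | None = 2.5

    def __post_init__(self) -> None:
        if self.well_energies is None:
            self.well_energies = [
                {"a": 0.0, "g": 2.7, "g-": 2.7}
                for _ in range(self.n_dihedrals)
            ]
        if len(self.well_energies) != self.n_dihedrals:
            raise ValueError("one well-energy map per dihedral is required")
        if not self.well_width_deg > 0:
            raise ValueError("well widths must be > 0")

    def energy_of(self, tokens: tuple[str, ...]) -> float:
        e = sum(self.well_energies[i][t] for i, t in enumerate(tokens))
        for t1, t2 in zip(tokens, tokens[1:]):
            if {t1, t2} == {"g", "g-"}:
                e += self.pair_penalty_kj
        return e

    def energy_continuous(self, dihedrals_deg: np.ndarray) -> np.ndarray:
        """Continuous torsional energy (kJ/mol) for arbitrary dihedral sets:
        the nearest staggered well's energy plus a harmonic restoring term
        whose width parameter is the room-temperature angular standard
        deviation within the well."""
        from .conformers import classify_dihedral

        d = np.atleast_2d(np.asarray(dihedrals_deg, dtype=float))
        rt298 = 8.31446 * 298.0 / 1000.0
        e = np.zeros(d.shape[0])
        tokens = []
        for i in range(self.n_dihedrals):
            toks = [classify_dihedral(t) for t in d[:, i]]
            tokens.append(toks)
            centers = np.array([WELL_CENTERS[t] for t in toks])
            delta = (d[:, i] - centers + 180.0) % 360.0 - 180.0
            e += np.array([self.well_energies[i][t] for t in toks])
            e += rt298 * (delta / self.well_width_deg) ** 2 / 2.0
        for i in range(self.n_dihedrals - 1):
            clash = np.array([
                {t1, t2} == {"g", "g-"}
                for t1, t2 in zip(tokens[i], tokens[i + 1])
            ])
            e += self.pair_penalty_kj * clash
        return e if np.ndim(dihedrals_deg) > 1 else e


def chain_coordinates(dihedrals_deg: np.ndarray) -> np.ndarray:
    """Backbone coordinates of an idealized chain with the given torsions
    (bond 1.53 Å, tetrahedral angles).  d dihedrals → d + 3 atoms."""
    d = len(dihedrals_deg)
    n_atoms = d + 3
    coords = np.zeros((n_atoms, 3))
    coords[1] = [_BOND_A, 0.0, 0.0]
    ang = np.deg2rad(180.0 - _TETRA_DEG)
    coords[2] = coords[1] + _BOND_A * np.array(
        [np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0]
    )
    for k in range(3, n_atoms):
        a, b, c = coords[k - 3], coords[k - 2], coords[k - 1]
        theta = np.deg2rad(dihedrals_deg[k - 3])
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        n1 = np.cross(ab, bc)
        n1 /= np.linalg.norm(n1)
        m1 = np.cross(n1, bc)
        d2 = np.deg2rad(_TETRA_DEG)
        vec = (-bc * np.cos(d2)
               + m1 * np.sin(d2) * np.cos(theta)
               + n1 * np.sin(d2) * np.sin(theta))
        coords[k] = c + _BOND_A * vec
    return coords


def has_clash(dihedrals_deg: np.ndarray, min_dist_a: float) -> bool:
    """True when any pair of backbone atoms ≥ 4 bonds apart comes closer
    than the threshold."""
    xyz = chain_coordinates(np.asarray(dihedrals_deg, dtype=float))
    n = len(xyz)
    for i in range(n):
        for j in range(i + 4, n):
            if np.linalg.norm(xyz[i] - xyz[j]) < min_dist_a:
                return True
    return False


def sample_dihedrals(model: RotamerModel, n_samples: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random dihedral sets with clash screening.

    Returns ``(dihedrals, survived)``: an (n_samples, d) array of angles in
    degrees and the boolean survival mask.  Reproducible under the seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    dihedrals = rng.uniform(-180.0, 180.0,
                            size=(n_samples, model.n_dihedrals))
    if model.clash_min_a is None:
        survived = np.ones(n_samples, dtype=bool)
    else:
        survived = np.array([
            not has_clash(row, model.clash_min_a) for row in dihedrals
        ])
    return dihedrals, survived


def build_truth_ensemble(model: RotamerModel,
                         curves: dict[str, tuple[KarplusCurve, int, float]],
                         T: float = 298.0,
                         within_well_points: int = 1
                         ) -> tuple[ConformerEnsemble, dict[str, float]]:
    """Staggered ensemble with Karplus-governed J values and the recorded
    ground-truth Boltzmann averages.

    ``curves`` maps a pair name to ``(curve, dihedral_index, offset_deg)``:
    the pair's dihedral is the backbone dihedral at that index plus the
    offset.  With ``within_well_points > 1`` the per-conformer J is averaged
    over a symmetric grid of that many points spanning ±width around the
    well centre (harmonic-well smearing).
    """
    labels = ["".join(t) for t in
              itertools.product(TOKENS, repeat=model.n_dihedrals)]
    tokens = [tuple(t) for t in
              itertools.product(TOKENS, repeat=model.n_dihedrals)]
    energies = np.array([model.energy_of(t) for t in tokens])
    j_table: dict[str, np.ndarray] = {}
    for pair, (curve, idx, offset) in curves.items():
        vals = []
        for t in tokens:
            center = WELL_CENTERS[t[idx]] + offset
            if within_well_points > 1:
                grid = center + np.linspace(-model.well_width_deg,
                                            model.well_width_deg,
                                            within_well_points)
                vals.append(float(np.mean(curve(grid))))
            else:
                vals.append(float(curve(center)))
        j_table[pair] = np.array(vals)
    ens = ConformerEnsemble(labels, energies, j_table=j_table)
    truth = {pair: ensemble_average_J(ens, T, pair) for pair in curves}
    return ens, truth


def app_geometry_map(model: RotamerModel, dihedral_index: int,
                     offset_deg: float = 0.0,
                     window_deg: float = 30.0) -> dict[str, bool]:
    """Conformer-label → antiperiplanar classification for the pair whose
    dihedral is backbone dihedral ``dihedral_index`` plus ``offset_deg``."""
    out = {}
    for t in itertools.product(TOKENS, repeat=model.n_dihedrals):
        theta = WELL_CENTERS[t[dihedral_index]] + offset_deg
        out["".join(t)] = is_antiperiplanar(theta, window_deg)
    return out


# ---------------------------------------------------------------------- #
# synthetic spin systems and spectra with known truth
# ---------------------------------------------------------------------- #

@dataclass
class SyntheticCase:
    """A generated fitting problem with its ground truth."""

    system: SpinSystem
    acquisitions: dict[str, AcquisitionParams]
    spectra: dict[str, Spectrum]
    noisy_spectra: dict[str, Spectrum] | None
    truth: FitParameters
    mapping: ParamMapping
    seed: int


def make_synthetic_case(n_spins: int, regime: str = "strong",
                        seed: int = 0, snr: float | None = None,
                        n_points: int = 2048,
                        zerofill_to: int = 4096) -> SyntheticCase:
    """Generate a mixed ¹H/¹⁹F spin system and its noiseless spectrum pair.

    In the ``"strong"`` regime same-isotope shift differences are drawn
    comparable to the couplings (second-order multiplets); ``"weak"`` places
    them hundreds of Hz apart (first-order).  Spectra are simulated through
    the standard pipeline on a sweep wide enough to hold every multiplet;
    ``snr`` adds white Gaussian noise at that peak signal-to-noise ratio in
    a separate noisy copy.
    """
    if not 2 <= n_spins <= 12:
        raise ValueError("n_spins must be between 2 and 12")
    if regime not in ("strong", "weak"):
        raise ValueError("regime must be 'strong' or 'weak'")
    rng = np.random.default_rng(seed)
    base_mhz = 500.0
    n_f = 1 if n_spins <= 4 else 2
    n_h = n_spins - n_f

    from .spin_system import ISOTOPES
    gamma_f = ISOTOPES["19F"].gamma_ratio

    if regime == "strong":
        h_gaps_hz = rng.uniform(5.0, 30.0, size=n_h - 1)
        f_gaps_hz = rng.uniform(5.0, 30.0, size=max(n_f - 1, 0))
    else:
        h_gaps_hz = rng.uniform(150.0, 400.0, size=n_h - 1)
        f_gaps_hz = rng.uniform(300.0, 600.0, size=max(n_f - 1, 0))
    h_shifts = 3.0 + np.concatenate([[0.0], np.cumsum(h_gaps_hz)]) / base_mhz
    f_shifts = -180.0 + np.concatenate(
        [[0.0], np.cumsum(f_gaps_hz)]) / (base_mhz * gamma_f)

    spins = ("1H",) * n_h + ("19F",) * n_f
    shifts = np.concatenate([h_shifts, f_shifts])
    j = np.zeros((n_spins, n_spins))
    for a in range(n_spins):
        for b in range(a + 1, n_spins):
            both_h = a < n_h and b < n_h
            both_f = a >= n_h and b >= n_h
            if both_h:
                j[a, b] = rng.uniform(3.0, 12.0)
            elif both_f:
                j[a, b] = rng.uniform(4.0, 15.0)
            else:
                j[a, b] = rng.uniform(6.0, 45.0)
            j[b, a] = j[a, b]
    system = SpinSystem(spins=spins, shifts_ppm=shifts, j_hz=j,
                        base_frequency_mhz=base_mhz)

    acquisitions: dict[str, AcquisitionParams] = {}
    spectra: dict[str, Spectrum] = {}
    noisy: dict[str, Spectrum] = {}
    for iso in system.isotopes_present():
        idx = system.isotope_indices(iso)
        gamma = system.spins[idx[0]].gamma_ratio
        freq = np.array([system.larmor_hz(i) for i in idx])
        halfwidth = np.array([np.abs(j[i]).sum() for i in idx]) / 2.0
        lo = (freq - halfwidth).min() - 60.0
        hi = (freq + halfwidth).max() + 60.0
        center = 0.5 * (lo + hi) / (base_mhz * gamma)
        sweep = (hi - lo) / (base_mhz * gamma)
        acq = AcquisitionParams(iso, n_points, zerofill_to, sweep, center,
                                line_broadening_hz=0.5)
        acquisitions[iso] = acq
        spec = simulate_spectrum(system, acq, method="hilbert")
        spectra[iso] = spec
        if snr is not None:
            noise = rng.normal(0.0, spec.absorption.max() / snr,
                               size=spec.intensity.shape)
            noisy[iso] = replace(spec, intensity=spec.intensity + noise)

    mapping = ParamMapping.from_system(system)
    truth = FitParameters.from_system(system, mapping, linewidth_hz=0.5)
    return SyntheticCase(system, acquisitions, spectra,
                         noisy or None, truth, mapping, seed)


def perturbed_guess(truth: FitParameters, rng: np.random.Generator,
                    dj_hz: float = 0.5,
                    dshift_ppm: float = 0.01) -> FitParameters:
    """Initial guess: truth uniformly perturbed by up to ±dj on J and
    ±dshift on shifts (the quality of a good theoretical prediction)."""
    g = truth.copy()
    g.j_hz = g.j_hz + rng.uniform(-dj_hz, dj_hz, size=g.j_hz.shape)
    g.shifts_ppm = g.shifts_ppm + rng.uniform(
        -dshift_ppm, dshift_ppm, size=g.shifts_ppm.shape)
    return g


# ---------------------------------------------------------------------- #
# representative 1,3-difluoroalkane templates
# ---------------------------------------------------------------------- #

def _sym_j(n: int, entries: dict[tuple[int, int], float]) -> np.ndarray:
    j = np.zeros((n, n))
    for (a, b), v in entries.items():
        j[a, b] = j[b, a] = v
    return j


def difluoropropane_system(base_mhz: float = 500.0) -> SpinSystem:
    """1,3-difluoropropane (8 spins: 2 ¹⁹F + 6 ¹H), representative values.

    Order: F1, F3, H1a, H1b, H2a, H2b, H3a, H3b.
    """
    shifts = [-219.8, -219.8, 4.52, 4.52, 1.98, 1.98, 4.52, 4.52]
    j = _sym_j(8, {
        (0, 2): 47.3, (0, 3): 47.3,        # 2J HF
        (0, 4): 25.6, (0, 5): 25.6,        # 3J HF
        (1, 6): 47.3, (1, 7): 47.3,
        (1, 4): 25.6, (1, 5): 25.6,
        (2, 4): 5.9, (2, 5): 5.9, (3, 4): 5.9, (3, 5): 5.9,   # 3J HH
        (6, 4): 5.9, (6, 5): 5.9, (7, 4): 5.9, (7, 5): 5.9,
        (2, 3): -10.1, (4, 5): -14.6, (6, 7): -10.1,          # 2J HH
        (0, 1): 4.5,                                          # 4J FF
    })
    perm = (1, 0, 6, 7, 4, 5, 2, 3)
    return SpinSystem(
        spins=("19F", "19F") + ("1H",) * 6, shifts_ppm=shifts, j_hz=j,
        base_frequency_mhz=base_mhz, molecule_permutations=[perm],
    )


def difluoropentane_system(anti: bool = True,
                           base_mhz: float = 500.0) -> SpinSystem:
    """2,4-difluoropentane (12 spins: 2 ¹⁹F + 10 ¹H), representative values.

    Order: F2, F4, CH3(C1)×3, H2, H3a, H3b, H4, CH3(C5)×3.  In the
    C2-symmetric anti isomer the rotation exchanges the two C3 protons
    (equivalent, one shift); in the meso syn isomer the mirror fixes them
    (diastereotopic, two shifts).
    """
    d_f = -172.5 if anti else -169.8
    h3 = (1.88, 1.88) if anti else (1.82, 1.95)
    shifts = [d_f, d_f, 1.36, 1.36, 1.36, 4.78, h3[0], h3[1], 4.78,
              1.36, 1.36, 1.36]
    me1, me2 = (2, 3, 4), (9, 10, 11)
    j_entries: dict[tuple[int, int], float] = {
        (0, 5): 48.6, (1, 8): 48.6,       # 2J HF
        (0, 6): 16.5, (0, 7): 28.0,       # 3J HF to C3
        (5, 6): 6.8, (5, 7): 4.2,         # 3J HH C2-C3
        (6, 7): -14.7,                    # 2J C3
        (0, 1): 3.2,                      # 4J FF
    }
    if anti:  # C2 maps H3a <-> H3b
        j_entries.update({(1, 7): 16.5, (1, 6): 28.0,
                          (8, 7): 6.8, (8, 6): 4.2})
        perm = (1, 0, 9, 10, 11, 8, 7, 6, 5, 2, 3, 4)
    else:     # mirror fixes H3a and H3b
        j_entries.update({(1, 6): 16.5, (1, 7): 28.0,
                          (8, 6): 6.8, (8, 7): 4.2})
        perm = (1, 0, 9, 10, 11, 8, 6, 7, 5, 2, 3, 4)
    for m in me1:
        j_entries[(m, 5)] = 6.2           # 3J CH3-H2
        j_entries[(0, m)] = 23.6          # 3J CH3-F2
    for m in me2:
        j_entries[(m, 8)] = 6.2
        j_entries[(1, m)] = 23.6
    return SpinSystem(
        spins=("19F", "19F") + ("1H",) * 10,
        shifts_ppm=shifts, j_hz=_sym_j(12, j_entries),
        base_frequency_mhz=base_mhz,
        symmetry_groups=[SymmetryGroup(me1, "S3"), SymmetryGroup(me2, "S3")],
        molecule_permutations=[perm],
    )


def difluoroheptane_system(anti: bool = True,
                           base_mhz: float = 500.0) -> SpinSystem:
    """3,5-difluoroheptane (16 spins: 2 ¹⁹F + 14 ¹H), representative values.

    Order: F3, F5, CH3(C1)×3, H2a, H2b, H3, H4a, H4b, H5, H6a, H6b,
    CH3(C7)×3.  The two methyl rotors carry S₃ symmetry groups each (the
    composite group has 36 operations); the two fluorines share one
    chemical shift but couple to different protons, which is what makes the
    ¹⁹F multiplet second-order.
    """
    d_f = -184.6 if anti else -181.9
    h4 = (1.79, 1.79) if anti else (1.74, 1.86)
    shifts = [d_f, d_f, 0.97, 0.97, 0.97, 1.56, 1.69, 4.43,
              h4[0], h4[1], 4.43, 1.56, 1.69, 0.97, 0.97, 0.97]
    me1, me2 = (2, 3, 4), (13, 14, 15)
    j_entries: dict[tuple[int, int], float] = {
        (0, 7): 48.9, (1, 10): 48.9,      # 2J HF
        (0, 5): 17.0, (0, 6): 27.5,       # 3J F3 to C2 protons
        (1, 11): 17.0, (1, 12): 27.5,
        (0, 8): 15.2, (0, 9): 31.8,       # 3J F3 to C4 protons
        (0, 10): 2.1, (1, 7): 2.1,        # 4J F-H(CF)
        (5, 6): -14.2, (8, 9): -14.8, (11, 12): -14.2,   # 2J HH
        (5, 7): 6.3, (6, 7): 4.1,         # 3J C2-C3
        (11, 10): 6.3, (12, 10): 4.1,
        (7, 8): 7.1, (7, 9): 3.6,         # 3J C3-C4
        (0, 1): 2.8,                      # 5J FF
    }
    if anti:  # C2 maps H4a <-> H4b
        j_entries.update({(1, 9): 15.2, (1, 8): 31.8,
                          (10, 9): 7.1, (10, 8): 3.6})
        perm = (1, 0, 13, 14, 15, 11, 12, 10, 9, 8, 7, 5, 6, 2, 3, 4)
    else:     # mirror fixes H4a and H4b
        j_entries.update({(1, 8): 15.2, (1, 9): 31.8,
                          (10, 8): 7.1, (10, 9): 3.6})
        perm = (1, 0, 13, 14, 15, 11, 12, 10, 8, 9, 7, 5, 6, 2, 3, 4)
    for m in me1:
        j_entries[(m, 5)] = 7.4
        j_entries[(m, 6)] = 7.4
    for m in me2:
        j_entries[(m, 11)] = 7.4
        j_entries[(m, 12)] = 7.4
    return SpinSystem(
        spins=("19F", "19F") + ("1H",) * 14,
        shifts_ppm=shifts, j_hz=_sym_j(16, j_entries),
        base_frequency_mhz=base_mhz,
        symmetry_groups=[SymmetryGroup(me1, "S3"), SymmetryGroup(me2, "S3")],
        molecule_permutations=[perm],
    )
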