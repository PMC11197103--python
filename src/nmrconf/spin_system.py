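"""Spin-system model: nuclei, shifts, scalar couplings, and symmetry.

This module defines the validated container that every simulation and
fitting operation consumes.  A spin system is an ordered list of spin-1/2
nuclei (here ¹H and ¹⁹F), one chemical shift per spin (ppm), a symmetric
scalar-coupling matrix (Hz), the spectrometer's ¹H Larmor frequency (MHz),
and an optional list of permutation-symmetry groups (e.g. the S₃ group of
a rapidly rotating methyl rotor).

Spin ordering in input files is authoritative: all matrices are indexed in
file order, 0-based internally and 1-based in files and reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import factorial
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "Isotope",
    "ISOTOPES",
    "SymmetryGroup",
    "SpinSystem",
    "AcquisitionParams",
    "SpinSystemError",
    "ParameterTies",
    "load_spin_system",
    "save_spin_system",
    "validate_equivalence",
    "H1_ACQUISITION",
    "F19_ACQUISITION",
]

#: gyromagnetic ratios in rad s^-1 T^-1 (CODATA-style values)
_GAMMA = {"1H": 26.7522128e7, "19F": 25.18148e7}


class SpinSystemError(ValueError):
    """Raised when a spin-system description violates an invariant."""


@dataclass(frozen=True)
class Isotope:
    """A spin-1/2 NMR nucleus.

    Attributes
    ----------
    symbol : str
        Text label, e.g. ``"1H"`` or ``"19F"``.
    spin : float
        Spin quantum number; only 1/2 is supported.
    gamma_ratio : float
        Gyromagnetic ratio relative to ¹H (dimensionless, > 0).
    """

    symbol: str
    spin: float
    gamma_ratio: float

    def __post_init__(self) -> None:
        if self.spin != 0.5:
            raise SpinSystemError(
                f"isotope {self.symbol!r}: only spin-1/2 nuclei are supported "
                f"(got spin={self.spin})"
            )
        if not self.gamma_ratio > 0:
            raise SpinSystemError(
                f"isotope {self.symbol!r}: gamma_ratio must be > 0"
            )


ISOTOPES: dict[str, Isotope] = {
    sym: Isotope(sym, 0.5, _GAMMA[sym] / _GAMMA["1H"]) for sym in _GAMMA
}


@dataclass(frozen=True)
class SymmetryGroup:
    """A set of mutually permutable equivalent spins.

    The ``label`` names the permutation group; ``"S2"``/``"S3"``/... denote
    the full symmetric group on the member spins (a three-fold rotor such as
    a methyl group carries ``"S3"``).
    """

    spins: tuple[int, ...]
    label: str = "S"

    @property
    def order(self) -> int:
        """Number of group elements (k! for the symmetric group on k spins)."""
        return factorial(len(self.spins))


@dataclass
class AcquisitionParams:
    """Pulse-acquire acquisition settings for one detected isotope.

    ``sweep_ppm`` and ``center_ppm`` refer to the detected isotope's own
    ppm scale; ``line_broadening_hz`` is the exponential apodization rate
    expressed as the Lorentzian full width at half height it imposes.
    """

    detect_isotope: str
    n_points: int
    zerofill_to: int
    sweep_ppm: float
    center_ppm: float
    line_broadening_hz: float = 0.5

    def __post_init__(self) -> None:
        if self.detect_isotope not in ISOTOPES:
            raise SpinSystemError(
                f"acquisition: unknown detect_isotope {self.detect_isotope!r}"
            )
        if self.zerofill_to < self.n_points:
            raise SpinSystemError(
                "acquisition: zerofill_to must be >= n_points "
                f"({self.zerofill_to} < {self.n_points})"
            )
        if not self.sweep_ppm > 0:
            raise SpinSystemError("acquisition: sweep_ppm must be > 0")

    def sweep_hz(self, base_frequency_mhz: float) -> float:
        """Spectral width in Hz at the given ¹H base frequency."""
        gamma = ISOTOPES[self.detect_isotope].gamma_ratio
        return self.sweep_ppm * base_frequency_mhz * gamma

    def dwell_s(self, base_frequency_mhz: float) -> float:
        """Dwell time (seconds per complex point)."""
        return 1.0 / self.sweep_hz(base_frequency_mhz)


#: high-field acquisition defaults used throughout: ¹H 131,072 points
#: zero-filled to 262,144 over a 14 ppm sweep centred at 5.0 ppm; ¹⁹F
#: 262,144 points zero-filled to 524,288 over a 50 ppm sweep.
H1_ACQUISITION = AcquisitionParams("1H", 131072, 262144, 14.0, 5.0, 0.5)
F19_ACQUISITION = AcquisitionParams("19F", 262144, 524288, 50.0, -180.0, 0.5)


@dataclass
class SpinSystem:
    """A validated liquid-state spin system.

    Attributes
    ----------
    spins : tuple of Isotope
        Ordered nuclei; order matches file order.
    shifts_ppm : ndarray, shape (n,)
        Chemical shift of each spin in ppm on its isotope's scale.
    j_hz : ndarray, shape (n, n)
        Symmetric scalar-coupling matrix in Hz with zero diagonal.
    base_frequency_mhz : float
        ¹H Larmor frequency of the magnet in MHz.
    symmetry_groups : list of SymmetryGroup
        Pairwise-disjoint groups of equivalent spins.
    molecule_permutations : list of tuple
        Extra whole-molecule symmetry permutations (0-based images),
        used only for parameter tying during fitting.
    """

    spins: tuple[Isotope, ...]
    shifts_ppm: np.ndarray
    j_hz: np.ndarray
    base_frequency_mhz: float
    symmetry_groups: list[SymmetryGroup] = field(default_factory=list)
    molecule_permutations: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spins = tuple(
            ISOTOPES[s] if isinstance(s, str) else s for s in self.spins
        )
        self.shifts_ppm = np.asarray(self.shifts_ppm, dtype=float)
        self.j_hz = np.asarray(self.j_hz, dtype=float)
        self.validate()

    # ------------------------------------------------------------------ #
    @property
    def n_spins(self) -> int:
        return len(self.spins)

    def isotope_indices(self, symbol: str) -> list[int]:
        """0-based indices of all spins of the given isotope."""
        return [i for i, iso in enumerate(self.spins) if iso.symbol == symbol]

    def isotopes_present(self) -> list[str]:
        out: list[str] = []
        for iso in self.spins:
            if iso.symbol not in out:
                out.append(iso.symbol)
        return out

    def larmor_hz(self, i: int) -> float:
        """Absolute rotating-frame frequency of spin i in Hz
        (shift_ppm × base_frequency_MHz × gamma_ratio)."""
        return (
            self.shifts_ppm[i]
            * self.base_frequency_mhz
            * self.spins[i].gamma_ratio
        )

    def coupling_graph(self, cutoff_hz: float = 0.01):
        """J-coupling graph: nodes are spins, edges where \\|J\\| > cutoff."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_spins))
        n = self.n_spins
        for i in range(n):
            for j in range(i + 1, n):
                if abs(self.j_hz[i, j]) > cutoff_hz:
                    g.add_edge(i, j)
        return g

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Check all structural invariants, raising SpinSystemError with the
        offending field named."""
        n = self.n_spins
        if n == 0:
            raise SpinSystemError("spins: empty spin system")
        if self.shifts_ppm.shape != (n,):
            raise SpinSystemError(
                f"shifts_ppm: expected {n} values, got {self.shifts_ppm.shape}"
            )
        if not np.all(np.isfinite(self.shifts_ppm)):
            raise SpinSystemError("shifts_ppm: all shifts must be finite")
        if self.j_hz.shape != (n, n):
            raise SpinSystemError(
                f"j_hz: expected shape ({n}, {n}), got {self.j_hz.shape}"
            )
        if not np.all(np.isfinite(self.j_hz)):
            raise SpinSystemError("j_hz: all couplings must be finite")
        asym = np.argwhere(~np.isclose(self.j_hz, self.j_hz.T, atol=1e-12))
        if asym.size:
            i, j = asym[0]
            raise SpinSystemError(
                f"j_hz: matrix not symmetric, J[{i + 1},{j + 1}]="
                f"{self.j_hz[i, j]} != J[{j + 1},{i + 1}]={self.j_hz[j, i]}"
            )
        if np.any(self.j_hz.diagonal() != 0.0):
            raise SpinSystemError("j_hz: diagonal must be zero")
        if not self.base_frequency_mhz > 0:
            raise SpinSystemError("base_frequency_mhz: must be > 0")

        seen: set[int] = set()
        for g in self.symmetry_groups:
            idx = set(g.spins)
            if not idx.issubset(range(n)):
                raise SpinSystemError(
                    f"symmetry_groups: spin index out of range in {g.spins}"
                )
            if idx & seen:
                raise SpinSystemError(
                    "symmetry_groups: groups must be pairwise disjoint"
                )
            seen |= idx
            members = sorted(idx)
            ref = members[0]
            for m in members[1:]:
                if self.spins[m].symbol != self.spins[ref].symbol:
                    raise SpinSystemError(
                        f"symmetry_groups: spins {ref + 1} and {m + 1} in one "
                        "group have different isotopes"
                    )
                if not np.isclose(self.shifts_ppm[m], self.shifts_ppm[ref]):
                    raise SpinSystemError(
                        f"symmetry_groups: member shifts differ "
                        f"(spins {ref + 1}, {m + 1})"
                    )
            for k in range(n):
                if k in idx:
                    continue
                outside = self.j_hz[members, k]
                if not np.allclose(outside, outside[0], atol=1e-9):
                    raise SpinSystemError(
                        f"symmetry_groups: members {tuple(m + 1 for m in members)} "
                        f"do not couple identically to spin {k + 1}"
                    )
        for perm in self.molecule_permutations:
            if sorted(perm) != list(range(n)):
                raise SpinSystemError(
                    f"molecule_permutations: {perm} is not a permutation of "
                    f"0..{n - 1}"
                )

    def decoupled(self, isotope: str) -> "SpinSystem":
        """Copy of the system with all couplings between ``isotope`` and every
        other isotope zeroed (ideal broadband decoupling)."""
        j = self.j_hz.copy()
        idx = self.isotope_indices(isotope)
        other = [i for i in range(self.n_spins) if i not in idx]
        for i in idx:
            j[i, other] = 0.0
            j[other, i] = 0.0
        return replace(self, j_hz=j)


# ---------------------------------------------------------------------- #
# structured-text (YAML) round trip; indices in files are 1-based
# ---------------------------------------------------------------------- #

def load_spin_system(path: str | Path) -> SpinSystem:
    """Load and validate a spin system from a structured-text (YAML) file.

    The file holds the fields of :class:`SpinSystem` with 1-based spin
    indices; ``j_hz`` is either a full matrix (list of rows) or a sparse
    ``{entries: [[i, j, value], ...]}`` block.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message path
        raise SpinSystemError(f"{path}: parse failure: {exc}") from exc
    if not isinstance(doc, dict):
        raise SpinSystemError(f"{path}: expected a mapping at top level")
    try:
        spins = [str(s) for s in doc["spins"]]
        shifts = np.asarray(doc["shifts_ppm"], dtype=float)
        base = float(doc["base_frequency_mhz"])
    except KeyError as exc:
        raise SpinSystemError(f"{path}: missing required field {exc}") from exc
    n = len(spins)
    for s in spins:
        if s not in ISOTOPES:
            raise SpinSystemError(f"spins: unknown or unsupported isotope {s!r}")

    raw_j = doc.get("j_hz", None)
    if raw_j is None:
        j = np.zeros((n, n))
    elif isinstance(raw_j, dict) and "entries" in raw_j:
        j = np.zeros((n, n))
        for ent in raw_j["entries"]:
            i, k, v = int(ent[0]) - 1, int(ent[1]) - 1, float(ent[2])
            if not (0 <= i < n and 0 <= k < n):
                raise SpinSystemError(
                    f"j_hz: entry index out of range in {ent}"
                )
            j[i, k] = j[k, i] = v
    else:
        j = np.asarray(raw_j, dtype=float)
        if j.shape != (n, n):
            raise SpinSystemError(
                f"j_hz: matrix dimensions {j.shape} inconsistent with "
                f"{n} spins"
            )

    groups = []
    for g in doc.get("symmetry_groups", []) or []:
        groups.append(
            SymmetryGroup(
                spins=tuple(int(i) - 1 for i in g["spins"]),
                label=str(g.get("group", "S")),
            )
        )
    perms = [
        tuple(int(i) - 1 for i in p)
        for p in doc.get("molecule_permutations", []) or []
    ]
    return SpinSystem(
        spins=tuple(ISOTOPES[s] for s in spins),
        shifts_ppm=shifts,
        j_hz=j,
        base_frequency_mhz=base,
        symmetry_groups=groups,
        molecule_permutations=perms,
    )


def save_spin_system(system: SpinSystem, path: str | Path) -> None:
    """Serialize a spin system to the structured-text schema (1-based)."""
    doc = {
        "spins": [iso.symbol for iso in system.spins],
        "shifts_ppm": [float(x) for x in system.shifts_ppm],
        "base_frequency_mhz": float(system.base_frequency_mhz),
        "j_hz": [[float(x) for x in row] for row in system.j_hz],
    }
    if system.symmetry_groups:
        doc["symmetry_groups"] = [
            {"spins": [i + 1 for i in g.spins], "group": g.label}
            for g in system.symmetry_groups
        ]
    if system.molecule_permutations:
        doc["molecule_permutations"] = [
            [i + 1 for i in p] for p in system.molecule_permutations
        ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------- #
# parameter tying
# ---------------------------------------------------------------------- #

@dataclass
class ParameterTies:
    """Map of parameters forced equal by symmetry.

    ``shift_groups`` lists orbits of spin indices with tied shifts (only
    orbits of size > 1); ``j_groups`` lists orbits of unordered spin pairs
    with tied couplings.  ``n_unique_shifts``/``n_unique_j`` count free
    parameters including untied singletons (zero couplings excluded from
    the J count).
    """

    shift_groups: list[tuple[int, ...]]
    j_groups: list[tuple[tuple[int, int], ...]]
    n_unique_shifts: int
    n_unique_j: int


def _generated_group(n: int, generators: list[tuple[int, ...]],
                     cap: int = 100000) -> list[tuple[int, ...]]:
    """Closure of a permutation generator set (permutations as image tuples)."""
    ident = tuple(range(n))
    group = {ident}
    frontier = [ident]
    while frontier:
        new = []
        for g in frontier:
            for h in generators:
                prod = tuple(g[h[i]] for i in range(n))
                if prod not in group:
                    group.add(prod)
                    new.append(prod)
                    if len(group) > cap:
                        raise SpinSystemError(
                            "symmetry group closure exceeds cap; check "
                            "declared permutations"
                        )
        frontier = new
    return sorted(group)


def symmetry_permutations(system: SpinSystem) -> list[tuple[int, ...]]:
    """All permutations of the composite symmetry group (direct product of
    the per-group symmetric groups and any declared molecule permutations)."""
    from itertools import permutations as iperm

    n = system.n_spins
    gens: list[tuple[int, ...]] = []
    for g in system.symmetry_groups:
        for img in iperm(g.spins):
            p = list(range(n))
            for src, dst in zip(g.spins, img):
                p[src] = dst
            gens.append(tuple(p))
    gens.extend(system.molecule_permutations)
    return _generated_group(n, gens)


def validate_equivalence(system: SpinSystem) -> ParameterTies:
    """Compute the parameter-tying map implied by the symmetry groups and any
    declared molecule-level permutations.

    Orbits are enumerated by brute force over the generated permutation
    group: spins in one orbit share a chemical shift; unordered spin pairs
    in one orbit share a J value.  Declared ties are checked for consistency
    with the stored shift/J values.
    """
    n = system.n_spins
    perms = symmetry_permutations(system)

    # spin orbits
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for p in perms:
        for i in range(n):
            union(i, p[i])
    orbits: dict[int, list[int]] = {}
    for i in range(n):
        orbits.setdefault(find(i), []).append(i)
    shift_groups = [tuple(v) for v in orbits.values() if len(v) > 1]
    for grp in shift_groups:
        vals = system.shifts_ppm[list(grp)]
        if not np.allclose(vals, vals[0]):
            raise SpinSystemError(
                f"inconsistent declared ties: shifts of spins "
                f"{tuple(i + 1 for i in grp)} are tied but differ"
            )

    # pair orbits
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pindex = {p: k for k, p in enumerate(pairs)}
    pparent = list(range(len(pairs)))

    def pfind(x: int) -> int:
        while pparent[x] != x:
            pparent[x] = pparent[pparent[x]]
            x = pparent[x]
        return x

    for p in perms:
        for k, (i, j) in enumerate(pairs):
            a, b = p[i], p[j]
            tgt = pindex[(a, b) if a < b else (b, a)]
            ra, rb = pfind(k), pfind(tgt)
            if ra != rb:
                pparent[max(ra, rb)] = min(ra, rb)
    porbits: dict[int, list[tuple[int, int]]] = {}
    for k, pr in enumerate(pairs):
        porbits.setdefault(pfind(k), []).append(pr)
    j_groups = [tuple(v) for v in porbits.values() if len(v) > 1]
    for grp in j_groups:
        vals = [system.j_hz[i, j] for i, j in grp]
        if not np.allclose(vals, vals[0], atol=1e-9):
            raise SpinSystemError(
                f"inconsistent declared ties: couplings of pairs "
                f"{[(i + 1, j + 1) for i, j in grp]} are tied but differ"
            )

    n_unique_shifts = len(orbits)
    nonzero_orbits = sum(
        1
        for v in porbits.values()
        if any(abs(system.j_hz[i, j]) > 0 for i, j in v)
    )
    return ParameterTies(
        shift_groups=shift_groups,
        j_groups=j_groups,
        n_unique_shifts=n_unique_shifts,
        n_unique_j=nonzero_orbits,
    )
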