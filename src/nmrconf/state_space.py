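"""Restricted Liouville-space product-operator basis and its reductions.

For n spin-1/2 nuclei the full Liouville space has dimension 4ⁿ.  Liquid
state pulse-acquire experiments populate only a small corner of it: high
orders of spin correlation stay empty, per-isotope total coherence order
is conserved at high field, and equivalent-spin permutation symmetry means
only the fully symmetric irreducible representation is needed.  This module
builds the product basis of irreducible spherical tensor operators and
applies that reduction cascade, keeping a provenance record of the
dimension after every stage.

Single-spin operator labels (unit Frobenius norm):

====  ========  =====================  ==
code  label     operator               m
====  ========  =====================  ==
0     ``E``     E/√2                    0
1     ``T10``   √2·Iz                   0
2     ``T1+1``  −I₊                    +1
3     ``T1-1``  I₋                     −1
====  ========  =====================  ==
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .spin_system import SpinSystem, SymmetryGroup

__all__ = [
    "LABELS",
    "LABEL_M",
    "ProductState",
    "ProductBasis",
    "SymmetrizedBasis",
    "build_basis",
    "filter_longitudinal",
    "filter_coherence",
    "symmetrize",
    "reduction_report",
]

LABELS = ("E", "T10", "T1+1", "T1-1")
#: coherence (projection) index m of each single-spin label
LABEL_M = np.array([0, 0, 1, -1], dtype=np.int64)
#: labels admitted by the longitudinal filter
_LONGITUDINAL = (0, 1)


@dataclass(frozen=True)
class ProductState:
    """One product-operator state, described by its per-spin labels."""

    labels: tuple[int, ...]

    @property
    def correlation_order(self) -> int:
        """Number of spins carrying a non-identity label."""
        return sum(1 for l in self.labels if l != 0)

    @property
    def coherence_order(self) -> int:
        """Sum of the projection indices m over all spins."""
        return int(LABEL_M[list(self.labels)].sum())

    def __str__(self) -> str:
        return "⊗".join(LABELS[l] for l in self.labels)


class ProductBasis:
    """Ordered set of product states with reduction provenance.

    States are stored as an integer label array of shape ``(dimension,
    n_spins)`` ordered lexicographically by correlation order and then by
    label tuple, so sparse patterns are reproducible.
    """

    def __init__(self, n_spins: int, labels: np.ndarray,
                 provenance: list[tuple[str, int]]):
        self.n_spins = int(n_spins)
        self.labels = np.asarray(labels, dtype=np.int64)
        self.provenance = list(provenance)
        self._pow4 = 4 ** np.arange(self.n_spins, dtype=np.int64)
        self.codes = self.labels @ self._pow4
        order = np.lexsort(
            tuple(self.labels[:, c] for c in range(self.n_spins - 1, -1, -1))
            + ((self.labels != 0).sum(axis=1),)
        )
        self.labels = self.labels[order]
        self.codes = self.codes[order]
        if len(np.unique(self.codes)) != len(self.codes):
            raise ValueError("duplicate states in basis")
        self._index: dict[int, int] | None = None

    # ------------------------------------------------------------------ #
    @property
    def dimension(self) -> int:
        return self.labels.shape[0]

    @property
    def index(self) -> dict[int, int]:
        """Map from base-4 state code to position."""
        if self._index is None:
            self._index = {int(c): i for i, c in enumerate(self.codes)}
        return self._index

    def state(self, i: int) -> ProductState:
        return ProductState(tuple(int(x) for x in self.labels[i]))

    def correlation_orders(self) -> np.ndarray:
        return (self.labels != 0).sum(axis=1)

    def coherence_orders(self, spins=None) -> np.ndarray:
        sub = self.labels if spins is None else self.labels[:, list(spins)]
        return LABEL_M[sub].sum(axis=1)

    def positions_of_codes(self, codes: np.ndarray) -> np.ndarray:
        """Positions of the given codes, -1 where absent (projection)."""
        srt = np.argsort(self.codes)
        sc = self.codes[srt]
        pos = np.searchsorted(sc, codes)
        pos = np.clip(pos, 0, len(sc) - 1)
        ok = sc[pos] == codes
        out = np.where(ok, srt[pos], -1)
        return out

    def save(self, path) -> None:
        """Dump states and provenance to an ``.npz`` container for reuse."""
        stages, dims = zip(*self.provenance)
        np.savez_compressed(
            path, labels=self.labels,
            stages=np.array(stages, dtype=np.str_),
            dims=np.array(dims, dtype=np.int64),
        )

    @classmethod
    def load(cls, path) -> "ProductBasis":
        with np.load(path) as f:
            labels = f["labels"]
            prov = list(zip((str(s) for s in f["stages"]),
                            (int(d) for d in f["dims"])))
        return cls(labels.shape[1], labels, prov)

    def subset(self, mask: np.ndarray, stage: str) -> "ProductBasis":
        nb = ProductBasis.__new__(ProductBasis)
        nb.n_spins = self.n_spins
        nb.labels = self.labels[mask]
        nb._pow4 = self._pow4
        nb.codes = self.codes[mask]
        nb.provenance = self.provenance + [(stage, int(mask.sum()))]
        nb._index = None
        return nb


@dataclass
class SymmetrizedBasis:
    """Fully symmetric projection of a ProductBasis.

    ``projector`` is the (dimension × n_orbits) sparse matrix B whose
    orthonormal columns are the orbit-averaged symmetric combinations;
    P = B Bᵀ is idempotent.
    """

    basis: ProductBasis
    projector: sp.csr_matrix
    dimension: int
    orbit_of_state: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------- #

def _connected_subsets(adj: list[set[int]], n: int, kmax: int):
    """All connected vertex subsets of size 1..kmax, each exactly once.

    Exclusive-neighborhood extension rooted at the smallest vertex: a
    candidate may only be added together with its neighbors that are new to
    the growing cluster, which makes every subset reachable along a unique
    path."""

    def extend(sub: frozenset, ext: set[int], root: int):
        yield sub
        if len(sub) >= kmax:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            excl = {
                u for u in adj[w]
                if u > root and u not in sub
                and all(u not in adj[s] for s in sub)
            }
            yield from extend(sub | {w}, set(ext) | excl, root)

    for root in range(n):
        yield from extend(frozenset([root]),
                          {u for u in adj[root] if u > root}, root)


def build_basis(system: SpinSystem, max_correlation_order: int,
                connectivity: float | None = None) -> ProductBasis:
    """Build the correlation-order-restricted product basis.

    Parameters
    ----------
    system : SpinSystem
    max_correlation_order : int
        Keep only states with at most this many non-identity labels.
    connectivity : float, optional
        If given, a J-coupling cutoff in Hz: only states whose non-identity
        spins form a connected cluster of the coupling graph (edges where
        \\|J\\| > cutoff) are generated.  This is a documented, togglable
        approximation on top of the correlation-order cap.

    The provenance records the full dimension 4ⁿ and the restricted
    dimension.
    """
    n = system.n_spins
    if max_correlation_order < 1:
        raise ValueError("max_correlation_order must be >= 1")
    kmax = min(max_correlation_order, n)

    if connectivity is None:
        subsets = itertools.chain.from_iterable(
            itertools.combinations(range(n), k) for k in range(1, kmax + 1)
        )
    else:
        g = system.coupling_graph(cutoff_hz=connectivity)
        adj = [set(g.neighbors(v)) for v in range(n)]
        subsets = _connected_subsets(adj, n, kmax)

    rows = [np.zeros((1, n), dtype=np.int64)]  # identity state
    for sub in subsets:
        sub = sorted(sub)
        k = len(sub)
        block = np.zeros((3 ** k, n), dtype=np.int64)
        assignments = np.array(
            list(itertools.product((1, 2, 3), repeat=k)), dtype=np.int64
        )
        block[:, sub] = assignments
        rows.append(block)
    labels = np.concatenate(rows, axis=0)

    stage = f"correlation order <= {kmax}"
    if connectivity is not None:
        stage += f", connected clusters (|J| > {connectivity:g} Hz)"
    prov = [("full Liouville space 4^n", 4 ** n), (stage, labels.shape[0])]
    return ProductBasis(n, labels, prov)


def filter_longitudinal(basis: ProductBasis, spins) -> ProductBasis:
    """Keep states where every listed spin is identity or T₁₀ (longitudinal
    spin-order filter).  Exact only when the listed spins are mutually
    uncoupled or magnetically equivalent; see docs for the exact
    per-isotope coherence filter used by default."""
    spins = _check_spins(basis, spins)
    if not spins:
        return basis.subset(np.ones(basis.dimension, bool),
                            "longitudinal filter (no spins)")
    mask = np.all(np.isin(basis.labels[:, spins], _LONGITUDINAL), axis=1)
    return basis.subset(mask, f"longitudinal filter on spins "
                              f"{tuple(s + 1 for s in spins)}")


def filter_coherence(basis: ProductBasis, total_m: int, spins) -> ProductBasis:
    """Keep states whose summed projection index over the listed spins
    equals ``total_m`` (conservation-law filter; exact at high field)."""
    spins = _check_spins(basis, spins)
    if abs(total_m) > len(spins):
        raise ValueError("|total_m| cannot exceed the number of listed spins")
    mask = basis.coherence_orders(spins) == total_m
    return basis.subset(mask, f"coherence filter m={total_m:+d} on spins "
                              f"{tuple(s + 1 for s in spins)}")


def _check_spins(basis: ProductBasis, spins) -> list[int]:
    spins = sorted(int(s) for s in spins)
    for s in spins:
        if not 0 <= s < basis.n_spins:
            raise IndexError(f"spin index {s} out of range")
    return spins


# ---------------------------------------------------------------------- #

def _group_permutations(n: int, groups: list[SymmetryGroup]):
    """Elements of the direct product of the symmetric groups on each
    equivalent-spin set, as full n-spin image tuples."""
    seen = set()
    for g in groups:
        if seen & set(g.spins):
            raise ValueError("symmetry groups must be disjoint")
        seen |= set(g.spins)
    per_group = [list(itertools.permutations(g.spins)) for g in groups]
    for combo in itertools.product(*per_group):
        p = list(range(n))
        for g, img in zip(groups, combo):
            for src, dst in zip(g.spins, img):
                p[src] = dst
        yield tuple(p)


def symmetrize(basis: ProductBasis,
               groups: list[SymmetryGroup]) -> SymmetrizedBasis:
    """Project the basis onto the fully symmetric irreducible representation
    of the composite equivalent-spin permutation group.

    Each orbit of basis states under the group contributes one symmetric
    combination (1/√\\|orbit\\| on every member), so the projector columns are
    orthonormal and P = B Bᵀ is idempotent.  Raises if the basis is not
    closed under a group permutation (incompatible truncation).
    """
    n = basis.n_spins
    d = basis.dimension
    if not groups:
        b = sp.identity(d, format="csr")
        return SymmetrizedBasis(basis, b, d, np.arange(d),
                                basis.provenance + [("no symmetry", d)])
    canon = basis.codes.copy()
    pow4 = 4 ** np.arange(n, dtype=np.int64)
    n_ops = 0
    for p in _group_permutations(n, groups):
        n_ops += 1
        pinv = np.empty(n, dtype=np.int64)
        pinv[list(p)] = np.arange(n)
        permuted = basis.labels[:, pinv]
        codes = permuted @ pow4
        pos = basis.positions_of_codes(codes)
        if np.any(pos < 0):
            bad = int(np.argmax(pos < 0))
            raise ValueError(
                "basis not closed under group permutation "
                f"{tuple(q + 1 for q in p)}: image of state "
                f"{basis.state(bad)} is missing (incompatible truncation)"
            )
        canon = np.minimum(canon, codes)

    uniq, orbit_of_state, counts = np.unique(
        canon, return_inverse=True, return_counts=True
    )
    m = len(uniq)
    vals = 1.0 / np.sqrt(counts[orbit_of_state])
    b = sp.csr_matrix(
        (vals, (np.arange(d), orbit_of_state)), shape=(d, m)
    )
    prov = basis.provenance + [
        (f"fully symmetric representation ({n_ops} group elements)", m)
    ]
    return SymmetrizedBasis(basis, b, m, orbit_of_state, prov)


def reduction_report(basis: ProductBasis | SymmetrizedBasis):
    """Reduction cascade as a table of stage → dimension (pandas DataFrame;
    ``str()`` of the result is the human-readable form)."""
    import pandas as pd

    prov = basis.provenance
    if not prov:
        raise ValueError("basis has no provenance")
    return pd.DataFrame(prov, columns=["stage", "dimension"])
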