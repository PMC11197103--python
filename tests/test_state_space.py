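"""Product basis construction and the reduction cascade."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmrconf.spin_system import SpinSystem, SymmetryGroup
from nmrconf.state_space import (
    LABEL_M,
    ProductState,
    build_basis,
    filter_coherence,
    filter_longitudinal,
    reduction_report,
    symmetrize,
)
from nmrconf.synthetic import difluoroheptane_system


def uncoupled(n: int) -> SpinSystem:
    return SpinSystem(
        spins=("1H",) * n,
        shifts_ppm=np.linspace(1.0, 2.0, n),
        j_hz=np.zeros((n, n)),
        base_frequency_mhz=500.0,
    )


def chain(n: int, j: float = 7.0) -> SpinSystem:
    mat = np.zeros((n, n))
    for i in range(n - 1):
        mat[i, i + 1] = mat[i + 1, i] = j
    return SpinSystem(
        spins=("1H",) * n,
        shifts_ppm=np.linspace(1.0, 2.0, n),
        j_hz=mat,
        base_frequency_mhz=500.0,
    )


def brute_force_count(n: int, kmax: int) -> int:
    """Independent enumeration oracle: Σ_{k<=kmax} C(n,k)·3^k."""
    from math import comb

    return sum(comb(n, k) * 3 ** k for k in range(kmax + 1))


def test_single_spin_order_one_has_four_states():
    basis = build_basis(uncoupled(1), 1)
    assert basis.dimension == 4
    names = {str(basis.state(i)) for i in range(4)}
    assert names == {"E", "T10", "T1+1", "T1-1"}


@pytest.mark.parametrize("n, kmax", [(2, 2), (3, 2), (3, 3), (5, 3)])
def test_dimension_matches_enumeration_oracle(n, kmax):
    basis = build_basis(uncoupled(n), kmax)
    assert basis.dimension == brute_force_count(n, kmax)


def test_three_spins_order_two_is_37_states():
    assert build_basis(uncoupled(3), 2).dimension == 37


@pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
def test_full_order_basis_has_dimension_4_to_n(n):
    assert build_basis(uncoupled(n), n).dimension == 4 ** n


def test_full_liouville_dimension_reported_for_16_spins():
    system = difluoroheptane_system()
    basis = build_basis(system, 2, connectivity=0.01)
    stage, dim = basis.provenance[0]
    assert dim == 4 ** 16
    assert dim == pytest.approx(4.3e9, rel=0.01)


def test_connectivity_restricts_to_coupled_clusters():
    """In a linear J-chain, non-identity spins must form a contiguous run."""
    basis = build_basis(chain(4), 3, connectivity=0.01)
    for i in range(basis.dimension):
        active = [k for k, l in enumerate(basis.state(i).labels) if l != 0]
        if len(active) > 1:
            assert max(active) - min(active) == len(active) - 1
    # full (no-connectivity) basis keeps non-contiguous clusters too
    assert basis.dimension < build_basis(chain(4), 3).dimension


def test_product_state_metadata_consistency():
    state = ProductState((0, 2, 3, 1))
    assert state.correlation_order == 3
    assert state.coherence_order == 0  # +1 - 1 + 0


def test_longitudinal_filter_single_spin():
    basis = filter_longitudinal(build_basis(uncoupled(1), 1), [0])
    assert {str(basis.state(i)) for i in range(basis.dimension)} == \
        {"E", "T10"}


def test_longitudinal_filter_two_spin_oracle():
    """Enumeration oracle: with spin 2 forced longitudinal, 4 x 2 label
    choices survive out of the full 16."""
    basis = build_basis(uncoupled(2), 2)
    filtered = filter_longitudinal(basis, [1])
    assert filtered.dimension == 8
    expected = {
        (a, b) for a, b in itertools.product(range(4), (0, 1))
    }
    got = {tuple(filtered.labels[i]) for i in range(8)}
    assert got == expected


def test_empty_filter_sets_are_identity():
    basis = build_basis(uncoupled(2), 2)
    assert filter_longitudinal(basis, []).dimension == basis.dimension


def test_coherence_filter_oracle_and_idempotency():
    basis = build_basis(uncoupled(2), 2)
    m1 = filter_coherence(basis, 1, [0, 1])
    expected = {
        lab for lab in itertools.product(range(4), repeat=2)
        if LABEL_M[list(lab)].sum() == 1
    }
    assert {tuple(m1.labels[i]) for i in range(m1.dimension)} == expected
    assert m1.dimension == 4
    again = filter_coherence(m1, 1, [0, 1])
    assert again.dimension == m1.dimension
    assert set(map(tuple, again.labels)) == set(map(tuple, m1.labels))


def test_single_spin_zero_quantum_filter():
    basis = filter_coherence(build_basis(uncoupled(1), 1), 0, [0])
    assert {str(basis.state(i)) for i in range(2)} == {"E", "T10"}


@given(st.integers(0, 2 ** 10 - 1))
def test_filters_commute(bits):
    """Longitudinal-then-coherence equals coherence-then-longitudinal on
    arbitrary sub-bases (set equality)."""
    basis = build_basis(uncoupled(3), 3)
    # drop a pseudo-random subset of states, keeping the identity state
    mask = np.ones(basis.dimension, dtype=bool)
    rng = np.random.default_rng(bits)
    mask[rng.integers(0, basis.dimension, size=16)] = False
    mask[0] = True
    sub = basis.subset(mask, "random subset")
    a = filter_coherence(filter_longitudinal(sub, [2]), 0, [0, 1])
    b = filter_longitudinal(filter_coherence(sub, 0, [0, 1]), [2])
    assert set(map(tuple, a.labels)) == set(map(tuple, b.labels))


def test_filters_produce_subsets_with_monotone_dimensions():
    basis = build_basis(uncoupled(4), 4)
    f1 = filter_coherence(basis, 1, [0, 1])
    f2 = filter_longitudinal(f1, [2, 3])
    dims = [d for _, d in f2.provenance]
    assert dims == sorted(dims, reverse=True)
    codes = set(basis.codes.tolist())
    assert set(f1.codes.tolist()) <= codes
    assert set(f2.codes.tolist()) <= set(f1.codes.tolist())


# ---------------------------------------------------------------------- #
# symmetry adaptation
# ---------------------------------------------------------------------- #

def equivalent_pair() -> SpinSystem:
    j = np.array([[0.0, 5.0], [5.0, 0.0]])
    return SpinSystem(
        spins=("1H", "1H"), shifts_ppm=[1.0, 1.0], j_hz=j,
        base_frequency_mhz=500.0,
        symmetry_groups=[SymmetryGroup((0, 1), "S2")],
    )


def test_trivial_group_leaves_dimension_unchanged():
    basis = build_basis(uncoupled(2), 2)
    sym = symmetrize(basis, [])
    assert sym.dimension == basis.dimension


def test_swap_group_projector_rank_oracle():
    """Dense-projector oracle: rank of (P_id + P_swap)/2 over the 16-state
    basis equals the number of symmetric combinations."""
    system = equivalent_pair()
    basis = build_basis(system, 2)
    sym = symmetrize(basis, system.symmetry_groups)

    # explicit permutation matrix for the swap (a, b) -> (b, a)
    perm_matrix = np.zeros((16, 16))
    for i in range(16):
        a, b = basis.labels[i]
        swapped_code = int(b) + 4 * int(a)
        code = int(a) + 4 * int(b)
        perm_matrix[basis.index[swapped_code], basis.index[code]] = 1.0
    projector = 0.5 * (np.eye(16) + perm_matrix)
    assert sym.dimension == np.linalg.matrix_rank(projector)
    assert sym.dimension == 10


def test_rotor_burnside_count():
    """S3 on a 3-spin rotor: Burnside's lemma gives (4^3 + 3·4^2 + 2·4)/6
    = 20 symmetric combinations of the full 64-state basis."""
    j = np.zeros((3, 3))
    system = SpinSystem(
        spins=("1H",) * 3, shifts_ppm=[1.0] * 3, j_hz=j,
        base_frequency_mhz=500.0,
        symmetry_groups=[SymmetryGroup((0, 1, 2), "S3")],
    )
    basis = build_basis(system, 3)
    sym = symmetrize(basis, system.symmetry_groups)
    assert sym.dimension == (4 ** 3 + 3 * 4 ** 2 + 2 * 4) // 6 == 20


def test_projector_is_idempotent():
    system = equivalent_pair()
    basis = build_basis(system, 2)
    sym = symmetrize(basis, system.symmetry_groups)
    b = sym.projector.toarray()
    p = b @ b.T
    assert np.abs(p @ p - p).max() < 1e-12


def test_symmetrize_rejects_unclosed_basis():
    system = equivalent_pair()
    basis = build_basis(system, 2)
    mask = np.ones(basis.dimension, dtype=bool)
    # remove one state whose swap partner stays: basis no longer closed
    target = basis.index[2]  # T1+1 on spin 0 only
    mask[target] = False
    broken = basis.subset(mask, "broken")
    with pytest.raises(ValueError, match="not closed"):
        symmetrize(broken, system.symmetry_groups)


def test_two_rotor_composite_group_has_36_elements():
    system = difluoroheptane_system()
    basis = build_basis(system, 1)
    sym = symmetrize(basis, system.symmetry_groups)
    stage = sym.provenance[-1][0]
    assert "36 group elements" in stage


# ---------------------------------------------------------------------- #
# reduction report
# ---------------------------------------------------------------------- #

def test_reduction_report_two_spin_pipeline():
    basis = build_basis(uncoupled(2), 2)
    basis = filter_longitudinal(basis, [1])
    basis = filter_coherence(basis, 1, [0])
    table = reduction_report(basis)
    assert list(table["dimension"]) == [16, 16, 8, 2]
    dims = list(table["dimension"])
    assert dims == sorted(dims, reverse=True)


def test_reduction_report_single_stage():
    basis = build_basis(uncoupled(1), 1)
    table = reduction_report(basis)
    assert len(table) == 2  # full dimension + restriction stage
    assert table["dimension"].iloc[0] == 4


def test_basis_container_round_trip(tmp_path):
    basis = filter_coherence(build_basis(uncoupled(3), 3), 1, [0, 1, 2])
    path = tmp_path / "basis.npz"
    basis.save(path)
    from nmrconf.state_space import ProductBasis

    back = ProductBasis.load(path)
    np.testing.assert_array_equal(back.labels, basis.labels)
    assert back.provenance == basis.provenance


def test_heptane_cascade_is_monotone_non_increasing():
    system = difluoroheptane_system()
    basis = build_basis(system, 3, connectivity=0.01)
    basis = filter_coherence(basis, 1, system.isotope_indices("19F"))
    basis = filter_coherence(basis, 0, system.isotope_indices("1H"))
    sym = symmetrize(basis, system.symmetry_groups)
    dims = [d for _, d in sym.provenance]
    assert dims == sorted(dims, reverse=True)
    assert dims[0] == 4 ** 16
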