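"""Liouvillian assembly, Krylov propagation, and spectrum synthesis,
checked against dense Hilbert-space oracles and closed forms."""

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.sparse as sp

from nmrconf.spin_system import AcquisitionParams, SpinSystem, SymmetryGroup
from nmrconf.simulator import (
    _BOPS,
    build_liouvillian,
    correlation_order_trajectory,
    fid_to_spectrum,
    initial_state,
    propagate,
    simulate_spectrum,
    Fid,
    Liouvillian,
)
from nmrconf.state_space import build_basis, filter_coherence


def dense_commutator_superop(system, carriers=None):
    """Independent oracle: the full 4ⁿ×4ⁿ superoperator of [H, ·] built
    from explicit Kronecker-product matrices, in the same basis ordering
    as build_basis(system, n)."""
    from nmrconf.simulator import _dense_hamiltonian, _default_carriers

    carriers = dict(_default_carriers(system), **(carriers or {}))
    h = _dense_hamiltonian(system, carriers)
    n = system.n_spins
    basis = build_basis(system, n)
    ops = []
    for i in range(basis.dimension):
        mat = np.array([[1.0 + 0j]])
        for l in basis.labels[i]:
            mat = np.kron(mat, _BOPS[l])
        ops.append(mat)
    d = basis.dimension
    out = np.zeros((d, d), dtype=complex)
    for q in range(d):
        comm = h @ ops[q] - ops[q] @ h
        for p in range(d):
            v = np.trace(ops[p].conj().T @ comm)
            if abs(v) > 1e-13:
                out[p, q] = v
    return basis, out


def strongly_coupled_3() -> SpinSystem:
    return SpinSystem(
        spins=("1H", "1H", "19F"),
        shifts_ppm=[3.00, 3.02, -180.0],
        j_hz=np.array([
            [0.0, 8.0, 48.0],
            [8.0, 0.0, 12.0],
            [48.0, 12.0, 0.0],
        ]),
        base_frequency_mhz=500.0,
    )


def test_liouvillian_matches_dense_commutator_oracle():
    system = strongly_coupled_3()
    basis, oracle = dense_commutator_superop(system)
    liou = build_liouvillian(system, basis)
    dev = np.abs(liou.matrix.toarray() - oracle).max()
    assert dev < 1e-10 * max(np.abs(oracle).max(), 1.0)


def test_single_spin_zeeman_eigenfrequency():
    """An uncoupled spin at offset ν: the T₁₊₁ state is an eigenvector of L
    with eigenvalue 2πν."""
    nu = 120.0
    system = SpinSystem(
        spins=("1H",), shifts_ppm=[3.0 + nu / 500.0], j_hz=np.zeros((1, 1)),
        base_frequency_mhz=500.0,
    )
    basis = build_basis(system, 1)
    liou = build_liouvillian(system, basis, carriers={"1H": 3.0})
    v = initial_state(system, basis, "1H")
    lv = liou.matrix @ v
    ratio = lv[np.abs(v) > 0][0] / v[np.abs(v) > 0][0]
    assert ratio == pytest.approx(2 * np.pi * nu, rel=1e-12)


def test_initial_state_support_and_norm():
    system = strongly_coupled_3()
    basis = build_basis(system, 3)
    vh = initial_state(system, basis, "1H")
    assert np.linalg.norm(vh) == pytest.approx(np.sqrt(2))
    vf = initial_state(system, basis, "19F")
    assert np.linalg.norm(vf) == pytest.approx(1.0)
    # support only on single-spin states of the detected isotope
    for i in np.nonzero(np.abs(vf) > 0)[0]:
        labels = basis.labels[i]
        assert labels[2] == 2 and labels[0] == 0 and labels[1] == 0
    with pytest.raises(ValueError, match="not present"):
        sys_h = SpinSystem(spins=("1H",), shifts_ppm=[1.0],
                           j_hz=np.zeros((1, 1)), base_frequency_mhz=500.0)
        initial_state(sys_h, build_basis(sys_h, 1), "19F")


def test_zero_liouvillian_gives_constant_fid():
    system = SpinSystem(spins=("1H",), shifts_ppm=[3.0],
                        j_hz=np.zeros((1, 1)), base_frequency_mhz=500.0)
    basis = build_basis(system, 1)
    liou = Liouvillian(sp.csr_matrix((4, 4), dtype=complex), basis)
    v = initial_state(system, basis, "1H")
    fid = propagate(liou, v, 1e-3, 64)
    np.testing.assert_allclose(fid.samples, fid.samples[0])


def test_single_spin_fid_is_analytic_phase_evolution():
    nu = 37.5
    system = SpinSystem(
        spins=("1H",), shifts_ppm=[3.0 + nu / 500.0], j_hz=np.zeros((1, 1)),
        base_frequency_mhz=500.0,
    )
    basis = build_basis(system, 1)
    liou = build_liouvillian(system, basis, carriers={"1H": 3.0})
    v = initial_state(system, basis, "1H")
    dwell = 1e-3
    fid = propagate(liou, v, dwell, 128)
    t = fid.times()
    np.testing.assert_allclose(fid.samples, np.exp(-2j * np.pi * nu * t),
                               atol=1e-9)


def test_propagation_conserves_state_norm():
    system = strongly_coupled_3()
    basis = build_basis(system, 3)
    liou = build_liouvillian(system, basis)
    v = initial_state(system, basis, "1H")
    from nmrconf.simulator import _lanczos_expv

    w = v.copy()
    for _ in range(50):
        w = _lanczos_expv(liou.matrix, w, 2e-3, 16, 1e-10)
    assert np.linalg.norm(w) == pytest.approx(np.linalg.norm(v), abs=1e-9)


def test_four_spin_fid_matches_dense_expm_oracle():
    """Step-by-step scipy expm of the full superoperator vs the Krylov
    propagator."""
    rng = np.random.default_rng(3)
    j = np.zeros((4, 4))
    for a in range(4):
        for b in range(a + 1, 4):
            j[a, b] = j[b, a] = rng.uniform(4, 12)
    system = SpinSystem(
        spins=("1H",) * 4,
        shifts_ppm=3.0 + rng.uniform(0, 0.05, 4),
        j_hz=j, base_frequency_mhz=500.0,
    )
    basis = build_basis(system, 4)
    liou = build_liouvillian(system, basis)
    v = initial_state(system, basis, "1H")
    dwell = 5e-4
    n_steps = 64
    fid = propagate(liou, v, dwell, n_steps)

    u = sla.expm(-1j * dwell * liou.matrix.toarray())
    w = v.copy()
    oracle = []
    for _ in range(n_steps):
        oracle.append(np.vdot(v, w))
        w = u @ w
    assert np.abs(fid.samples - np.array(oracle)).max() < 1e-8


def test_ax_doublets_at_first_order_positions():
    """Weakly coupled AX: four absorption maxima at ±Δ/2 ± J/2."""
    delta_hz, j_hz = 400.0, 10.0
    system = SpinSystem(
        spins=("1H", "1H"),
        shifts_ppm=[3.0 - delta_hz / 1000.0, 3.0 + delta_hz / 1000.0],
        j_hz=np.array([[0.0, j_hz], [j_hz, 0.0]]),
        base_frequency_mhz=500.0,
    )
    acq = AcquisitionParams("1H", 4096, 8192, 2.0, 3.0, 0.3)
    spec = simulate_spectrum(system, acq)
    freqs_hz = (spec.axis_ppm - 3.0) * 500.0
    peaks = freqs_hz[_peak_indices(spec.absorption)]
    expected = sorted([-delta_hz / 2 - 5, -delta_hz / 2 + 5,
                       delta_hz / 2 - 5, delta_hz / 2 + 5])
    assert len(peaks) == 4
    np.testing.assert_allclose(sorted(peaks), expected, atol=0.3)


def _peak_indices(y: np.ndarray, frac: float = 0.05) -> np.ndarray:
    thr = frac * y.max()
    return np.nonzero(
        (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]) & (y[1:-1] > thr)
    )[0] + 1


def test_ab_quartet_closed_form_and_roof_effect():
    """AB pair (δν = 20 Hz, J = 10 Hz): lines at ±(√500 ± 10)/2 about the
    mean shift, with the inner lines taller."""
    system = SpinSystem(
        spins=("1H", "1H"),
        shifts_ppm=[3.0 - 10.0 / 500.0, 3.0 + 10.0 / 500.0],
        j_hz=np.array([[0.0, 10.0], [10.0, 0.0]]),
        base_frequency_mhz=500.0,
    )
    acq = AcquisitionParams("1H", 8192, 16384, 0.4, 3.0, 0.2)
    spec = simulate_spectrum(system, acq)
    freqs_hz = (spec.axis_ppm - 3.0) * 500.0
    idx = _peak_indices(spec.absorption)
    assert len(idx) == 4
    c = np.sqrt(500.0)
    expected = sorted([-(c + 10) / 2, -(c - 10) / 2,
                       (c - 10) / 2, (c + 10) / 2])
    np.testing.assert_allclose(sorted(freqs_hz[idx]), expected, atol=0.05)
    heights = spec.absorption[idx]
    inner = heights[np.argsort(np.abs(freqs_hz[idx]))[:2]]
    outer = heights[np.argsort(np.abs(freqs_hz[idx]))[2:]]
    assert inner.min() > outer.max()


def test_parseval_consistency_without_apodization():
    rng = np.random.default_rng(0)
    samples = rng.normal(size=256) + 1j * rng.normal(size=256)
    fid = Fid(samples, 1e-3, "1H")
    acq = AcquisitionParams("1H", 256, 256, 2.0, 3.0, 0.0)
    spec = fid_to_spectrum(fid, acq, 500.0)
    energy_t = np.sum(np.abs(samples) ** 2)
    energy_f = np.sum(np.abs(spec.intensity) ** 2) / len(spec.intensity)
    assert energy_f == pytest.approx(energy_t, rel=1e-12)


def test_zerofill_shorter_than_fid_rejected():
    fid = Fid(np.zeros(256, dtype=complex), 1e-3, "1H")
    acq = AcquisitionParams("1H", 256, 256, 2.0, 3.0, 0.0)
    object.__setattr__(acq, "zerofill_to", 128)
    with pytest.raises(ValueError):
        fid_to_spectrum(fid, acq, 500.0)


def test_decoupled_hf_pair_collapses_to_singlet(hf_pair):
    acq = AcquisitionParams("1H", 1024, 2048, 0.5, 4.5, 0.5)
    coupled = simulate_spectrum(hf_pair, acq)
    decoupled = simulate_spectrum(hf_pair, acq, decouple="19F")
    assert len(_peak_indices(coupled.absorption)) == 2
    assert len(_peak_indices(decoupled.absorption)) == 1


def test_restricted_simulation_matches_dense_oracle_with_filters():
    system = strongly_coupled_3()
    acq = AcquisitionParams("1H", 512, 1024, 0.6, 3.01, 0.5)
    dense = simulate_spectrum(system, acq, method="hilbert")
    liouv = simulate_spectrum(system, acq, method="liouville")
    scale = np.abs(dense.intensity).max()
    assert np.abs(liouv.intensity - dense.intensity).max() / scale < 1e-9


def test_restricted_spectrum_converges_monotonically_to_dense():
    """Truncation error decreases as the correlation-order cap grows."""
    rng = np.random.default_rng(11)
    n = 6
    j = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            j[a, b] = j[b, a] = rng.uniform(3, 10)
    system = SpinSystem(
        spins=("1H",) * n, shifts_ppm=3.0 + rng.uniform(0, 0.08, n),
        j_hz=j, base_frequency_mhz=500.0,
    )
    acq = AcquisitionParams("1H", 256, 512, 0.6, 3.04, 1.0)
    dense = simulate_spectrum(system, acq, method="hilbert")
    scale = np.linalg.norm(dense.absorption)
    errs = []
    for k in (2, 4, 6):
        sub = simulate_spectrum(system, acq, max_order=k)
        errs.append(np.linalg.norm(sub.absorption - dense.absorption)
                    / scale)
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-6


def test_spectrum_invariant_under_equivalent_spin_relabeling():
    j = np.zeros((4, 4))
    j[[0, 1, 2], 3] = 7.2
    j[3, [0, 1, 2]] = 7.2
    base = dict(shifts_ppm=[1.2, 1.2, 1.2, 3.6], j_hz=j,
                base_frequency_mhz=500.0)
    a = SpinSystem(spins=("1H",) * 4, **base)
    # move the CH proton to position 0
    perm = [3, 0, 1, 2]
    b = SpinSystem(
        spins=("1H",) * 4,
        shifts_ppm=np.array(base["shifts_ppm"])[perm],
        j_hz=j[np.ix_(perm, perm)],
        base_frequency_mhz=500.0,
    )
    acq = AcquisitionParams("1H", 512, 1024, 3.0, 2.4, 0.5)
    sa = simulate_spectrum(a, acq)
    sb = simulate_spectrum(b, acq)
    scale = np.abs(sa.intensity).max()
    assert np.abs(sa.intensity - sb.intensity).max() / scale < 1e-10


def test_symmetry_projection_leaves_spectrum_unchanged(rotor_system):
    acq = AcquisitionParams("1H", 512, 1024, 3.0, 2.4, 0.5)
    with_sym = simulate_spectrum(rotor_system, acq, symmetry=True)
    without = simulate_spectrum(rotor_system, acq, symmetry=False)
    scale = np.abs(without.intensity).max()
    assert np.abs(with_sym.intensity - without.intensity).max() / scale \
        < 1e-10
    assert with_sym.provenance[-1][1] < without.provenance[-1][1]


def test_correlation_trajectory_single_spin_all_order_one():
    system = SpinSystem(spins=("1H",), shifts_ppm=[3.1],
                        j_hz=np.zeros((1, 1)), base_frequency_mhz=500.0)
    acq = AcquisitionParams("1H", 64, 64, 0.5, 3.1, 0.5)
    _, series = correlation_order_trajectory(system, acq)
    assert set(series) == {1}
    np.testing.assert_allclose(series[1], 1.0, atol=1e-9)


def test_correlation_trajectory_ax_pair_norm_conserved():
    system = SpinSystem(
        spins=("1H", "1H"), shifts_ppm=[3.0, 3.05],
        j_hz=np.array([[0.0, 8.0], [8.0, 0.0]]),
        base_frequency_mhz=500.0,
    )
    acq = AcquisitionParams("1H", 128, 128, 0.3, 3.025, 0.5)
    _, series = correlation_order_trajectory(system, acq)
    assert set(series) <= {1, 2}
    total = np.sqrt(sum(series[k] ** 2 for k in series))
    np.testing.assert_allclose(total, total[0], atol=1e-9)


def test_heptane_19f_multiplet_is_mirror_asymmetric():
    """Two fluorines share one shift but couple to different protons, so
    the ¹⁹F multiplet has no mirror symmetry about its centre."""
    from nmrconf.synthetic import difluoroheptane_system

    system = difluoroheptane_system(anti=False)
    acq = AcquisitionParams("19F", 256, 512, 1.0, -181.9, 1.0)
    spec = simulate_spectrum(system, acq, max_order=4, connectivity=0.01)
    a = spec.absorption
    w = np.abs(a)
    cg = np.sum(spec.axis_ppm * w) / np.sum(w)
    i_cg = int(np.argmin(np.abs(spec.axis_ppm - cg)))
    k = min(i_cg, len(a) - 1 - i_cg)
    seg = a[i_cg - k:i_cg + k + 1]
    asym = np.linalg.norm(seg - seg[::-1]) / np.linalg.norm(seg)
    assert asym > 0.01
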