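"""Time-domain NMR simulation in a restricted Liouville space.

The Hamiltonian is the standard high-field liquid-state form

    H = Σᵢ ωᵢ Iz(i) + 2π Σ_{i<j} J_ij (Iᵢ·Iⱼ  or  Iz(i)Iz(j)),

with the full scalar-coupling form between same-isotope spins and the
secular Iz Iz truncation between different isotopes.  The commutation
superoperator L = [H, ·] is assembled directly in the product-operator
basis, term by term, without ever forming 2ⁿ×2ⁿ matrices: each one- or
two-spin term has a small (4×4 or 16×16) superoperator block that is
scattered over the basis by vectorized code arithmetic.  Components that
the basis truncation does not contain are dropped (restricted state-space
approximation).

Propagation is diagonalization-free: L is Hermitian in the orthonormal
tensor basis, so each dwell-time step exp(−iLτ)·v is computed with a
short-recurrence Lanczos (Krylov) approximation with adaptive step
subdivision.  A dense Hilbert-space route (eigendecomposition → transition
table → FID) serves as the independent oracle for small systems and as the
fast forward model during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .spin_system import (
    ISOTOPES,
    AcquisitionParams,
    SpinSystem,
)
from .state_space import (
    ProductBasis,
    SymmetrizedBasis,
    build_basis,
    filter_coherence,
    filter_longitudinal,
    symmetrize,
)

__all__ = [
    "Liouvillian",
    "Fid",
    "Spectrum",
    "build_liouvillian",
    "initial_state",
    "propagate",
    "fid_to_spectrum",
    "simulate_spectrum",
    "simulate_fid",
    "correlation_order_trajectory",
    "dense_transition_table",
    "DENSE_SPIN_CAP",
]

#: refuse dense Hilbert-space simulation above this many spins
DENSE_SPIN_CAP = 12

# single-spin 2×2 operators
_E2 = np.eye(2, dtype=complex)
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_IP = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)
_IM = _IP.T.conj()
_IX = 0.5 * (_IP + _IM)
_IY = -0.5j * (_IP - _IM)

#: unit-Frobenius-norm single-spin basis, indexed by state_space label codes
_BOPS = (
    _E2 / np.sqrt(2.0),   # E
    np.sqrt(2.0) * _IZ,   # T10
    -_IP,                 # T1+1
    _IM,                  # T1-1
)


class KrylovError(RuntimeError):
    """Krylov propagation failed to reach the requested tolerance."""


@dataclass
class Liouvillian:
    """Sparse commutation superoperator: the matrix of [H, ·] in rad/s over
    a ProductBasis or SymmetrizedBasis (the propagator is exp(−iLt))."""

    matrix: sp.csr_matrix
    basis: ProductBasis | SymmetrizedBasis

    @property
    def dimension(self) -> int:
        return self.matrix.shape[0]

    @property
    def nnz(self) -> int:
        return self.matrix.nnz


@dataclass
class Fid:
    """Complex free-induction decay."""

    samples: np.ndarray
    dwell: float
    detect_isotope: str

    def times(self) -> np.ndarray:
        return self.dwell * np.arange(len(self.samples))


@dataclass
class Spectrum:
    """Frequency-domain spectrum with its acquisition metadata."""

    axis_ppm: np.ndarray
    intensity: np.ndarray          # complex
    params: AcquisitionParams
    base_frequency_mhz: float
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def absorption(self) -> np.ndarray:
        """Real (absorption-mode) intensity."""
        return self.intensity.real

    def __post_init__(self) -> None:
        d = np.diff(self.axis_ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("spectrum axis must be strictly monotone")


# ---------------------------------------------------------------------- #
# Hamiltonian terms and superoperator assembly
# ---------------------------------------------------------------------- #

def _default_carriers(system: SpinSystem) -> dict[str, float]:
    """Mean shift per isotope; the undetected-isotope carrier has no effect
    on the detected signal (total Sz of that isotope commutes with H)."""
    out = {}
    for sym in system.isotopes_present():
        idx = system.isotope_indices(sym)
        out[sym] = float(np.mean(system.shifts_ppm[idx]))
    return out


def _hamiltonian_terms(system: SpinSystem, carriers: dict[str, float]):
    """Yield ('1', i, h2x2) and ('2', i, j, h4x4) terms in rad/s."""
    n = system.n_spins
    for i in range(n):
        iso = system.spins[i]
        nu = (system.shifts_ppm[i] - carriers[iso.symbol]) \
            * system.base_frequency_mhz * iso.gamma_ratio
        if nu != 0.0:
            yield ("1", i, 2.0 * np.pi * nu * _IZ)
    for i in range(n):
        for j in range(i + 1, n):
            jij = system.j_hz[i, j]
            if jij == 0.0:
                continue
            if system.spins[i].symbol == system.spins[j].symbol:
                h = (np.kron(_IX, _IX) + np.kron(_IY, _IY)
                     + np.kron(_IZ, _IZ))
            else:
                h = np.kron(_IZ, _IZ)
            yield ("2", i, j, 2.0 * np.pi * jij * h)


def _superop_block(h: np.ndarray, nspins: int) -> np.ndarray:
    """Commutation superoperator of a 1- or 2-spin Hamiltonian block in the
    normalized tensor basis: S[q, p] = ⟨B_q, [h, B_p]⟩."""
    if nspins == 1:
        bops = _BOPS
    else:
        bops = [np.kron(a, b) for a in _BOPS for b in _BOPS]
    dim = len(bops)
    s = np.zeros((dim, dim), dtype=complex)
    for p, bp in enumerate(bops):
        c = h @ bp - bp @ h
        for q, bq in enumerate(bops):
            v = np.trace(bq.conj().T @ c)
            if abs(v) > 1e-14:
                s[q, p] = v
    return s


def build_liouvillian(system: SpinSystem,
                      basis: ProductBasis | SymmetrizedBasis,
                      carriers: dict[str, float] | None = None) -> Liouvillian:
    """Assemble L = [H, ·] (rad/s) over the given basis.

    ``carriers`` maps isotope symbol to the rotating-frame carrier position
    in ppm (defaults to the mean shift of each isotope).  For a
    SymmetrizedBasis the product-space matrix is congruence-projected with
    the symmetric projector.
    """
    pbasis = basis.basis if isinstance(basis, SymmetrizedBasis) else basis
    if pbasis.n_spins != system.n_spins:
        raise ValueError("basis/system mismatch: different spin counts")
    carriers = dict(_default_carriers(system), **(carriers or {}))

    d = pbasis.dimension
    codes = pbasis.codes
    labels = pbasis.labels
    pos_cache = np.argsort(codes)
    sorted_codes = codes[pos_cache]

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def scatter(src_idx: np.ndarray, tgt_codes: np.ndarray,
                coeff: complex) -> None:
        pos = np.searchsorted(sorted_codes, tgt_codes)
        pos = np.clip(pos, 0, d - 1)
        ok = sorted_codes[pos] == tgt_codes
        if not np.any(ok):
            return
        rows.append(pos_cache[pos[ok]])
        cols.append(src_idx[ok])
        vals.append(np.full(int(ok.sum()), coeff, dtype=complex))

    for term in _hamiltonian_terms(system, carriers):
        if term[0] == "1":
            _, i, h = term
            s = _superop_block(h, 1)
            li = labels[:, i]
            w = 4 ** np.int64(i)
            for p in range(4):
                idx = np.nonzero(li == p)[0]
                if idx.size == 0:
                    continue
                base_codes = codes[idx]
                for q in range(4):
                    if s[q, p] == 0:
                        continue
                    scatter(idx, base_codes + (q - p) * w, s[q, p])
        else:
            _, i, j, h = term
            s = _superop_block(h, 2)
            wi = 4 ** np.int64(i)
            wj = 4 ** np.int64(j)
            pair = labels[:, i] * 4 + labels[:, j]
            for p in range(16):
                idx = np.nonzero(pair == p)[0]
                if idx.size == 0:
                    continue
                base_codes = codes[idx]
                pi, pj = divmod(p, 4)
                for q in range(16):
                    if s[q, p] == 0:
                        continue
                    qi, qj = divmod(q, 4)
                    scatter(idx,
                            base_codes + (qi - pi) * wi + (qj - pj) * wj,
                            s[q, p])

    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(d, d),
        ).tocsr()
    else:
        mat = sp.csr_matrix((d, d), dtype=complex)

    if isinstance(basis, SymmetrizedBasis):
        b = basis.projector
        mat = (b.T.conjugate() @ mat @ b).tocsr()
    return Liouvillian(mat, basis)


def initial_state(system: SpinSystem,
                  basis: ProductBasis | SymmetrizedBasis,
                  isotope: str) -> np.ndarray:
    """State vector after an ideal 90° pulse on ``isotope``: unit coefficient
    on each single-spin T₁₊₁ state of that isotope (norm √n_detected)."""
    idx = system.isotope_indices(isotope)
    if not idx:
        raise ValueError(f"isotope {isotope!r} not present in system")
    pbasis = basis.basis if isinstance(basis, SymmetrizedBasis) else basis
    v = np.zeros(pbasis.dimension, dtype=complex)
    codes = np.array([2 * 4 ** np.int64(i) for i in idx])
    pos = pbasis.positions_of_codes(codes)
    if np.any(pos < 0):
        raise ValueError(
            "basis does not contain the single-spin transverse states of "
            f"{isotope}; build it with max_correlation_order >= 1 and "
            "compatible filters"
        )
    v[pos] = 1.0
    if isinstance(basis, SymmetrizedBasis):
        v = basis.projector.T.conjugate() @ v
    return v


# ---------------------------------------------------------------------- #
# Krylov propagation
# ---------------------------------------------------------------------- #

def _lanczos_expv(mat: sp.csr_matrix, v: np.ndarray, t: float,
                  m: int, tol: float, depth: int = 0) -> np.ndarray:
    """exp(−i·t·mat)·v for Hermitian ``mat`` via the Lanczos process with
    a posteriori error estimate and recursive step halving."""
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return v.copy()
    if depth > 30:
        raise KrylovError(
            "Krylov propagation did not converge at the requested "
            "tolerance; the step is too large for the operator norm"
        )
    dim = len(v)
    m_eff = min(m, dim)
    vecs = np.empty((m_eff + 1, dim), dtype=complex)
    alpha = np.zeros(m_eff)
    beta = np.zeros(m_eff)
    vecs[0] = v / nv
    k = m_eff
    breakdown = False
    for j in range(m_eff):
        w = mat @ vecs[j]
        a = float(np.real(np.vdot(vecs[j], w)))
        alpha[j] = a
        w = w - a * vecs[j]
        if j > 0:
            w = w - beta[j - 1] * vecs[j - 1]
        # full reorthogonalization (m is small; keeps T faithful)
        w = w - vecs[: j + 1].T @ (vecs[: j + 1].conj() @ w)
        b = np.linalg.norm(w)
        beta[j] = b
        if b < 1e-14 * nv:
            k = j + 1
            breakdown = True
            break
        vecs[j + 1] = w / b

    evals, evecs = sla.eigh_tridiagonal(alpha[:k], beta[: k - 1])
    small = evecs @ (np.exp(-1j * t * evals) * evecs[0].conj())
    if not breakdown:
        err = abs(beta[k - 1] * small[k - 1])
        if err > tol:
            half = _lanczos_expv(mat, v, t / 2.0, m, tol / 2.0, depth + 1)
            return _lanczos_expv(mat, half, t / 2.0, m, tol / 2.0, depth + 1)
    return nv * (vecs[:k].T @ small)


def propagate(liouvillian: Liouvillian, state: np.ndarray, dwell: float,
              n_steps: int, coil: np.ndarray | None = None,
              detect_isotope: str = "1H", krylov_dim: int = 16,
              tol: float = 1e-10) -> Fid:
    """Pulse-acquire detection: samples[k] = ⟨coil| exp(−iLk·dwell) |state⟩.

    Each dwell step is one Krylov exponential action; no dense factorization
    of L is performed.  ``coil`` defaults to the initial state (quadrature
    detection of the same transverse magnetization).
    """
    if dwell <= 0:
        raise ValueError("dwell must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    coil = state if coil is None else coil
    v = state.astype(complex)
    samples = np.empty(n_steps, dtype=complex)
    for k in range(n_steps):
        samples[k] = np.vdot(coil, v)
        if k < n_steps - 1:
            v = _lanczos_expv(liouvillian.matrix, v, dwell, krylov_dim, tol)
    return Fid(samples, dwell, detect_isotope)


# ---------------------------------------------------------------------- #
# spectrum synthesis
# ---------------------------------------------------------------------- #

def fid_to_spectrum(fid: Fid, params: AcquisitionParams,
                    base_frequency_mhz: float,
                    provenance: list | None = None) -> Spectrum:
    """Exponential apodization, zero-filling, and discrete Fourier transform.

    The apodization rate is chosen so an undamped resonance acquires a
    Lorentzian full width at half height of ``line_broadening_hz``.  The
    axis is in ppm of the detected isotope, centred at ``center_ppm``.
    """
    if params.zerofill_to < len(fid.samples):
        raise ValueError("zerofill_to must be >= number of FID points")
    if len(fid.samples) != params.n_points:
        raise ValueError("FID length does not match acquisition n_points")
    t = fid.times()
    x = fid.samples * np.exp(-np.pi * params.line_broadening_hz * t)
    nfft = params.zerofill_to
    # the +1 coherence evolves as exp(-i omega t); conjugation maps it to the
    # detected m = -1 quadrature so resonances land at +offset on the axis
    spec = np.fft.fftshift(np.fft.fft(np.conj(x), n=nfft))
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=fid.dwell))
    gamma = ISOTOPES[params.detect_isotope].gamma_ratio
    axis = params.center_ppm + freqs / (base_frequency_mhz * gamma)
    return Spectrum(axis, spec, params, base_frequency_mhz,
                    provenance or [])


# ---------------------------------------------------------------------- #
# dense Hilbert-space oracle
# ---------------------------------------------------------------------- #

def _kron_chain(ops: dict[int, np.ndarray], n: int) -> np.ndarray:
    out = np.array([[1.0 + 0.0j]])
    for i in range(n):
        out = np.kron(out, ops.get(i, _E2))
    return out


def _dense_hamiltonian(system: SpinSystem,
                       carriers: dict[str, float]) -> np.ndarray:
    """H over the 2ⁿ computational basis, assembled with bit arithmetic.

    Spin i maps to bit (n−1−i) so the matrix coincides with the Kronecker
    ordering used for the detection operators (spin 0 = leftmost factor);
    bit value 1 is the m = +1/2 state.
    """
    n = system.n_spins
    if n > DENSE_SPIN_CAP:
        raise ValueError(
            f"dense Hilbert-space simulation refused above {DENSE_SPIN_CAP} "
            f"spins (requested {n}); use the restricted Liouville route"
        )
    dim = 2 ** n
    states = np.arange(dim)
    # m[s, i] = ±1/2 of spin i in computational state s; Iz = diag(+½, −½),
    # so the 0 bit (first basis vector of each factor) is m = +1/2
    m = (0.5
         - ((states[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1))
    h = np.zeros((dim, dim), dtype=complex)
    diag = np.zeros(dim)
    for i in range(n):
        iso = system.spins[i]
        nu = (system.shifts_ppm[i] - carriers[iso.symbol]) \
            * system.base_frequency_mhz * iso.gamma_ratio
        diag += 2.0 * np.pi * nu * m[:, i]
    for i in range(n):
        for j in range(i + 1, n):
            jij = system.j_hz[i, j]
            if jij == 0.0:
                continue
            diag += 2.0 * np.pi * jij * m[:, i] * m[:, j]
            if system.spins[i].symbol == system.spins[j].symbol:
                # flip-flop (I+I- + I-I+)/2 between antiparallel pairs
                sel = states[m[:, i] != m[:, j]]
                flip = sel ^ ((1 << (n - 1 - i)) | (1 << (n - 1 - j)))
                h[flip, sel] += np.pi * jij
    h[states, states] += diag
    return h


#: relative amplitude below which transitions are dropped from the dense
#: transition table (identical in generation and fitting, so synthetic
#: round trips are bit-exact)
DEFAULT_AMP_CUTOFF = 1e-9


def dense_transition_table(system: SpinSystem, detect_isotope: str,
                           carriers: dict[str, float] | None = None,
                           amp_cutoff: float = DEFAULT_AMP_CUTOFF):
    """Eigendecompose H in Hilbert space and return (frequencies rad/s,
    complex amplitudes) of all transitions contributing to the detected
    signal, in the same normalization as the Liouville route (unit
    coefficient per single-spin T₁₊₁ state)."""
    carriers = dict(_default_carriers(system), **(carriers or {}))
    n = system.n_spins
    h = _dense_hamiltonian(system, carriers)
    w, vec = np.linalg.eigh(h)
    idx = system.isotope_indices(detect_isotope)
    if not idx:
        raise ValueError(f"isotope {detect_isotope!r} not present")
    # -I+(i) on the full Hilbert space equals √2^(n-1) times the normalized
    # product state T1+1(i); the final scale^2 division converts the trace
    # to the unit-coefficient Liouville convention
    scale = np.sqrt(2.0) ** (n - 1)
    rho0 = sum(_kron_chain({i: -_IP}, n) for i in idx)
    coil = rho0
    r = vec.conj().T @ rho0 @ vec
    c = vec.conj().T @ coil @ vec
    amps = (np.conj(c) * r).ravel()
    freqs = (w[:, None] - w[None, :]).ravel()
    keep = np.abs(amps) > amp_cutoff * max(np.abs(amps).max(), 1e-300)
    # divide by scale^2 so amplitudes match the unit-coefficient Liouville
    # convention (rho0 and coil were each multiplied by scale above)
    return freqs[keep], amps[keep] / scale ** 2


def _dense_fid(system: SpinSystem, acq: AcquisitionParams,
               carriers: dict[str, float] | None = None,
               amp_cutoff: float = DEFAULT_AMP_CUTOFF) -> Fid:
    """FID from the dense transition table.

    samples[n] = Σ_k A_k z_kⁿ with z_k = exp(−iω_k·dwell); the power matrix
    is built by index doubling (each half-block is the first half times a
    scalar power), so the synthesis is a single BLAS product.
    """
    freqs, amps = dense_transition_table(system, acq.detect_isotope,
                                         carriers, amp_cutoff)
    dwell = acq.dwell_s(system.base_frequency_mhz)
    npts = acq.n_points
    z = np.exp(-1j * freqs * dwell)
    powers = np.empty((len(z), npts), dtype=complex)
    powers[:, 0] = 1.0
    filled = 1
    zp = z.copy()
    while filled < npts:
        step = min(filled, npts - filled)
        powers[:, filled:filled + step] = powers[:, :step] * zp[:, None]
        filled += step
        zp = zp * zp  # zp tracks z**filled while doubling
    samples = amps @ powers
    return Fid(samples, dwell, acq.detect_isotope)


# ---------------------------------------------------------------------- #
# end-to-end composition
# ---------------------------------------------------------------------- #

def simulate_fid(system: SpinSystem, acq: AcquisitionParams,
                 max_order: int | None = None,
                 connectivity: float | None = None,
                 filters: bool = True,
                 filter_mode: str = "coherence",
                 symmetry: bool = True,
                 krylov_dim: int = 16,
                 krylov_tol: float = 1e-10) -> tuple[Fid, list]:
    """Restricted Liouville-space pulse-acquire FID; returns the FID and the
    reduction-cascade provenance.

    ``filter_mode="coherence"`` applies the exact conservation-law filters
    (total m = +1 on the detected isotope, total m = 0 on every other
    isotope).  ``"longitudinal"`` applies the stricter longitudinal filter
    on undetected isotopes instead — exact only when those spins are
    mutually uncoupled or magnetically equivalent.
    """
    n = system.n_spins
    det = system.isotope_indices(acq.detect_isotope)
    if not det:
        raise ValueError(f"isotope {acq.detect_isotope!r} not in system")
    basis = build_basis(system, max_order or n, connectivity)
    if filters:
        basis = filter_coherence(basis, +1, det)
        for sym in system.isotopes_present():
            if sym == acq.detect_isotope:
                continue
            other = system.isotope_indices(sym)
            if filter_mode == "longitudinal":
                basis = filter_longitudinal(basis, other)
            elif filter_mode == "coherence":
                basis = filter_coherence(basis, 0, other)
            else:
                raise ValueError(f"unknown filter_mode {filter_mode!r}")
    work: ProductBasis | SymmetrizedBasis = basis
    if symmetry and system.symmetry_groups:
        work = symmetrize(basis, system.symmetry_groups)
    carriers = {acq.detect_isotope: acq.center_ppm}
    liou = build_liouvillian(system, work, carriers)
    v0 = initial_state(system, work, acq.detect_isotope)
    fid = propagate(liou, v0, acq.dwell_s(system.base_frequency_mhz),
                    acq.n_points, detect_isotope=acq.detect_isotope,
                    krylov_dim=krylov_dim, tol=krylov_tol)
    prov = work.provenance if isinstance(work, SymmetrizedBasis) \
        else basis.provenance
    return fid, prov


def simulate_spectrum(system: SpinSystem, acq: AcquisitionParams,
                      max_order: int | None = None,
                      connectivity: float | None = None,
                      filters: bool = True,
                      filter_mode: str = "coherence",
                      symmetry: bool = True,
                      decouple: str | None = None,
                      method: str = "liouville",
                      krylov_dim: int = 16,
                      krylov_tol: float = 1e-10) -> Spectrum:
    """End-to-end simulation: basis build → Liouvillian → Krylov propagation
    → apodization/FFT.

    ``decouple`` zeroes all couplings between the named isotope and every
    other isotope before simulating (ideal broadband decoupling, the
    validation mode used for partially decoupled spectra).  ``method``
    selects the restricted-Liouville route (default) or the dense
    Hilbert-space oracle (``"hilbert"``, small systems only); both feed the
    same spectrum synthesis, so they are directly comparable.
    """
    if decouple is not None:
        system = system.decoupled(decouple)
    if method == "hilbert":
        carriers = {acq.detect_isotope: acq.center_ppm}
        fid = _dense_fid(system, acq, carriers)
        prov = [("dense Hilbert space 2^n", 2 ** system.n_spins)]
    elif method == "liouville":
        fid, prov = simulate_fid(
            system, acq, max_order=max_order, connectivity=connectivity,
            filters=filters, filter_mode=filter_mode, symmetry=symmetry,
            krylov_dim=krylov_dim, krylov_tol=krylov_tol,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return fid_to_spectrum(fid, acq, system.base_frequency_mhz, prov)


def correlation_order_trajectory(system: SpinSystem, acq: AcquisitionParams,
                                 max_tracked_order: int | None = None,
                                 filters: bool = True,
                                 krylov_dim: int = 16,
                                 krylov_tol: float = 1e-10):
    """Per-order amplitude time series during pulse-acquire evolution.

    Returns ``(times, {order: norms})`` where ``norms[k]`` is the Euclidean
    norm of the state projected onto the subspace of that spin-correlation
    order at time step k.
    """
    n = system.n_spins
    kmax = max_tracked_order or n
    det = system.isotope_indices(acq.detect_isotope)
    basis = build_basis(system, kmax)
    if filters:
        basis = filter_coherence(basis, +1, det)
        for sym in system.isotopes_present():
            if sym != acq.detect_isotope:
                basis = filter_coherence(basis, 0,
                                         system.isotope_indices(sym))
    orders = basis.correlation_orders()
    masks = {k: orders == k for k in range(1, kmax + 1)
             if np.any(orders == k)}
    carriers = {acq.detect_isotope: acq.center_ppm}
    liou = build_liouvillian(system, basis, carriers)
    v = initial_state(system, basis, acq.detect_isotope)
    dwell = acq.dwell_s(system.base_frequency_mhz)
    series = {k: np.empty(acq.n_points) for k in masks}
    for step in range(acq.n_points):
        for k, m in masks.items():
            series[k][step] = np.linalg.norm(v[m])
        if step < acq.n_points - 1:
            v = _lanczos_expv(liou.matrix, v, dwell, krylov_dim, krylov_tol)
    times = dwell * np.arange(acq.n_points)
    return times, series
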