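"""Exact diagonalization of small coupled-QDO systems in a truncated Fock basis.

This module is the independent ground truth for the Gaussian-state
machinery: it represents the coupled Hamiltonian directly through ladder
matrix elements of q = sqrt(hbar/2w)(a + a^dag) and p = i sqrt(hbar w/2)
(a^dag - a) in the product basis of uncoupled QDO number states, finds the
lowest eigenpair(s) by sparse iteration, and evaluates observables by
explicit contraction with the eigenvectors (reduced density matrices by
explicit partial trace).  Truncation at per-mode occupation nmax is
variational for the ground-state energy and converges rapidly in the
perturbative coupling regime.

Practical only for N <= 3 atoms; the default dimension cap is 3e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hamiltonian import DampingParams, MBDPotential, assemble_potential
from .parameters import QDOParams
from .structures import AtomicSystem
from .units import HBAR

__all__ = [
    "FockBasis",
    "FockGroundState",
    "fock_ground_state",
    "fock_expectation",
    "fock_transition_dipoles",
    "converged_nmax",
]

DIMENSION_CAP = 3_000_000


@dataclass(frozen=True)
class FockBasis:
    """Truncated product basis of 3N oscillator modes, cap nmax per mode."""

    nmax: int
    n_modes: int

    def __post_init__(self) -> None:
        if self.dimension > DIMENSION_CAP:
            raise ValueError(
                f"basis dimension {self.dimension} exceeds cap {DIMENSION_CAP}"
            )

    @property
    def dim_per_mode(self) -> int:
        return self.nmax + 1

    @property
    def dimension(self) -> int:
        return self.dim_per_mode**self.n_modes

    def occupations(self) -> np.ndarray:
        """(dimension, n_modes) occupation numbers; mode 0 varies slowest."""
        d = self.dim_per_mode
        idx = np.arange(self.dimension)
        out = np.empty((self.dimension, self.n_modes), dtype=np.int16)
        for m in range(self.n_modes - 1, -1, -1):
            out[:, m] = idx % d
            idx //= d
        return out

    def index_of(self, occ: tuple[int, ...]) -> int:
        pos = 0
        for n in occ:
            pos = pos * self.dim_per_mode + n
        return pos


def _single_mode_ops(nmax: int) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Annihilation a and identity for one truncated oscillator mode."""
    n = np.arange(1, nmax + 1)
    a = sp.diags(np.sqrt(n), offsets=1, format="csr")
    return a, sp.identity(nmax + 1, format="csr")


def _embed(ops: dict[int, sp.spmatrix], basis: FockBasis) -> sp.csr_matrix:
    """Kronecker-embed single-mode operators at given mode positions."""
    out = None
    eye = sp.identity(basis.dim_per_mode, format="csr")
    for m in range(basis.n_modes):
        factor = ops.get(m, eye)
        out = factor if out is None else sp.kron(out, factor, format="csr")
    return out


@dataclass(frozen=True)
class FockGroundState:
    """Ground eigenpair plus the operator cache needed for expectations."""

    basis: FockBasis
    energy: float
    vector: np.ndarray
    potential: MBDPotential
    omega_composite: np.ndarray
    q_ops: tuple[sp.csr_matrix, ...]
    pm_ops: tuple[sp.csr_matrix, ...]   # real part of p: p = i * pm
    hamiltonian: sp.csr_matrix


def _build_hamiltonian(
    potential: MBDPotential, basis: FockBasis
) -> tuple[sp.csr_matrix, list[sp.csr_matrix], list[sp.csr_matrix], np.ndarray]:
    omega = np.repeat(potential.omega, 3)
    a1, _ = _single_mode_ops(basis.nmax)
    q_ops, pm_ops = [], []
    v = potential.matrix
    h = sp.csr_matrix((basis.dimension, basis.dimension))
    # exact single-mode matrix elements of (a + a^dag)^2 in the truncated
    # basis (diag 2n+1, band +/-2), so the truncation is a true projection
    # P H P and the ground energy is variational in nmax
    nvec = np.arange(basis.nmax + 1)
    band2 = np.sqrt((nvec[:-2] + 1) * (nvec[:-2] + 2))
    sum_sq = sp.diags(
        [band2, 2.0 * nvec + 1.0, band2], offsets=[2, 0, -2], format="csr"
    )  # (a + a^dag)^2 restricted
    dif_sq = sp.diags(
        [band2, -(2.0 * nvec + 1.0), band2], offsets=[2, 0, -2], format="csr"
    )  # (a^dag - a)^2 restricted
    for mu in range(basis.n_modes):
        w = omega[mu]
        q1 = np.sqrt(HBAR / (2.0 * w)) * (a1 + a1.T)
        pm1 = np.sqrt(HBAR * w / 2.0) * (a1.T - a1)   # p = i * pm
        q_ops.append(_embed({mu: q1}, basis))
        pm_ops.append(_embed({mu: pm1}, basis))
        # single-mode part: p^2/2 + (1/2) V_mumu q^2
        p2 = -(HBAR * w / 2.0) * dif_sq
        q2 = (HBAR / (2.0 * w)) * sum_sq
        single = 0.5 * p2 + 0.5 * v[mu, mu] * q2
        h = h + _embed({mu: single}, basis)
    for mu in range(basis.n_modes):
        w_mu = omega[mu]
        q_mu = np.sqrt(HBAR / (2.0 * w_mu)) * (a1 + a1.T)
        for nu in range(mu + 1, basis.n_modes):
            if v[mu, nu] == 0.0:
                continue
            w_nu = omega[nu]
            q_nu = np.sqrt(HBAR / (2.0 * w_nu)) * (a1 + a1.T)
            h = h + v[mu, nu] * _embed({mu: q_mu, nu: q_nu}, basis)
    return h.tocsr(), q_ops, pm_ops, omega


def fock_ground_state(
    system: AtomicSystem,
    params: QDOParams,
    damping: DampingParams | None = None,
    nmax: int = 8,
    range_part: str = "long_range",
    r_vdw_damping: np.ndarray | None = None,
    potential: MBDPotential | None = None,
) -> FockGroundState:
    """Lowest eigenpair of the coupled Hamiltonian in the truncated basis.

    ``potential`` may be supplied directly (e.g. a hand-assembled matrix);
    otherwise it is assembled from (system, params, damping, range_part).
    """
    if potential is None:
        potential = assemble_potential(
            system, params, damping, range_part, r_vdw_damping=r_vdw_damping
        )
    basis = FockBasis(nmax, 3 * system.n_atoms)
    h, q_ops, pm_ops, omega = _build_hamiltonian(potential, basis)
    if basis.dimension <= 256:
        evals, evecs = np.linalg.eigh(h.toarray())
        e0, v0 = evals[0], evecs[:, 0]
    else:
        evals, evecs = spla.eigsh(h, k=1, which="SA")
        e0, v0 = evals[0], evecs[:, 0]
    v0 = v0 / np.linalg.norm(v0)
    if v0[np.argmax(np.abs(v0))] < 0:
        v0 = -v0
    return FockGroundState(
        basis, float(e0), v0, potential, omega, tuple(q_ops), tuple(pm_ops), h
    )


def _rdm(state: FockGroundState, keep: np.ndarray) -> np.ndarray:
    """Reduced density matrix over the kept composite modes (explicit trace)."""
    basis = state.basis
    keep = np.asarray(sorted(keep), dtype=int)
    rest = np.array([m for m in range(basis.n_modes) if m not in set(keep.tolist())])
    shape = (basis.dim_per_mode,) * basis.n_modes
    psi = state.vector.reshape(shape)
    psi = np.transpose(psi, axes=list(keep) + list(rest))
    dk = basis.dim_per_mode ** keep.size
    psi = psi.reshape(dk, -1)
    return psi @ psi.T


def fock_expectation(state: FockGroundState, observable, *args):
    """Exact expectation values in the truncated ground state.

    Observables: ``'energy'``, ``'number'`` (per-composite vector),
    ``'number_cov'`` (3N x 3N), ``'qq'``, ``'pp'`` (second-moment
    matrices), ``'rdm'`` and ``'entropy'`` (args: composite index list).
    """
    psi = state.vector
    if observable == "energy":
        return float(psi @ (state.hamiltonian @ psi))
    if observable == "number":
        occ = state.basis.occupations().astype(float)
        return occ.T @ psi**2
    if observable == "number_cov":
        occ = state.basis.occupations().astype(float)
        w = psi**2
        second = (occ.T * w) @ occ
        mean = occ.T @ w
        return second - np.outer(mean, mean)
    if observable == "qq":
        vecs = np.stack([op @ psi for op in state.q_ops])
        return vecs @ vecs.T
    if observable == "pp":
        vecs = np.stack([op @ psi for op in state.pm_ops])
        return vecs @ vecs.T  # p = i*pm, pm antisymmetric: <p p> = (pm psi).(pm psi)
    if observable == "rdm":
        return _rdm(state, np.asarray(args[0], dtype=int))
    if observable == "entropy":
        # Schmidt spectrum of the pure ground state: the Gram matrix on the
        # smaller side of the bipartition has the same nonzero eigenvalues
        # as the reduced density matrix
        basis = state.basis
        keep = sorted(int(k) for k in args[0])
        rest = [m for m in range(basis.n_modes) if m not in set(keep)]
        shape = (basis.dim_per_mode,) * basis.n_modes
        a = np.transpose(psi.reshape(shape), axes=keep + rest).reshape(
            basis.dim_per_mode ** len(keep), -1
        )
        gram = a @ a.T if a.shape[0] <= a.shape[1] else a.T @ a
        lam = np.linalg.eigvalsh(gram)
        lam = lam[lam > 1e-14]
        return float(-(lam * np.log(lam)).sum())
    raise ValueError(f"unknown observable {observable!r}")


def fock_transition_dipoles(
    state: FockGroundState,
    coupling: np.ndarray,
    n_excited: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Transition energies and isotropic square dipole moduli from the oracle.

    ``coupling`` is the per-atom omega_A sqrt(alpha_A) factor.  Computes
    the lowest ``n_excited`` excited eigenstates (default: all 3N singly
    excited levels) and the matrix elements of the total dipole operator
    mu_i = sum_A coupling_A q_{A,i}.  Returns (delta_e, iso_sq) sorted by
    excitation energy.
    """
    basis = state.basis
    if n_excited is None:
        n_excited = basis.n_modes
    k = n_excited + 1
    evals, evecs = spla.eigsh(state.hamiltonian, k=k, which="SA")
    order = np.argsort(evals)
    evals, evecs = evals[order], evecs[:, order]
    psi0 = evecs[:, 0]
    coup = np.repeat(np.asarray(coupling, dtype=float), 3)
    dip_ops = []
    for i in range(3):
        op = None
        for a in range(basis.n_modes // 3):
            term = coup[3 * a + i] * state.q_ops[3 * a + i]
            op = term if op is None else op + term
        dip_ops.append(op)
    delta_e = evals[1:] - evals[0]
    iso_sq = np.empty(n_excited)
    for j in range(1, k):
        mu = np.array([psi0 @ (op @ evecs[:, j]) for op in dip_ops])
        iso_sq[j - 1] = (mu @ mu) / 3.0
    return delta_e, iso_sq


def converged_nmax(
    system: AtomicSystem,
    params: QDOParams,
    damping: DampingParams | None = None,
    start: int = 4,
    step: int = 2,
    e_tol: float = 1e-9,
    max_nmax: int = 14,
    **kwargs,
) -> int:
    """Smallest nmax at which successive ground energies differ < e_tol."""
    prev = fock_ground_state(system, params, damping, nmax=start, **kwargs).energy
    nmax = start
    while nmax + step <= max_nmax:
        nmax += step
        cur = fock_ground_state(system, params, damping, nmax=nmax, **kwargs).energy
        if abs(cur - prev) < e_tol:
            return nmax
        prev = cur
    return nmax
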