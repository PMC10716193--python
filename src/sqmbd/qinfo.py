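"""Gaussian-state quantum information for the collective ground state.

Because the ground state is Gaussian, the reduced state of any fragment is
fully determined by restricting the global second moments to the
fragment's composite indices (the partial trace of a Gaussian state).
Entropies come from the symplectic spectrum of the quadrature covariance:
a symplectic eigenvalue nu contributes

    s(nu) = (nu + 1/2) ln(nu + 1/2) - (nu - 1/2) ln(nu - 1/2)   [nats]

(in units of hbar), so the vacuum (nu = 1/2) carries zero entropy.  The
pairwise quantum mutual information MI_ab = S_a + S_b - S_ab feeds a
distance power-law fit and an eigenvector-centrality analysis of the
fragment interaction network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import statsmodels.api as sm

from .observables import GroundCovariances, ladder_moments
from .secondq import BogoliubovMap, ladder_map
from .structures import AtomicSystem, FragmentPartition
from .units import HBAR

__all__ = [
    "LadderCovariance",
    "MIMatrix",
    "CentralityVector",
    "reduced_covariance",
    "vn_entropy",
    "mutual_information",
    "mi_matrix",
    "mi_distance_fit",
    "eigenvector_centrality",
]


@dataclass(frozen=True)
class LadderCovariance:
    """Reduced second moments of a fragment, in both representations.

    ``sigma_ladder`` is the 2n x 2n block matrix
    ((<aa>, <a a^dag>), (<a^dag a>, <a^dag a^dag>)) over the fragment's
    composite modes; ``sigma_quad`` is the equivalent real symmetric
    quadrature covariance in (q..., p...) ordering.
    """

    indices: np.ndarray
    sigma_ladder: np.ndarray
    sigma_quad: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.indices.size

    def symplectic_eigenvalues(self) -> np.ndarray:
        return _symplectic_eigenvalues(self.sigma_quad)


def _resolve_indices(
    part: FragmentPartition, alpha: int | tuple[int, ...]
) -> np.ndarray:
    sel = (alpha,) if isinstance(alpha, (int, np.integer)) else tuple(alpha)
    return np.sort(np.concatenate([part.composite_indices(a) for a in sel]))


def reduced_covariance(
    source: BogoliubovMap | GroundCovariances,
    part: FragmentPartition,
    alpha: int | tuple[int, ...],
    omega_composite: np.ndarray | None = None,
) -> LadderCovariance:
    """Reduced covariance of one fragment (or a union of fragments).

    Accepts either the Bogoliubov map (ladder route) or the quadrature
    ground covariances; the two routes agree by construction of the
    ladder map and are cross-checked in the test suite.  For the ladder
    route, ``omega_composite`` (atomic frequencies per composite index) is
    required to produce the quadrature form.
    """
    idx = _resolve_indices(part, alpha)
    if isinstance(source, BogoliubovMap):
        if omega_composite is None:
            raise ValueError("ladder route needs omega_composite")
        mom = ladder_moments(source)
        m = mom["a_a"][np.ix_(idx, idx)]
        g = mom["adag_a"][np.ix_(idx, idx)]
        gt = mom["a_adag"][np.ix_(idx, idx)]
        w = np.asarray(omega_composite)[idx]
        sw = np.sqrt(np.outer(w, w))
        cqq = HBAR * (2.0 * m + g + gt) / (2.0 * sw)
        cpp = HBAR * sw * (g + gt - 2.0 * m) / 2.0
    else:
        cqq = source.cqq[np.ix_(idx, idx)]
        cpp = source.cpp[np.ix_(idx, idx)]
        modes = source.modes
        lm = ladder_map(np.repeat(modes.omega, 3)[idx])
        # invert the quadrature relations for the ladder second moments
        a_qq = np.outer(lm.d_sqrt, lm.d_sqrt) * cqq / HBAR
        a_pp = np.outer(lm.d_isqrt, lm.d_isqrt) * cpp / HBAR
        m = a_qq - a_pp
        g = a_qq + a_pp - 0.5 * np.eye(idx.size)
        gt = g + np.eye(idx.size)
    n = idx.size
    zero = np.zeros((n, n))
    sigma_ladder = np.block([[m, gt], [g, m]])
    sigma_quad = np.block([[cqq, zero], [zero, cpp]])
    return LadderCovariance(idx, sigma_ladder, sigma_quad)


def _symplectic_eigenvalues(sigma: np.ndarray) -> np.ndarray:
    """Williamson spectrum of a (q..., p...)-ordered quadrature covariance."""
    n = sigma.shape[0] // 2
    q = sigma[:n, :n]
    p = sigma[n:, n:]
    c = sigma[:n, n:]
    if np.abs(c).max(initial=0.0) < 1e-12:
        # block-diagonal fast path: nu^2 = spec(Q^{1/2} P Q^{1/2})
        lam, u = np.linalg.eigh(q)
        lam = np.clip(lam, 0.0, None)
        q_half = (u * np.sqrt(lam)) @ u.T
        nu_sq = np.linalg.eigvalsh(q_half @ p @ q_half)
        return np.sqrt(np.clip(nu_sq, 0.0, None)) / HBAR
    omega_form = np.block(
        [[np.zeros((n, n)), np.eye(n)], [-np.eye(n), np.zeros((n, n))]]
    )
    ev = np.linalg.eigvals(omega_form @ sigma)
    nu = np.sort(np.abs(ev.imag))
    return nu[::2] / HBAR  # each value appears twice (+/- i nu)


def vn_entropy(cov: LadderCovariance) -> float:
    """Von Neumann entropy (nats) from the symplectic spectrum."""
    nu = cov.symplectic_eigenvalues()
    if np.any(nu < 0.5 - 1e-8):
        raise ValueError(
            f"unphysical covariance: symplectic eigenvalue {nu.min():.6f} < 1/2"
        )
    nu = np.clip(nu, 0.5, None)
    up = nu + 0.5
    dn = nu - 0.5
    s = up * np.log(up)
    dn_safe = np.where(dn > 1e-12, dn, 1.0)  # (nu - 1/2) ln(nu - 1/2) -> 0
    s -= dn_safe * np.log(dn_safe)
    return float(s.sum())


def mutual_information(
    source: BogoliubovMap | GroundCovariances,
    part: FragmentPartition,
    alpha: int,
    beta: int,
    omega_composite: np.ndarray | None = None,
) -> float:
    """Quantum mutual information S_a + S_b - S_ab between two fragments."""
    if alpha == beta:
        raise ValueError("alpha and beta must differ")
    s_a = vn_entropy(reduced_covariance(source, part, alpha, omega_composite))
    s_b = vn_entropy(reduced_covariance(source, part, beta, omega_composite))
    s_ab = vn_entropy(reduced_covariance(source, part, (alpha, beta), omega_composite))
    return s_a + s_b - s_ab


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric fragment-pair mutual-information matrix (nats), zero diagonal."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-10):
            raise ValueError(f"grossly negative mutual information {v.min():.3e}")
        if np.any(v < 0):
            warnings.warn("clipping slightly negative MI entries to 0", stacklevel=2)
            v = np.clip(v, 0.0, None)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", 0.5 * (v + v.T))


def mi_matrix(
    source: BogoliubovMap | GroundCovariances,
    part: FragmentPartition,
    omega_composite: np.ndarray | None = None,
) -> MIMatrix:
    """All-pairs mutual information for a partition."""
    nf = part.n_fragments
    s_single = np.array(
        [vn_entropy(reduced_covariance(source, part, a, omega_composite)) for a in range(nf)]
    )
    values = np.zeros((nf, nf))
    for a in range(nf):
        for b in range(a + 1, nf):
            s_ab = vn_entropy(reduced_covariance(source, part, (a, b), omega_composite))
            values[a, b] = values[b, a] = s_single[a] + s_single[b] - s_ab
    return MIMatrix(part.names, values)


def fragment_centers_of_mass(
    system: AtomicSystem, part: FragmentPartition
) -> np.ndarray:
    masses = system.masses()
    out = np.empty((part.n_fragments, 3))
    for a in range(part.n_fragments):
        idx = part.atom_indices(a)
        w = masses[idx]
        out[a] = (w[:, None] * system.positions[idx]).sum(axis=0) / w.sum()
    return out


def mi_distance_fit(
    mi: MIMatrix,
    part: FragmentPartition,
    system: AtomicSystem,
    floor: float = 1e-14,
) -> tuple[float, float, float, int]:
    """OLS fit of ln(MI) on ln(d) over fragment pairs.

    d is the center-of-mass distance (standard atomic masses).  Returns
    (exponent, intercept, exponent standard error, n_excluded) where
    pairs with MI below ``floor`` are excluded from the fit.
    """
    com = fragment_centers_of_mass(system, part)
    log_mi, log_d = [], []
    excluded = 0
    for a in range(part.n_fragments):
        for b in range(a + 1, part.n_fragments):
            v = mi.values[a, b]
            if v <= floor:
                excluded += 1
                continue
            log_mi.append(np.log(v))
            log_d.append(np.log(np.linalg.norm(com[a] - com[b])))
    if len(log_mi) < 3:
        raise ValueError(f"only {len(log_mi)} usable fragment pairs (need >= 3)")
    x = sm.add_constant(np.asarray(log_d))
    fit = sm.OLS(np.asarray(log_mi), x).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.bse[1]), excluded


@dataclass(frozen=True)
class CentralityVector:
    """Eigenvector centrality of the MI graph, Perron-normalized."""

    names: tuple[str, ...]
    s: np.ndarray
    lambda_max: float


def eigenvector_centrality(mi: MIMatrix) -> CentralityVector:
    """Leading eigenvector of the MI matrix, non-negative, sum s^2 = 1."""
    values = mi.values
    if not np.any(values > 0):
        raise ValueError("all-zero mutual-information matrix")
    graph = nx.from_numpy_array(values)
    if not nx.is_connected(graph):
        warnings.warn(
            "MI graph is disconnected; centrality reflects the dominant component",
            stacklevel=2,
        )
    evals, evecs = np.linalg.eigh(values)
    lam = evals[-1]
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)  # Perron vector of a non-negative matrix
    v = v / np.linalg.norm(v)
    return CentralityVector(mi.names, v, float(lam))
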