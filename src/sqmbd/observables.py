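"""Ground-state expectation values of the coupled-QDO system.

The collective ground state is Gaussian, so every observable here reduces
to the second moments of either the quadratures (Cqq, Cpp) or the atomic
ladder operators.  In terms of the Bogoliubov pair (X, Y):

    <a^dag_mu a_nu>  = (Y^T Y)_{mu nu}
    <a_mu a^dag_nu>  = (X^T X)_{mu nu}
    <a_mu a_nu>      = -(X^T Y)_{mu nu}   (the anomalous moment)

and q-p cross covariances vanish identically for this real Hamiltonian.
Number-operator covariances follow from Wick contractions of these
moments; transition dipoles couple the ground state only to singly
excited collective modes, with per-atom matrix elements proportional to
omega_A sqrt(alpha_A) (the only combination of QDO charge and mass that
the parametrization fixes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonian import MBDModes
from .parameters import QDOParams
from .secondq import BogoliubovMap
from .structures import FragmentPartition
from .units import HBAR

__all__ = [
    "GroundCovariances",
    "ExcitationStats",
    "TransitionDipoles",
    "ground_covariances",
    "ladder_moments",
    "excitation_numbers",
    "excitation_covariance",
    "transition_dipoles",
    "fragment_pair_dipole",
]


@dataclass(frozen=True)
class GroundCovariances:
    """Position and momentum second moments of the collective ground state."""

    cqq: np.ndarray
    cpp: np.ndarray
    modes: MBDModes

    def mode_contribution(self, k: int, which: str = "cqq") -> np.ndarray:
        """Rank-1 contribution of mode k: (hbar/2w~_k) v_k v_k^T (or w~_k-weighted)."""
        v = self.modes.mode_vector(k)
        w = self.modes.omega_tilde[k]
        scale = HBAR / (2.0 * w) if which == "cqq" else HBAR * w / 2.0
        return scale * np.outer(v, v)


def ground_covariances(modes: MBDModes) -> GroundCovariances:
    """Cqq = O^T diag(hbar/2w~) O and Cpp = O^T diag(hbar w~/2) O."""
    o = modes.o
    wt = modes.omega_tilde
    cqq = (o.T * (HBAR / (2.0 * wt))[None, :]) @ o
    cpp = (o.T * (HBAR * wt / 2.0)[None, :]) @ o
    return GroundCovariances(cqq, cpp, modes)


def ladder_moments(bog: BogoliubovMap) -> dict[str, np.ndarray]:
    """Atomic-ladder second moments of the collective ground state."""
    g = bog.y.T @ bog.y          # <a^dag a>
    gt = bog.x.T @ bog.x         # <a a^dag>
    m = -bog.x.T @ bog.y         # <a a> (= <a^dag a^dag>, real state)
    return {"adag_a": g, "a_adag": gt, "a_a": m}


@dataclass(frozen=True)
class ExcitationStats:
    """Mean excitation numbers and their covariances in the ground state.

    ``cov_norm`` entries where either mean vanishes are NaN (undefined),
    not zero.
    """

    n_atom: np.ndarray          # per-atom <N_A>, length N
    n_composite: np.ndarray     # per composite index, length 3N
    cov: np.ndarray             # 3N x 3N number covariance
    cov_norm: np.ndarray        # normalized; NaN where undefined


def excitation_numbers(bog: BogoliubovMap) -> np.ndarray:
    """Per-atom mean excitation number <N_A> = sum_i (Y^T Y)_{3A+i, 3A+i}."""
    n_comp = np.einsum("km,km->m", bog.y, bog.y)
    return n_comp.reshape(-1, 3).sum(axis=1)


def excitation_covariance(bog: BogoliubovMap) -> ExcitationStats:
    """Number-operator covariance via Wick contraction of ladder moments.

    Cov(N_mu, N_nu) = <a^dag a^dag>_{mu nu} <a a>_{mu nu}
                    + <a^dag a>_{mu nu} <a a^dag>_{mu nu}.
    """
    mom = ladder_moments(bog)
    g, gt, m = mom["adag_a"], mom["a_adag"], mom["a_a"]
    cov = m * m + g * gt
    n_comp = np.diag(g).copy()
    denom = np.sqrt(np.outer(n_comp, n_comp))
    with np.errstate(divide="ignore", invalid="ignore"):
        cov_norm = np.where(denom > 0, cov / denom, np.nan)
    return ExcitationStats(
        n_atom=n_comp.reshape(-1, 3).sum(axis=1),
        n_composite=n_comp,
        cov=cov,
        cov_norm=cov_norm,
    )


@dataclass(frozen=True)
class TransitionDipoles:
    """Ground-to-single-excitation transition dipoles of every mode.

    ``per_atom[k, A, i]`` is the matrix element of the dipole operator of
    atom A along Cartesian axis i between the ground state and the state
    with one quantum in collective mode k (a.u.).
    """

    per_atom: np.ndarray        # (3N, N, 3)
    omega_tilde: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.per_atom.shape[0]

    def total_vector(self, k: int) -> np.ndarray:
        """Cartesian transition-dipole vector of mode k, summed over atoms."""
        return self.per_atom[k].sum(axis=0)

    def iso_modulus_sq(self, k: int | None = None) -> np.ndarray | float:
        """Isotropic square modulus |mu_k|^2 = (1/3)||sum_A mu_{k,A}||^2."""
        tot = self.per_atom.sum(axis=1)  # (3N, 3)
        vals = np.einsum("ki,ki->k", tot, tot) / 3.0
        return vals if k is None else float(vals[k])


def transition_dipoles(modes: MBDModes, params: QDOParams) -> TransitionDipoles:
    """Per-atom transition dipoles mu_{k;A,i} = w_A sqrt(alpha_A) O_{k,3A+i} sqrt(hbar/2w~_k).

    The QDO charge-to-root-mass ratio Z_A e / sqrt(m_A) equals
    omega_A sqrt(alpha_A) through alpha = Z^2 e^2/(m omega^2); neither the
    charge nor the mass is needed separately.
    """
    if params.n_atoms * 3 != modes.n_modes:
        raise ValueError("params/modes size mismatch")
    coup = np.repeat(params.omega * np.sqrt(params.alpha), 3)  # per composite
    amp = np.sqrt(HBAR / (2.0 * modes.omega_tilde))            # per mode
    per_comp = amp[:, None] * modes.o * coup[None, :]          # (3N, 3N)
    per_atom = per_comp.reshape(modes.n_modes, -1, 3)
    return TransitionDipoles(per_atom, modes.omega_tilde.copy())


def fragment_pair_dipole(
    td: TransitionDipoles, part: FragmentPartition, k: int
) -> np.ndarray:
    """Fragment-pair decomposition of the isotropic transition-dipole square.

    (|mu_k|^2)_{ab} = (1/3) sum_{A in a, B in b} sum_i mu_{k;A,i} mu_{k;B,i};
    summing every entry recovers the total isotropic square modulus.
    """
    if not 0 <= k < td.n_modes:
        raise IndexError(f"mode index {k} out of range [0, {td.n_modes})")
    frag_sum = np.stack(
        [td.per_atom[k][part.atom_indices(a)].sum(axis=0) for a in range(part.n_fragments)]
    )  # (n_frag, 3)
    return frag_sum @ frag_sum.T / 3.0


def static_polarizability(modes: MBDModes, params: QDOParams) -> np.ndarray:
    """Interacting static polarizability tensor from the dipole sum rule.

    alpha_stat = sum_k (2/hbar w~_k) mu_k mu_k^T with mu_k the total
    transition-dipole vector of mode k; equals B^T V^{-1} B with
    B_{mu,i} = omega_A sqrt(alpha_A) delta_{i, comp(mu)}.
    """
    td = transition_dipoles(modes, params)
    tot = td.per_atom.sum(axis=1)  # (3N, 3)
    w = 2.0 / (HBAR * modes.omega_tilde)
    return np.einsum("k,ki,kj->ij", w, tot, tot)
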