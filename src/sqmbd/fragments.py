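"""Fragment- and mode-resolved decomposition of the dispersion energy.

For a partition {F_a} the ground-state expectation of the Hamiltonian
restricted to fragment atoms splits E_MBD into

    U_a      internal energy of fragment a (its restricted kinetic +
             potential expectation minus the uncoupled zero point
             (3 hbar/2) sum_{A in a} omega_A),
    V_ab     mutual interaction: the full cross-coupling expectation
             sum_{A in a, B in b} Tr[V_AB Cqq(B,A)], each unordered
             cross pair counted once,
    E_frag_a = U_a + sum_{b != a} V_ab / ... row sum with half of V_ab
             assigned to each ordered fragment pair,

so that sum_a E_frag_a = E_MBD exactly.  Replacing Cqq by the rank-1
contribution of a single collective mode resolves V_ab over modes; modes
with a negative (positive) contribution are "bonding" ("antibonding") for
that fragment pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonian import MBDModes, MBDPotential
from .observables import GroundCovariances
from .structures import FragmentPartition
from .units import HBAR

__all__ = [
    "FragmentEnergies",
    "ModeSpectrum",
    "fragment_energy_table",
    "mode_resolved_interaction",
    "classify_modes",
    "atom_pair_mode_map",
]


@dataclass(frozen=True)
class FragmentEnergies:
    """U (per fragment), V (fragment-pair, zero diagonal), E_frag (Ha)."""

    names: tuple[str, ...]
    u: np.ndarray
    v: np.ndarray
    e_frag: np.ndarray

    @property
    def total(self) -> float:
        """Sum of fragment contributions; equals E_MBD by construction."""
        return float(self.e_frag.sum())


def _blocks(idx_a: np.ndarray, idx_b: np.ndarray, m: np.ndarray) -> np.ndarray:
    return m[np.ix_(idx_a, idx_b)]


def fragment_energy_table(
    cov: GroundCovariances,
    potential: MBDPotential,
    part: FragmentPartition,
) -> FragmentEnergies:
    """Fragment decomposition of the MBD energy from ground-state covariances."""
    if part.n_atoms != potential.n_atoms:
        raise ValueError("partition/system size mismatch")
    nf = part.n_fragments
    omega = potential.omega
    u = np.empty(nf)
    comp = [part.composite_indices(a) for a in range(nf)]
    atoms = [part.atom_indices(a) for a in range(nf)]
    for a in range(nf):
        ia = comp[a]
        kin = 0.5 * np.trace(_blocks(ia, ia, cov.cpp))
        pot = 0.5 * np.sum(_blocks(ia, ia, potential.matrix) * _blocks(ia, ia, cov.cqq))
        u[a] = kin + pot - 1.5 * HBAR * omega[atoms[a]].sum()
    v = np.zeros((nf, nf))
    for a in range(nf):
        for b in range(a + 1, nf):
            ia, ib = comp[a], comp[b]
            v[a, b] = v[b, a] = np.sum(
                _blocks(ia, ib, potential.matrix) * _blocks(ia, ib, cov.cqq)
            )
    # half of each unordered-pair energy is assigned to either fragment,
    # the unique split under which the fragment totals sum to E_MBD
    e_frag = u + 0.5 * v.sum(axis=1)
    return FragmentEnergies(part.names, u, v, e_frag)


@dataclass(frozen=True)
class ModeSpectrum:
    """Per-mode contributions to one fragment pair's interaction energy."""

    contributions: np.ndarray   # length 3N, Hartree
    omega_tilde: np.ndarray
    pair: tuple[int, int]

    @property
    def total(self) -> float:
        return float(self.contributions.sum())


def mode_resolved_interaction(
    modes: MBDModes,
    potential: MBDPotential,
    part: FragmentPartition,
    alpha: int,
    beta: int,
) -> ModeSpectrum:
    """Decompose V_ab over collective modes via the rank-1 Cqq expansion.

    (V)_{ab,k} = sum_{A in a, B in b} Tr[V_AB (hbar/2w~_k)(v_k v_k^T)(A,B)].
    """
    if alpha == beta:
        raise ValueError("alpha and beta must differ (use the internal-energy path)")
    ia = part.composite_indices(alpha)
    ib = part.composite_indices(beta)
    vab = potential.matrix[np.ix_(ia, ib)]
    o_a = modes.o[:, ia]  # (3N, |a|)
    o_b = modes.o[:, ib]
    scale = HBAR / (2.0 * modes.omega_tilde)
    contrib = scale * np.einsum("km,mn,kn->k", o_a, vab, o_b)
    return ModeSpectrum(contrib, modes.omega_tilde.copy(), (alpha, beta))


def classify_modes(spectrum: ModeSpectrum, epsilon: float = 1e-8) -> list[str]:
    """Label each mode bonding (< -eps), antibonding (> +eps) or negligible."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    labels = []
    for c in spectrum.contributions:
        if c < -epsilon:
            labels.append("bonding")
        elif c > epsilon:
            labels.append("antibonding")
        else:
            labels.append("negligible")
    return labels


def atom_pair_mode_map(
    modes: MBDModes, potential: MBDPotential, k: int
) -> np.ndarray:
    """Atom-pair contributions of mode k to the coupling energy (zero diagonal).

    Entry (A, B) = Tr[V_AB (hbar/2w~_k)(v_k v_k^T)(A, B)] for A != B; the
    sum of any cross-fragment block equals that pair's mode-k interaction.
    """
    if not 0 <= k < modes.n_modes:
        raise IndexError(f"mode index {k} out of range")
    n = potential.n_atoms
    v_k = modes.mode_vector(k)
    scale = HBAR / (2.0 * modes.omega_tilde[k])
    weighted = potential.matrix * np.outer(v_k, v_k) * scale
    per_pair = weighted.reshape(n, 3, n, 3).sum(axis=(1, 3))
    np.fill_diagonal(per_pair, 0.0)
    return per_pair


def merge_fragments(
    part: FragmentPartition, alpha: int, beta: int, name: str | None = None
) -> FragmentPartition:
    """Partition with fragments alpha and beta merged (refinement tests)."""
    if alpha == beta:
        raise ValueError("cannot merge a fragment with itself")
    names, frags = [], []
    merged = part.fragments[alpha] | part.fragments[beta]
    merged_name = name or f"{part.names[alpha]}+{part.names[beta]}"
    for i, (n, f) in enumerate(zip(part.names, part.fragments)):
        if i == alpha:
            names.append(merged_name)
            frags.append(frozenset(merged))
        elif i != beta:
            names.append(n)
            frags.append(f)
    return FragmentPartition(tuple(names), tuple(frags), part.n_atoms)
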