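"""First <-> second quantization maps and the multimodal Bogoliubov transform.

For a harmonic mode of frequency w, a = sqrt(w/2hbar) q + i/sqrt(2 hbar w) p.
Collecting all 3N atomic (or collective) modes gives the diagonal-scaling
ladder map M(omega).  Composing atomic-side M, the orthogonal modal matrix O
and the collective-side map gives the Bogoliubov pair

    X = (1/2) [ Dt^{1/2} O D^{-1/2} + Dt^{-1/2} O D^{1/2} ]
    Y = (1/2) [ Dt^{1/2} O D^{-1/2} - Dt^{-1/2} O D^{1/2} ]

with D = diag(omega per composite index), Dt = diag(omega_tilde), so that
b = X a + Y a^dagger.  X X^T - Y Y^T = I (canonical commutation relations
are preserved) and Theta = X^{-1} Y is symmetric with spectral radius < 1;
Theta generates the collective ground state as a squeezed vacuum
exp(a^dag Theta a^dag / 2)|0> / det(XX^T)^{1/4}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .hamiltonian import MBDModes
from .units import HBAR

__all__ = ["LadderMap", "BogoliubovMap", "ladder_map", "bogoliubov_xy"]

#: hard cap on atom count for dense 3N x 3N storage
MAX_ATOMS = 5000


@dataclass(frozen=True)
class LadderMap:
    """Diagonal-scaling representation of the map (q, p) -> (a, a^dagger).

    The blocks are M_aq = M_a+q = (1/sqrt(2 hbar)) D^{1/2} and
    M_ap = -M_a+p = (i/sqrt(2 hbar)) D^{-1/2}; only the real diagonal
    factors are stored, the imaginary unit being carried by the fixed sign
    pattern of the block structure.
    """

    frequencies: np.ndarray  # per composite index, length 3N

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if np.any(f <= 0):
            raise ValueError("ladder map requires positive frequencies")
        object.__setattr__(self, "frequencies", f)

    @property
    def d_sqrt(self) -> np.ndarray:
        """Diagonal of D^{1/2} / sqrt(2 hbar): coefficient of q in a."""
        return np.sqrt(self.frequencies / (2.0 * HBAR))

    @property
    def d_isqrt(self) -> np.ndarray:
        """Diagonal of D^{-1/2} / sqrt(2 hbar): coefficient of (i p) in a."""
        return 1.0 / np.sqrt(2.0 * HBAR * self.frequencies)

    def to_ladder(self, q: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(q, p) -> (a, a^dagger); accepts complex expectation amplitudes."""
        a = self.d_sqrt * q + 1j * self.d_isqrt * p
        adag = self.d_sqrt * q - 1j * self.d_isqrt * p
        return a, adag

    def to_quadrature(
        self, a: np.ndarray, adag: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(a, a^dagger) -> (q, p), the exact inverse of :meth:`to_ladder`."""
        q = (a + adag) / (2.0 * self.d_sqrt)
        p = (a - adag) / (2j * self.d_isqrt)
        return q, p


def ladder_map(frequencies: np.ndarray) -> LadderMap:
    """Ladder map for a set of positive composite-index frequencies."""
    return LadderMap(np.asarray(frequencies, dtype=float))


@dataclass(frozen=True)
class BogoliubovMap:
    """X, Y of b = X a + Y a^dagger and Theta = X^{-1} Y."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.x.shape[0]

    def symplectic_defect(self) -> float:
        """max |X X^T - Y Y^T - I|; zero for an exact Bogoliubov map."""
        eye = np.eye(self.n_modes)
        return float(np.abs(self.x @ self.x.T - self.y @ self.y.T - eye).max())


def bogoliubov_xy(modes: MBDModes) -> BogoliubovMap:
    """Bogoliubov (X, Y, Theta) connecting atomic and collective ladders.

    Theta is obtained by linear solve (never an explicit inverse) and
    symmetrized by averaging with its transpose; an asymmetry beyond 1e-8
    before symmetrization raises, since it signals corrupted modes.
    """
    if modes.n_modes > 3 * MAX_ATOMS:
        raise ValueError(f"system exceeds the {MAX_ATOMS}-atom dense-storage cap")
    d = np.repeat(modes.omega, 3)  # atomic frequencies per composite index
    dt = modes.omega_tilde
    o = modes.o
    # P = Dt^{1/2} O D^{-1/2}, Q = Dt^{-1/2} O D^{1/2}
    p = np.sqrt(dt)[:, None] * o / np.sqrt(d)[None, :]
    q = o * np.sqrt(d)[None, :] / np.sqrt(dt)[:, None]
    x = 0.5 * (p + q)
    y = 0.5 * (p - q)
    theta = scipy.linalg.solve(x, y)
    asym = float(np.abs(theta - theta.T).max())
    if asym > 1e-8:
        raise ValueError(f"Theta asymmetry {asym:.2e} exceeds 1e-8")
    theta = 0.5 * (theta + theta.T)
    return BogoliubovMap(x, y, theta)


def reconstruct_modal_matrix(bog: BogoliubovMap, modes: MBDModes) -> np.ndarray:
    """Invert the Bogoliubov construction back to the orthogonal matrix O.

    X + Y = Dt^{1/2} O D^{-1/2}, so O = Dt^{-1/2} (X + Y) D^{1/2}.
    """
    d = np.repeat(modes.omega, 3)
    dt = modes.omega_tilde
    return (bog.x + bog.y) * np.sqrt(d)[None, :] / np.sqrt(dt)[:, None]
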