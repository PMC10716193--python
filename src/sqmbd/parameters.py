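"""Per-atom quantum-Drude-oscillator parameters.

Two parametrization stages are produced:

``aim``
    Free-atom reference values scaled by the atom-in-molecule ratio eta
    (Tkatchenko-Scheffler): C6 <- eta^2 C6_0, alpha <- eta alpha_0,
    R_vdW <- eta^(1/3) R_vdW_0.
``scs``
    The aim parameters screened self-consistently through the short-range
    part of the range-separated dipole tensor, with the screened C6
    recovered by Casimir-Polder quadrature over imaginary frequency.

The characteristic QDO frequency is omega = (4/3) C6 / (hbar alpha^2) at
either stage; it is invariant under the aim scaling.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import AtomicSystem
from .units import HBAR

__all__ = [
    "FreeAtomReference",
    "QDOParams",
    "FrequencyGrid",
    "scale_free_atom",
    "qdo_frequency",
    "scs_screen",
]


@dataclass(frozen=True)
class FreeAtomReference:
    """Free-atom alpha_0 (Bohr^3), C6_0 (Ha Bohr^6), R_vdW_0 (Bohr)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"alpha0", "c60", "rvdw0"}
        if not required <= set(self.table.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        if (self.table[list(required)] <= 0).any().any():
            raise ValueError("free-atom reference values must be positive")

    @classmethod
    def packaged(cls) -> "FreeAtomReference":
        with importlib.resources.files("sqmbd.data").joinpath(
            "free_atom_params.csv"
        ).open() as fh:
            table = pd.read_csv(fh, comment="#", index_col="element")
        return cls(table)

    def lookup(self, elements: tuple[str, ...]) -> pd.DataFrame:
        missing = sorted(set(elements) - set(self.table.index))
        if missing:
            raise KeyError(f"elements missing from reference table: {missing}")
        return self.table.loc[list(elements)]


@dataclass(frozen=True)
class QDOParams:
    """Per-atom (alpha, C6, R_vdW, omega) at a given parametrization stage."""

    alpha: np.ndarray
    c6: np.ndarray
    r_vdw: np.ndarray
    omega: np.ndarray
    stage: str  # 'aim' or 'scs'

    def __post_init__(self) -> None:
        for name in ("alpha", "c6", "r_vdw", "omega"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or np.any(arr <= 0):
                raise ValueError(f"{name} must be a 1-D positive array")
            object.__setattr__(self, name, arr)
        if self.stage not in ("aim", "scs"):
            raise ValueError(f"unknown stage {self.stage!r}")
        # omega must be consistent with (c6, alpha)
        expected = qdo_frequency(self.c6, self.alpha)
        if not np.allclose(self.omega, expected, rtol=1e-12, atol=0.0):
            raise ValueError("omega inconsistent with (c6, alpha)")

    @property
    def n_atoms(self) -> int:
        return self.alpha.size


def qdo_frequency(c6: np.ndarray | float, alpha: np.ndarray | float) -> np.ndarray:
    """Characteristic QDO angular frequency omega = (4/3) C6 / (hbar alpha^2)."""
    c6 = np.asarray(c6, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(c6 <= 0) or np.any(alpha <= 0):
        raise ValueError("c6 and alpha must be positive")
    return (4.0 / 3.0) * c6 / (HBAR * alpha**2)


def scale_free_atom(
    ref: FreeAtomReference | None, system: AtomicSystem
) -> QDOParams:
    """Tkatchenko-Scheffler scaling of free-atom reference values by eta."""
    if system.eta is None:
        raise ValueError("system has no eta ratios attached")
    if ref is None:
        ref = FreeAtomReference.packaged()
    rows = ref.lookup(system.elements)
    eta = system.eta
    alpha = eta * rows["alpha0"].to_numpy()
    c6 = eta**2 * rows["c60"].to_numpy()
    r_vdw = eta ** (1.0 / 3.0) * rows["rvdw0"].to_numpy()
    return QDOParams(alpha, c6, r_vdw, qdo_frequency(c6, alpha), stage="aim")


@dataclass(frozen=True)
class FrequencyGrid:
    """Imaginary-frequency quadrature nodes/weights on [0, inf).

    Gauss-Legendre on (-1, 1) mapped through omega = scale*(1+t)/(1-t),
    the de-facto standard grid for Casimir-Polder integrals in MBD codes.
    """

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_legendre(cls, n: int = 15, scale: float = 0.6) -> "FrequencyGrid":
        if n < 10:
            raise ValueError("need at least 10 quadrature nodes")
        t, w = np.polynomial.legendre.leggauss(n)
        nodes = scale * (1.0 + t) / (1.0 - t)
        weights = w * 2.0 * scale / (1.0 - t) ** 2
        return cls(nodes, weights)

    def casimir_polder_c6(self, alpha_a: np.ndarray, alpha_b: np.ndarray) -> np.ndarray:
        """C6 = (3/pi) * sum_g w_g alpha_A(i w_g) alpha_B(i w_g)."""
        return (3.0 / np.pi) * np.einsum("g,g...,g...->...", self.weights, alpha_a, alpha_b)


def dynamic_polarizability(params: QDOParams, omega_im: float) -> np.ndarray:
    """Isotropic QDO polarizability alpha/(1 + w^2/omega_A^2) at iw."""
    return params.alpha / (1.0 + (omega_im / params.omega) ** 2)


def scs_screen(
    params: QDOParams,
    system: AtomicSystem,
    grid: FrequencyGrid | None = None,
    damping: "DampingParams | None" = None,
) -> QDOParams:
    """Range-separated self-consistent screening of aim-stage parameters.

    At every quadrature frequency the bare per-atom dynamic polarizabilities
    are dressed through the short-range part of the oscillator-regularized
    (erf) dipole tensor by solving ``abar = (A^-1 + T_sr)^-1`` (a dense
    3N x 3N linear system) and each
    atom's screened tensor is contracted to a scalar by summing its row of
    partner blocks and taking one third of the trace.  Screened C6 follows
    from the Casimir-Polder quadrature, the screened van der Waals radius
    scales as the cube root of the polarizability ratio, and omega is
    recomputed from the screened (C6, alpha).
    """
    from .hamiltonian import DampingParams, dipole_coupling_matrix, qho_width

    if params.stage != "aim":
        raise ValueError("scs_screen expects aim-stage parameters")
    if grid is None:
        grid = FrequencyGrid.gauss_legendre()
    if damping is None:
        damping = DampingParams()
    n = system.n_atoms
    alpha_bar = np.empty((grid.nodes.size + 1, n))
    freqs = np.concatenate([[0.0], grid.nodes])
    for g, w in enumerate(freqs):
        a_dyn = dynamic_polarizability(params, w)
        # short-range part of the oscillator-regularized dipole tensor,
        # with Gaussian widths tracking the dynamic polarizabilities
        t_sr = dipole_coupling_matrix(
            system, params.r_vdw, damping, range_part="short_range",
            sigma=qho_width(a_dyn),
        )
        b = t_sr
        diag = np.repeat(1.0 / a_dyn, 3)
        b[np.diag_indices_from(b)] += diag
        try:
            full = np.linalg.inv(b)
        except np.linalg.LinAlgError as exc:
            piv = np.abs(np.linalg.eigvalsh(b)).min()
            d = system.distance_matrix()
            np.fill_diagonal(d, np.inf)
            a, bb = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"singular screening system (polarization catastrophe): "
                f"smallest pivot {piv:.3e}, closest atoms {a} and {bb} "
                f"at {d[a, bb]:.3f} Bohr"
            ) from exc
        # row-sum over partner blocks, then isotropic (1/3) trace
        blocks = full.reshape(n, 3, n, 3).sum(axis=2)
        alpha_bar[g] = np.trace(blocks, axis1=1, axis2=2) / 3.0
    alpha_scs = alpha_bar[0]
    if np.any(alpha_scs <= 0):
        bad = int(np.argmax(alpha_scs <= 0))
        raise ValueError(f"negative screened polarizability for atom {bad}")
    c6_scs = grid.casimir_polder_c6(alpha_bar[1:], alpha_bar[1:])
    r_vdw_scs = params.r_vdw * (alpha_scs / params.alpha) ** (1.0 / 3.0)
    return QDOParams(
        alpha_scs, c6_scs, r_vdw_scs, qdo_frequency(c6_scs, alpha_scs), stage="scs"
    )
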