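import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from sqmbd.fixtures import FixtureSpec, dimer_system, generate
from sqmbd.hamiltonian import (
    DampingParams,
    MBDPotential,
    assemble_potential,
    bare_dipole_tensor,
    diagonalize_modes,
    erf_dipole_tensor,
    mbd_energy,
    range_damping,
)
from sqmbd.parameters import scale_free_atom
from sqmbd.structures import AtomicSystem

unit_vectors = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).filter(lambda v: 0.1 < np.linalg.norm(v) < 1.8)


def test_axis_aligned_dipole_tensor():
    r = 3.0
    t = bare_dipole_tensor(np.array([0.0, 0.0, r]))
    np.testing.assert_allclose(t, np.diag([1.0, 1.0, -2.0]) / r**3, atol=1e-15)


@given(v=unit_vectors)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_dipole_tensor_traceless_symmetric(v):
    t = bare_dipole_tensor(np.asarray(v) * 3.0)
    assert abs(np.trace(t)) < 1e-14
    np.testing.assert_allclose(t, t.T, atol=1e-15)


def test_dipole_tensor_matches_coulomb_hessian():
    """T = grad_A grad_B 1/|R| = -Hessian_r, by central differences."""
    rng = np.random.default_rng(5)
    r0 = rng.normal(size=3) * 3.0
    h = 1e-4
    hess = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
            hess[i, j] = (
                1 / np.linalg.norm(r0 + ei + ej)
                - 1 / np.linalg.norm(r0 + ei - ej)
                - 1 / np.linalg.norm(r0 - ei + ej)
                + 1 / np.linalg.norm(r0 - ei - ej)
            ) / (4 * h * h)
    np.testing.assert_allclose(bare_dipole_tensor(r0), -hess, atol=1e-6)


def test_erf_tensor_limits():
    r_vec = np.array([0.0, 0.0, 4.0])
    # wide separation: reduces to the bare tensor
    np.testing.assert_allclose(
        erf_dipole_tensor(r_vec, 0.2), bare_dipole_tensor(r_vec), rtol=1e-10
    )
    # near contact: finite, bounded by the contact value 4/(3 sqrt(pi) s^3)
    close = erf_dipole_tensor(np.array([0.0, 0.0, 1e-3]), 2.0)
    assert np.all(np.isfinite(close))
    np.testing.assert_allclose(
        close, 4.0 / (3 * np.sqrt(np.pi) * 2.0**3) * np.eye(3), atol=1e-6
    )


def test_zero_separation_errors():
    with pytest.raises(ValueError):
        bare_dipole_tensor(np.zeros(3))


def test_range_damping_midpoint_and_limits():
    d = DampingParams()
    assert range_damping(0.83 * 6.0, 6.0, d) == pytest.approx(0.5)
    assert range_damping(1e3, 6.0, d) == pytest.approx(0.0, abs=1e-12)
    assert range_damping(1e-9, 6.0, d) == pytest.approx(1 - 1 / (1 + np.exp(6.0)), rel=1e-6)


def test_single_atom_potential_is_harmonic():
    system = AtomicSystem(("C",), np.zeros((1, 3)), eta=np.array([1.0]))
    params = scale_free_atom(None, system)
    pot = assemble_potential(system, params)
    np.testing.assert_allclose(pot.matrix, params.omega[0] ** 2 * np.eye(3))


def test_dimer_potential_matches_hand_assembly():
    """Independent term-by-term 6x6 construction from the damped tensor."""
    system, _ = dimer_system(5.0, "C", 0.9)
    params = scale_free_atom(None, system)
    damping = DampingParams()
    pot = assemble_potential(system, params, damping, range_part="long_range")

    w, alpha, rv = params.omega, params.alpha, params.r_vdw
    r_vec = system.positions[1] - system.positions[0]
    r = np.linalg.norm(r_vec)
    g = 1.0 - 1.0 / (1.0 + np.exp(-damping.a * (r / (damping.beta * (rv[0] + rv[1])) - 1)))
    t = (np.eye(3) - 3 * np.outer(r_vec / r, r_vec / r)) / r**3
    off = w[0] * w[1] * np.sqrt(alpha[0] * alpha[1]) * (1.0 - g) * t
    expected = np.zeros((6, 6))
    expected[:3, :3] = w[0] ** 2 * np.eye(3)
    expected[3:, 3:] = w[1] ** 2 * np.eye(3)
    expected[:3, 3:] = off
    expected[3:, :3] = off.T
    np.testing.assert_allclose(pot.matrix, expected, atol=1e-14)


def test_potential_symmetric_on_cluster(cluster_result):
    v = cluster_result.potential.matrix
    np.testing.assert_allclose(v, v.T, atol=1e-12)


def analytic_dimer_frequencies(omega, alpha, r):
    """Closed-form spectrum of two identical bare-coupled QDOs on an axis."""
    t_long, t_trans = -2.0 / r**3, 1.0 / r**3
    freqs = [
        omega * np.sqrt(1 + alpha * t_long),
        omega * np.sqrt(1 - alpha * t_long),
        omega * np.sqrt(1 + alpha * t_trans),
        omega * np.sqrt(1 + alpha * t_trans),
        omega * np.sqrt(1 - alpha * t_trans),
        omega * np.sqrt(1 - alpha * t_trans),
    ]
    return np.sort(freqs)


def test_two_oscillator_spectrum_closed_form():
    system, _ = dimer_system(8.0, "C", 1.0)
    params = scale_free_atom(None, system)
    pot = assemble_potential(system, params, range_part="bare")
    modes = diagonalize_modes(pot)
    expected = analytic_dimer_frequencies(params.omega[0], params.alpha[0], 8.0)
    np.testing.assert_allclose(modes.omega_tilde, expected, atol=1e-10)


def test_modes_reconstruct_potential(cluster_result):
    modes = cluster_result.modes
    recon = modes.o.T @ np.diag(modes.omega_tilde**2) @ modes.o
    v = cluster_result.potential.matrix
    assert np.abs(recon - v).max() / np.abs(v).max() < 1e-9
    np.testing.assert_allclose(modes.o @ modes.o.T, np.eye(modes.n_modes), atol=1e-10)
    assert np.all(np.diff(modes.omega_tilde) >= 0)


def test_uncoupled_system_zero_energy():
    system, _ = dimer_system(1e5, "C", 1.0)
    params = scale_free_atom(None, system)
    modes = diagonalize_modes(assemble_potential(system, params))
    assert mbd_energy(modes) == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(modes.omega_tilde, np.repeat(params.omega, 3), rtol=1e-12)


def test_large_r_energy_matches_leading_dispersion():
    """E -> -(3/4) hbar omega alpha^2 / R^6 where damping is negligible."""
    system, _ = dimer_system(30.0, "C", 1.0)
    params = scale_free_atom(None, system)
    modes = diagonalize_modes(assemble_potential(system, params, range_part="bare"))
    w, a = params.omega[0], params.alpha[0]
    assert mbd_energy(modes) == pytest.approx(-0.75 * w * a**2 / 30.0**6, rel=0.01)


def test_damped_dimer_curve_monotone_to_zero():
    energies = []
    for r in [6.0, 8.0, 10.0, 14.0, 20.0]:
        system, _ = dimer_system(r, "C", 1.0)
        params = scale_free_atom(None, system)
        energies.append(diagonalize_modes(assemble_potential(system, params)).e_mbd)
    energies = np.array(energies)
    assert np.all(energies < 0)
    assert np.all(np.diff(energies) > 0)  # increasing toward 0-


def test_rigid_motion_leaves_spectrum_invariant():
    system, _ = generate(FixtureSpec(n_atoms=6, seed=2))
    params = scale_free_atom(None, system)
    base = diagonalize_modes(assemble_potential(system, params)).omega_tilde
    rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
    moved = AtomicSystem(
        system.elements, system.positions @ rot.T + np.array([5.0, -3.0, 1.0]),
        eta=system.eta,
    )
    rotated = diagonalize_modes(assemble_potential(moved, params)).omega_tilde
    assert np.abs(rotated / base - 1).max() < 1e-9


def test_permutation_equivariance():
    system, _ = generate(FixtureSpec(n_atoms=5, seed=9))
    params = scale_free_atom(None, system)
    modes = diagonalize_modes(assemble_potential(system, params))
    perm = np.array([3, 1, 4, 0, 2])
    permuted = AtomicSystem(
        tuple(system.elements[p] for p in perm), system.positions[perm],
        eta=system.eta[perm],
    )
    params_p = scale_free_atom(None, permuted)
    modes_p = diagonalize_modes(assemble_potential(permuted, params_p))
    np.testing.assert_allclose(modes_p.omega_tilde, modes.omega_tilde, rtol=1e-10)
    assert modes_p.e_mbd == pytest.approx(modes.e_mbd, abs=1e-12)
    # columns permute with the atoms (up to the fixed sign convention)
    comp = (3 * perm[:, None] + np.arange(3)[None, :]).ravel()
    np.testing.assert_allclose(
        np.abs(modes_p.o), np.abs(modes.o[:, comp]), atol=1e-8
    )


def test_polarization_catastrophe_reported():
    system, _ = dimer_system(1.2, "C", 1.0)
    params = scale_free_atom(None, system)
    pot = assemble_potential(system, params, range_part="bare")
    with pytest.raises(ValueError, match="polarization catastrophe"):
        diagonalize_modes(pot)
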