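import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import uncoupled_modes
from sqmbd.fixtures import FixtureSpec, dimer_system, generate
from sqmbd.fragments import fragment_energy_table
from sqmbd.observables import ground_covariances
from sqmbd.pipeline import run_mbd
from sqmbd.qinfo import (
    MIMatrix,
    eigenvector_centrality,
    mi_distance_fit,
    mi_matrix,
    mutual_information,
    reduced_covariance,
    vn_entropy,
)
from sqmbd.structures import AtomicSystem, FragmentPartition


def test_whole_system_is_pure(cluster_result):
    part = FragmentPartition.single(cluster_result.system.n_atoms)
    cov = reduced_covariance(cluster_result.covariances, part, 0)
    nu = cov.symplectic_eigenvalues()
    np.testing.assert_allclose(nu, 0.5, atol=1e-10)
    assert vn_entropy(cov) == pytest.approx(0.0, abs=1e-8)


def test_vacuum_entropy_zero():
    modes = uncoupled_modes(n_atoms=2, omega=0.5)
    cov = ground_covariances(modes)
    part = FragmentPartition.from_dict({"a": [0], "b": [1]}, 2)
    assert vn_entropy(reduced_covariance(cov, part, 0)) == pytest.approx(0.0, abs=1e-12)
    assert mutual_information(cov, part, 0, 1) == pytest.approx(0.0, abs=1e-10)


def test_complementary_fragments_equal_entropy(two_blob):
    system, part, result = two_blob
    s_a = vn_entropy(reduced_covariance(result.covariances, part, 0))
    s_b = vn_entropy(reduced_covariance(result.covariances, part, 1))
    assert s_a == pytest.approx(s_b, abs=1e-8)
    assert s_a > 0


def test_ladder_and_quadrature_routes_agree(cluster_result):
    part = FragmentPartition.from_dict(
        {"a": [0, 1, 2], "b": [3, 4], "c": [5, 6, 7]}, 8
    )
    omega_comp = cluster_result.omega_composite
    for alpha in (0, 1, (0, 2)):
        via_cov = reduced_covariance(cluster_result.covariances, part, alpha)
        via_bog = reduced_covariance(
            cluster_result.bogoliubov, part, alpha, omega_composite=omega_comp
        )
        np.testing.assert_allclose(
            via_cov.sigma_quad, via_bog.sigma_quad, atol=1e-10
        )
        np.testing.assert_allclose(
            via_cov.sigma_ladder, via_bog.sigma_ladder, atol=1e-10
        )
        assert vn_entropy(via_cov) == pytest.approx(vn_entropy(via_bog), abs=1e-10)


def test_mi_symmetric_nonnegative(cluster_result):
    part = FragmentPartition.from_dict(
        {"a": [0, 1], "b": [2, 3], "c": [4, 5], "d": [6, 7]}, 8
    )
    mi = mi_matrix(cluster_result.covariances, part)
    np.testing.assert_allclose(mi.values, mi.values.T, atol=1e-12)
    assert np.all(mi.values >= 0)
    assert np.all(np.diag(mi.values) == 0)


def test_mi_decreases_with_dimer_separation():
    values = []
    for r in (5.0, 7.0, 9.0, 12.0, 16.0):
        system, part = dimer_system(r, "C", 1.0)
        result = run_mbd(system, screen=False)
        values.append(mutual_information(result.covariances, part, 0, 1))
    assert np.all(np.diff(values) < 0)
    assert values[-1] > 0


def test_mi_energy_correlation(two_blob):
    """MI and |V_ab| rank together across pairs of a partitioned cluster."""
    system, _, result = two_blob
    part = FragmentPartition.from_dict(
        {f"f{i}": [2 * i, 2 * i + 1] for i in range(5)}, 10
    )
    mi = mi_matrix(result.covariances, part)
    table = fragment_energy_table(result.covariances, result.potential, part)
    iu = np.triu_indices(5, k=1)
    rho = spearmanr(mi.values[iu], np.abs(table.v[iu])).statistic
    assert rho > 0.9


def test_mi_fit_exact_power_law():
    """Noiseless MI ~ d^-6 data must return slope -6 with zero stderr."""
    positions = np.array(
        [[0, 0, 0], [10, 0, 0], [0, 17, 0], [0, 0, 26], [13, 13, 0]], dtype=float
    )
    system = AtomicSystem(("C",) * 5, positions)
    part = FragmentPartition.from_dict({f"f{i}": [i] for i in range(5)}, 5)
    com = positions
    values = np.zeros((5, 5))
    for a in range(5):
        for b in range(a + 1, 5):
            d = np.linalg.norm(com[a] - com[b])
            values[a, b] = values[b, a] = 2.7 * d**-6
    mi = MIMatrix(part.names, values)
    exponent, intercept, stderr, excluded = mi_distance_fit(mi, part, system)
    assert exponent == pytest.approx(-6.0, abs=1e-10)
    assert intercept == pytest.approx(np.log(2.7), abs=1e-10)
    assert stderr == pytest.approx(0.0, abs=1e-8)
    assert excluded == 0


def test_mi_fit_excludes_floor_and_requires_three_pairs():
    positions = np.array([[0, 0, 0], [10, 0, 0], [0, 17, 0]], dtype=float)
    system = AtomicSystem(("C",) * 3, positions)
    part = FragmentPartition.from_dict({f"f{i}": [i] for i in range(3)}, 3)
    values = np.zeros((3, 3))
    values[0, 1] = values[1, 0] = 1e-3
    mi = MIMatrix(part.names, values)
    with pytest.raises(ValueError, match="usable fragment pairs"):
        mi_distance_fit(mi, part, system)


def test_mi_fit_recovers_exponent_under_lognormal_noise():
    """Seeded multiplicative noise: slope stays within 3 stderr of -6."""
    rng = np.random.default_rng(42)
    n = 12
    positions = rng.uniform(0, 60, size=(n, 3))
    system = AtomicSystem(("C",) * n, positions)
    part = FragmentPartition.from_dict({f"f{i}": [i] for i in range(n)}, n)
    hits, slopes = 0, []
    for _ in range(100):
        values = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d = np.linalg.norm(positions[a] - positions[b])
                noise = np.exp(rng.normal(0.0, 0.3))
                values[a, b] = values[b, a] = d**-6 * noise
        mi = MIMatrix(part.names, values)
        slope, _, stderr, _ = mi_distance_fit(mi, part, system)
        slopes.append(slope)
        if abs(slope + 6.0) <= 3.0 * stderr:
            hits += 1
    assert hits >= 95
    assert np.mean(slopes) == pytest.approx(-6.0, abs=0.05)


def test_centrality_two_fragments_symmetric():
    mi = MIMatrix(("a", "b"), np.array([[0.0, 0.3], [0.3, 0.0]]))
    cent = eigenvector_centrality(mi)
    np.testing.assert_allclose(cent.s, [1 / np.sqrt(2)] * 2, atol=1e-12)
    assert cent.lambda_max == pytest.approx(0.3)
    assert np.sum(cent.s**2) == pytest.approx(1.0, abs=1e-12)


def test_centrality_matches_power_iteration(cluster_result):
    part = FragmentPartition.from_dict(
        {"a": [0, 1], "b": [2, 3], "c": [4, 5], "d": [6, 7]}, 8
    )
    mi = mi_matrix(cluster_result.covariances, part)
    cent = eigenvector_centrality(mi)
    v = np.ones(4)
    for _ in range(1000):
        v = mi.values @ v
        v /= np.linalg.norm(v)
    np.testing.assert_allclose(cent.s, v, atol=1e-10)


def test_centrality_rejects_zero_matrix():
    mi = MIMatrix(("a", "b"), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="all-zero"):
        eigenvector_centrality(mi)


def test_grossly_negative_mi_rejected():
    with pytest.raises(ValueError, match="negative"):
        MIMatrix(("a", "b"), np.array([[0.0, -1e-3], [-1e-3, 0.0]]))


def test_unphysical_covariance_rejected(cluster_result):
    part = FragmentPartition.single(8)
    cov = reduced_covariance(cluster_result.covariances, part, 0)
    bad = cov.__class__(cov.indices, cov.sigma_ladder, cov.sigma_quad * 0.5)
    with pytest.raises(ValueError, match="symplectic eigenvalue"):
        vn_entropy(bad)
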