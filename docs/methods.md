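# Methods

This note records the model, the numerical choices and the validation
strategy behind `sqmbd`, at the level of detail a maintainer or a careful
user needs. Everything below is computed by the test suite or by
`scripts/acceptance.py`; no number here is asserted without a test.

## Model and conventions

One isotropic quantum Drude oscillator (QDO) per atom, mass-weighted
coordinates, Hartree atomic units throughout (ħ = 1, Bohr, Hartree).
Composite index μ = 3A + i (0-based atom A, Cartesian i) orders all
3N-dimensional objects. Atoms are 0-based internally and 1-based in
user-facing reports.

The potential matrix has diagonal blocks ω_A²·I and off-diagonal blocks
ω_A ω_B √(α_A α_B) f_AB T_AB. Three range factors are exposed:

- `long_range` (the MBD Hamiltonian): f = 1 − g_rs,
- `short_range` (the screening step): f = g_rs,
- `bare`: f = 1 (used by the analytic-limit tests).

g_rs(r) = 1 − 1/(1 + exp(−a[r/(β R_vdW,AB) − 1])) with a = 6.0, β = 0.83
and R_vdW,AB the *sum* of the per-atom van der Waals radii. g_rs → 1 at
contact and → 0 at long range, so the Hamiltonian coupling is suppressed at
short range, where screening has already absorbed the interaction. The
damping radii are taken at the aim (pre-screening) stage in both places;
this follows the superscript the damping function is defined with, and the
choice is isolated behind the `r_vdw_damping` argument of
`assemble_potential` should anyone want the screened radii instead.

Inner sums of the Hamiltonian include the diagonal harmonic term
ω_A²‖q_A‖²/2 explicitly — the standard coupled-oscillator form, and the
only reading that reproduces the normal form and the zero-point energy
expression E_MBD = (ħ/2)[Σω̃ − 3Σω].

## Parametrization

Free-atom α⁰, C6⁰, R_vdW⁰ are packaged as a CSV for H, C, N, O, F, P, S,
Cl, Se, Br (the standard Tkatchenko–Scheffler reference set; provenance in
the file header). Per-atom η ratios are an *input*: the package is agnostic
about whether they come from Hirshfeld volumes or Mulliken populations.
The TS scaling C6 ← η²C6⁰, α ← ηα⁰, R_vdW ← η^⅓R_vdW⁰ leaves
ω = (4/3)C6/α² invariant, which is asserted to machine precision.

Self-consistent screening solves ᾱ(iω) = (A⁻¹ + T_sr)⁻¹ on a 15-node
Gauss–Legendre imaginary-frequency grid mapped to [0, ∞) with scale 0.6
a.u. (configurable; 15 nodes put the single-QDO Casimir–Polder closure
C6 = (3/4)ωα² at ~1e-10 relative error). Each atom's screened scalar is the
row-sum over partner blocks followed by (1/3)·trace — the published rsSCS
contraction, verified against an independently coded finite-difference
dense solve. Screened C6 comes from the Casimir–Polder quadrature, R_vdW
scales with the cube root of the polarizability ratio, and ω is recomputed
from the screened pair.

The short-range screening tensor is g_rs times the *oscillator-regularized*
(erf) dipole tensor, with frequency-dependent Gaussian widths
σ_A(iω) = (√(2/π) α_A(iω)/3)^⅓ combined in quadrature. The bare dipole
tensor in this role loses positive-definiteness for clusters with several
neighbors near 2 Bohr (negative isotropized polarizabilities — the
polarization catastrophe the regularization exists to prevent), so the
package uses the regularized form, which is also what production rsSCS
implementations do. The closed form

T_erf = [erf(z) − (2z/√π)e^(−z²)] T_bare + (4/√π) z³ e^(−z²) r̂r̂ᵀ/R³,
z = R/σ_AB

is validated against a central-difference Hessian of erf(R/σ)/R and has the
correct limits (bare tensor for z ≫ 1, finite 4/(3√π σ³)·I at contact).

## Diagonalization and the Bogoliubov map

`eigh` on the symmetric 3N×3N potential; eigenvalues are ω̃², modes sorted
ascending, and any non-positive eigenvalue raises a polarization-catastrophe
error naming the dominant atoms. Sign convention: each eigenvector's
largest-magnitude entry is made positive (ties broken at the lowest
composite index), so mode-resolved outputs are bit-reproducible.

X and Y are built directly from (O, ω, ω̃); Θ = X⁻¹Y by linear solve (never
an explicit inverse), symmetrized by averaging after asserting the
pre-symmetrization asymmetry is ≤ 1e-8. The symplectic identity
XXᵀ − YYᵀ = I holds at ~1e-15 on every generated system and ≤ 1e-9 is
enforced over a 50-system battery. Dense storage caps the system at 5000
atoms with a clear error beyond.

The unitary squeezing operator is never materialized: all ground-state
expectations are Gaussian and follow from (X, Y) or from the quadrature
covariances Cqq = Oᵀdiag(ħ/2ω̃)O, Cpp = Oᵀdiag(ħω̃/2)O. The ladder second
moments are ⟨a†a⟩ = YᵀY, ⟨aa†⟩ = XᵀX, ⟨aa⟩ = −XᵀY; number covariances use
the Wick contraction Cov(N_μ,N_ν) = ⟨aa⟩²_{μν} + (YᵀY)_{μν}(XᵀX)_{μν},
whose sign structure was confirmed against the Fock oracle before being
relied on (the diagonal of the normalized covariance is ≥ 1:
super-Poissonian, vacuum-squeezed statistics — also oracle-confirmed).

QDO charge and mass never appear separately: transition dipoles only need
ω_A√α_A (from α = Z²e²/mω²). Dipoles, like all mode-resolved observables,
use the screened (α, ω) stage, keeping them consistent with the screened
total energies.

## Fragment decomposition

For a partition {F_α}: U_α is the restricted kinetic+potential expectation
minus (3ħ/2)Σ_{A∈α}ω_A. The 3/2 factor (three Cartesian modes per atom) is
the only subtraction consistent with the −3Σω_A term in E_MBD and with the
exact sum rule Σ_α E_frag,α = E_MBD, which is enforced at 1e-10 Ha on every
fixture. V_αβ counts each unordered cross pair once; E_frag assigns half of
each pair energy to each partner — the unique split under which fragment
totals resum to E_MBD. Merging two fragments satisfies
U_merged = U_α + U_β + V_αβ exactly.

Mode resolution replaces Cqq by its rank-1 mode contribution
(ħ/2ω̃_k)v_kv_kᵀ; the spectrum sums back to V_αβ at 1e-10. Modes are
labeled bonding/antibonding/negligible by a symmetric threshold ε
(default 1e-8 Ha) on their contribution.

## Quantum information

Reduced states of a Gaussian vacuum are obtained by index restriction of
the covariance — no state vectors. Two equivalent routes (quadrature
restriction of Cqq/Cpp; ladder-moment restriction of (X,Y) mapped through
the ladder map) are both implemented and cross-checked at 1e-10.
q–p cross covariances vanish identically for this real Hamiltonian and are
asserted ≤ 1e-12, not assumed.

Entropy uses the symplectic (Williamson) spectrum of the quadrature
covariance: for block-diagonal σ = diag(Q, P) the eigenvalues are
√spec(Q^½PQ^½) (a symmetric eigenproblem; a general Ωσ fallback exists for
non-zero cross blocks). S = Σ[(ν+½)ln(ν+½) − (ν−½)ln(ν−½)] in nats;
ν < ½ − 1e-8 is an error (unphysical covariance), ν within 1e-12 of ½
contributes zero. Purity identities (S = 0 for the whole system,
S[ρ_α] = S[ρ_complement]) hold at 1e-8 and anchor the convention.

The MI distance fit is ordinary least squares of ln MI on ln d (d =
center-of-mass distance, standard atomic masses from gemmi), excluding
pairs below a 1e-14-nat floor and requiring ≥ 3 usable pairs. Eigenvector
centrality is the leading eigenvector of the MI matrix, Perron-normalized
with Σs² = 1; a disconnected MI graph warns and reflects the dominant
component.

## Fock-space oracle

The oracle represents H in the truncated product number basis using exact
single-mode matrix elements of q², p² (band ±2), so the truncation is a
true projection P H P and the ground energy is variational in nmax — this
matters: building q² as the square of the truncated q breaks monotonicity
at the 1e-7 level. Cross-mode terms factorize over modes and are exact
products of truncated single-mode operators. Lowest eigenpairs by sparse
Lanczos; reduced density matrices by explicit partial trace, with
subsystem entropies taken from the Gram matrix on the smaller side of the
bipartition (same Schmidt spectrum, avoids materializing large RDMs).

Convergence protocol: accept nmax when successive ground energies differ
by < 1e-9 Ha. The basis dimension is capped at 3e6, which in practice
means dimers at nmax ≤ 10 and trimers at nmax ≤ 4; at the couplings of the
test fixtures (occupations ≲ 1e-3) these reproduce the Gaussian results to
1e-7 or better, comfortably inside the stated oracle tolerances (1e-6 Ha
energies, 1e-7 occupations/covariances, 1e-5 nats entropies).

Transition-dipole comparisons are made per degenerate frequency group
(summed |μ̄|² within a group), since individual dipoles inside a
degenerate subspace are basis-dependent.

## Synthetic systems

The generator emulates the *scale* of molecular problems — interatomic
distances ≥ 2 Bohr, organic element mix (H/C/N/O/S at 50/30/10/8/2%),
η ∈ [0.7, 1.1] — in four geometries: random clusters (rejection sampling,
bounded at 1e5 tries), helix-like chains, dimer distance scans and
two-blob complexes with a 2-fragment partition. Randomness is the
counter-based Philox generator, so fixtures are bit-reproducible across
platforms for a given seed. What these fixtures do *not* emulate: covalent
bonding networks, realistic protein geometry, or DFT-derived η ratios —
passing tests demonstrate the correctness of the machinery, not the
chemical accuracy of predictions on real structures, which additionally
depends on the quality of the supplied η.

Problem sizes used by the default verification runs: 50 systems of 2–30
atoms for the symplectic battery, dimers/trimers for the oracle, 8–12-atom
two-blob clusters for the sum rules and quantum-information checks, and
100 noise replicates for the distance-exponent recovery. These sizes were
chosen as the smallest at which every identity is non-trivially exercised.

## Known limitations

- Dipole–dipole coupling only; no higher multipoles, no periodic boundary
  conditions, no nuclear gradients.
- The MBD@rsSCS parametrization is known to degrade for ionic and hybrid
  metal–organic systems; nothing here addresses that.
- mmCIF and trajectory formats are not parsed; PDB reading follows the
  v3.3 fixed-column dialect, first MODEL, altloc 'A' or blank.
- The oracle is exact diagonalization and cannot exceed three atoms; the
  Gaussian machinery itself is exact for quadratic Hamiltonians, so the
  small-N validation carries over structurally to large N.
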