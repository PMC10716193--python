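# sqmbd — second-quantized many-body dispersion analysis

`sqmbd` computes many-body dispersion (MBD) interactions for molecular
systems — proteins, supramolecular complexes, synthetic clusters — and
analyzes the resulting correlated ground state with the tools of
second quantization and continuous-variable quantum information.

It is aimed at people studying non-covalent interactions who want more than
a single dispersion energy: which residues hold a protein together, which
collective electronic modes bind a host–guest complex, how strongly
electronic charge fluctuations on one fragment are correlated with another.

## The model

Each atom *A* carries a quantum Drude oscillator (QDO): a 3-D isotropic
charged harmonic oscillator with frequency ω<sub>A</sub> and static
polarizability α<sub>A</sub>. In mass-weighted coordinates the coupled
Hamiltonian is

```
H = 1/2 Σ_A ||p_A||²  +  1/2 Σ_{A,B} q_A · V_AB · q_B
V_AA = ω_A² I,   V_AB = ω_A ω_B √(α_A α_B) (1 − g_rs) T_AB
```

with T<sub>AB</sub> the dipole–dipole tensor and g<sub>rs</sub> a Fermi-type
range-separation factor (a = 6.0, β = 0.83) that suppresses the coupling at
short range. Per-atom parameters come from free-atom reference values scaled
by user-supplied atom-in-molecule ratios η (Tkatchenko–Scheffler:
C6 ← η²C6⁰, α ← ηα⁰, R<sub>vdW</sub> ← η^⅓R<sub>vdW</sub>⁰) and then
dressed by range-separated self-consistent screening (rsSCS) through the
short-range part of the oscillator-regularized dipole tensor.

Diagonalizing V gives collective plasmon-like modes ω̃<sub>k</sub> and the
dispersion energy as a zero-point shift,

```
E_MBD = (ħ/2) [ Σ_k ω̃_k − 3 Σ_A ω_A ].
```

The second-quantized layer connects atomic and collective ladder operators
through a multimodal Bogoliubov transformation b = X a + Y a†, with
X = ½[D̃^½ O D^−½ + D̃^−½ O D^½] and Y its minus-sign partner. The
collective ground state is then a Gaussian squeezed vacuum
exp(a†·Θ·a†/2)|0⟩/det(XXᵀ)^¼ with Θ = X⁻¹Y, and every observable reduces to
second moments:

- **excitation statistics**: ⟨N⟩ = diag(YᵀY) and Wick-contracted
  number covariances;
- **fragment energies**: internal (U), mutual (V) and total per-fragment
  contributions that sum exactly to E_MBD, with per-mode resolution into
  "bonding" (negative) and "antibonding" (positive) contributions;
- **transition dipoles**: μ<sub>k</sub> ∝ ω_A√α_A O<sub>kμ</sub>(ħ/2ω̃_k)^½,
  satisfying the static polarizability sum rule
  Σ_k (2/ħω̃_k) μ_k μ_kᵀ = Bᵀ V⁻¹ B;
- **quantum information**: von Neumann entropies from symplectic spectra of
  reduced covariances, pairwise mutual information
  MI<sub>αβ</sub> = S[ρ_α] + S[ρ_β] − S[ρ_αβ], its distance scaling
  exponent, and eigenvector centrality of the MI graph.

A truncated-Fock exact-diagonalization oracle (`sqmbd.fock`) provides an
independent brute-force ground truth for all of this on systems of up to
three atoms, and a seeded generator (`sqmbd.fixtures`) produces synthetic
clusters so nothing requires external data.

## Worked example

```python
import numpy as np
from sqmbd import FixtureSpec, generate, run_mbd, fragment_energy_table, \
    mutual_information
from sqmbd.fragments import mode_resolved_interaction, classify_modes
from sqmbd.observables import transition_dipoles
from sqmbd.units import HARTREE_TO_EV, AU_TO_DEBYE

system, part = generate(FixtureSpec(n_atoms=10, geometry="two_blob", seed=42))
result = run_mbd(system)                      # TS scaling + rsSCS + modes
print(f"E_MBD = {result.e_mbd:.8f} Ha = {result.e_mbd*HARTREE_TO_EV:.5f} eV")

table = fragment_energy_table(result.covariances, result.potential, part)
spec = mode_resolved_interaction(result.modes, result.potential, part, 0, 1)
td = transition_dipoles(result.modes, result.params)
k = int(np.argmax(td.iso_modulus_sq()))
print(f"V(blob1,blob2) = {table.v[0,1]*HARTREE_TO_EV:+.5f} eV")
print(f"strongest mode k={k}: "
      f"|mu| = {np.sqrt(td.iso_modulus_sq(k))*AU_TO_DEBYE:.3f} D")
print(f"MI(blob1,blob2) = "
      f"{mutual_information(result.covariances, part, 0, 1):.6f} nats")
```

prints

```
E_MBD = -0.00320574 Ha = -0.08723 eV
V(blob1,blob2) = -0.02339 eV
strongest mode k=23: |mu| = 3.886 D
MI(blob1,blob2) = 0.009229 nats
```

The two blobs attract (V < 0, about a quarter of the total dispersion
energy here), the strongest collective mode carries a transition dipole of
a few Debye — the same order as organic chromophores — and the
mutual-information entry quantifies the quantum correlation between the
blobs' charge-density fluctuations, in nats.

The same analyses are available from the shell via the `sqmbd` CLI
(`energy`, `fragments`, `modes`, `dipoles`, `qinfo`, `fixture`, `oracle`);
run `sqmbd --help`.

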