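# gvpt2

Anharmonic vibrational spectroscopy for semirigid molecules: second-order
vibrational perturbation theory (VPT2) with **automated, intensity-aware
identification and treatment of Fermi and Darling–Dennison resonances**
(the generalized scheme, GVPT2), from a harmonic + quartic force field to
anharmonic energies, transition moments, and broadened IR/VCD spectra.

It is written for computational spectroscopists who already have a harmonic
model and semidiagonal cubic/quartic force constants (e.g. from numerical
differentiation of quantum-chemistry Hessians) and need reliable anharmonic
band positions *and intensities* — in particular for chiroptical
spectroscopies (VCD), whose weak signals are exquisitely sensitive to
untreated resonances.

## The model

With dimensionless normal coordinates, harmonic wavenumbers ω and cubic /
semidiagonal quartic force constants k<sub>ijk</sub>, K<sub>ijkl</sub>
(all in cm⁻¹), VPT2 gives vibrational energies

    E(v) = ε₀ + Σᵢ ωᵢ(vᵢ+½) + Σ_{i≤j} χᵢⱼ (vᵢ+½)(vⱼ+½)

where the anharmonicity matrix χ collects quartic terms, squares of cubic
constants over frequency-difference denominators, and Coriolis
contributions.  Those denominators are the problem: near-degeneracies
ωᵢ ≈ 2ωⱼ (type-I Fermi), ωᵢ ≈ ωⱼ+ω_k (type II), ωᵢ ≈ ωⱼ (1–1
Darling–Dennison) make individual terms — and, even more dramatically, the
transition moments — blow up.

The package automates the standard three-step remedy:

1. **Identify** resonances: an energy-window prefilter over all candidate
   triads/pairs, then per-candidate tests.  Energy-based tests (Martin's
   κ = φ⁴/(256Δ³) for overtone partners, φ⁴/(64Δ³) for combination partners;
   the effective Darling–Dennison coupling |W|) are complemented by
   intensity-oriented tests on the perturbative wave-function coefficients
   (`R12COEF`, `R11COEF`), accepted with a logical OR.  Default protocol:
   `R12MART`/`R12COEF` (Δ¹⁻²=200, K¹⁻²=1.0, K_I¹⁻²=0.1),
   `R11HRS`/`R11COEF` (Δ¹⁻¹=100, K¹⁻¹=10, K_I¹⁻¹=0.3),
   `R22HRS` (Δ²⁻²=100, K²⁻²=20).
2. **Deperturb** (DVPT2): every term whose denominator matches an accepted
   resonance is removed from the χ sums and from the transition-moment
   expressions — term by term, with a ledger.
3. **Correct variationally** (GVPT2): accepted resonances connect states
   into *polyads* (connected components of the resonance graph); each polyad
   block — deperturbed energies on the diagonal, couplings off-diagonal — is
   diagonalized, and the deperturbed moments are projected onto the
   variational states by the eigenvectors.

A hybrid degeneracy-corrected regularization (HDCPT2-style) is available for
the χ matrix and is always applied to the internal denominators of
Darling–Dennison couplings, so those stay finite for any input.

Every formula is validated in-repo against a brute-force oracle that
diagonalizes the same quartic Hamiltonian in a dense product
harmonic-oscillator basis (≤ 3 modes) — energies *and* moments.

## Worked example

`examples/02_gvpt2_vs_oracle.py` builds a two-mode system in strong type-I
Fermi resonance (gap Δ = ω₂ − 2ω₁ = 2.6 cm⁻¹, cubic coupling φ = 38 cm⁻¹ —
the methyloxirane neat-liquid scenario) and compares every treatment level
with exact diagonalization:

```
identified: FERMI_I (2, 1, 1), Martin index 463.4 cm-1

state       VPT2     DVPT2     GVPT2     exact   (cm-1)
2v1      1461.82   1496.53   1488.59   1488.59
v2       1534.68   1499.97   1507.90   1507.91
```

Plain VPT2 misplaces both bands by ~27 cm⁻¹ (the resonant denominator);
deperturbation removes the divergence but ignores the real coupling; the
2×2 variational step (off-diagonal element φ/4 = 9.5 cm⁻¹) recovers the
exact energies to a few hundredths of a cm⁻¹.  The other examples cover
automatic identification on a 24-mode synthetic molecule
(`01_resonance_analysis.py`), a full IR+VCD simulation with stick tables
and Lorentzian bandshapes (`03_ir_vcd_spectrum.py`), and the Duschinsky
mode-correspondence gate for hybrid force fields (`04_duschinsky_gate.py`).

A thin CLI mirrors the library:

```bash
gvpt2 synth --seed 1 --n-modes 24 --plant FERMI_I:2.6:38 --out mol.json
gvpt2 resonances mol.json
gvpt2 spectrum mol.json --kind vcd --shape lorentzian --hwhm 2
gvpt2 duschinsky-check high.json low.json
```

## Layout

| module | contents |
| --- | --- |
| `gvpt2.model`, `gvpt2.io`, `gvpt2.states` | domain types, validation, masking, versioned-JSON VibData I/O |
| `gvpt2.chi` | χ matrix, ZPE, VPT2/DVPT2/HDCPT2 state energies |
| `gvpt2.resonance` | candidate enumeration, all identification schemes, ResonanceDB |
| `gvpt2.polyad`, `gvpt2.variational` | polyad graphs, block diagonalization, state assignment |
| `gvpt2.moments` | VPT2/DVPT2 transition moments, GVPT2 projection, pseudoeigenvectors |
| `gvpt2.spectra` | stick spectra, Lorentzian/Gaussian broadening, IR/VCD conversions |
| `gvpt2.duschinsky` | mode-correspondence gate between electronic-structure levels |
| `gvpt2.synthetic`, `gvpt2.oracle` | planted-resonance generator, dense variational oracle |
| `gvpt2.pipeline`, `gvpt2.cli` | end-to-end runs, YAML config, artifacts |

See `docs/methods.md` for the working equations, numerical choices, and
known limitations.
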