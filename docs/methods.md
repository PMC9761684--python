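# Methods

## Scope and Hamiltonian

The package treats the J = 0 vibrational problem of a semirigid molecule in
dimensionless normal coordinates q with conjugate momenta p:

    H = 1/2 Σᵢ ωᵢ (pᵢ² + qᵢ²)
      + 1/6 Σ_{ijk} k_ijk qᵢ qⱼ q_k
      + 1/24 Σ_{ijkl} K_ijkl qᵢ qⱼ q_k q_l
      + (Coriolis coupling through ζ and B^eq)

with all energies in cm⁻¹.  The mass-dependent Watson term is dropped: it
cancels in transition energies, so absolute zero-point energies reported by
the package exclude it (documented limitation, not a guess at its value).
Force constants are fully symmetric under index permutation and stored once
per sorted index tuple.  Quartic constants are restricted to semidiagonal
patterns (at most three distinct indices) unless `has_full_quartic` is set:
two-step numerical differentiation of Hessians yields only K_{ab,cc}, and an
unavailable off-semidiagonal element is an error, never a silent zero.
Because 11–11 Darling–Dennison couplings need the off-semidiagonal
K_{ijkl}, they are excluded from the automatic treatment; 2-quanta pairs are
restricted to overtone–overtone and overtone–combination patterns.

## Energies

The anharmonicity matrix χ follows the standard second-order results:

* χᵢᵢ = K_iiii/16 − Σⱼ (k_iij²/16)·(8ωᵢ²−3ωⱼ²)/(ωⱼ(4ωᵢ²−ωⱼ²)),
  with the j = i term reducing to 5k_iii²/(48ωᵢ);
* χᵢⱼ = K_iijj/4 − Σ_k k_iik k_jjk/(4ω_k)
  − Σ_k (k_ijk²/8)·[1/(ωᵢ+ωⱼ+ω_k) + 1/(ωⱼ+ω_k−ωᵢ) + 1/(ωᵢ+ω_k−ωⱼ)
  − 1/(ωᵢ+ωⱼ−ω_k)]
  + Σ_axis B^eq(ζᵢⱼ)²(ωᵢ/ωⱼ + ωⱼ/ωᵢ);
* ε₀ from the same perturbative treatment at v = 0 (no Coriolis ZPE term).

Each difference denominator is tagged with its Fermi triad, so the
deperturbed variant (DVPT2) removes exactly the terms whose triad is in the
resonance database — per denominator occurrence, not per χ element — and
records them.  State energies relative to the ground state are

    E(v) − E(0) = Σᵢ vᵢωᵢ + Σ_{i≤j} χᵢⱼ[(vᵢ+½)(vⱼ+½) − ¼].

The implementation was cross-validated against the in-repo variational
oracle: for two- and three-mode systems with couplings of a few cm⁻¹ the
fundamentals agree to < 0.01 cm⁻¹ and the absolute ZPE to < 0.01 cm⁻¹;
at a 30 cm⁻¹ coupling 40 cm⁻¹ off resonance the residual (third-order)
error is ≈ 0.1–0.3 cm⁻¹.

### HDCPT2-style regularization

A resonance-prone term x = λ²·sgn/Δ (λ² the coupling-squared prefactor) is
replaced by

    Λ·(λ² sgn/Δ) + (1−Λ)·(λ² sgn·Δ/(Δ² + 4λ²)),   Λ = 1 − exp(−Δ²/(αλ²)),

with α = 1 by default (exposed in `hdcpt2_term`).  The blend is finite and
continuous for every (λ, Δ), odd in Δ, bounded by λ/4, and converges to the
plain term with relative deviation e^(−Δ²/λ²) away from resonance.  The
specific switching function is this package's own pinned choice, documented
here precisely so results are reproducible; it is used (a) for the whole χ
matrix in `HDCPT2` mode and (b) always for the internal Fermi-like
denominators inside Darling–Dennison couplings and second-order
coefficients, which is what keeps every identification index finite.

## Resonance identification

Candidates are prefiltered by energy windows (|ωᵢ−ωⱼ−ω_k| ≤ Δ¹⁻², etc.).
Fermi triads exclude i ∈ {j,k} (ωᵢ ≈ ωᵢ+ω_k would need ω_k ≈ 0); for a
72-mode molecule this gives exactly 184 032 triads, 2556 one–one pairs, and
3 451 878 two-quanta pairs.

Scores, all monotone in |coupling| and 1/|Δ|:

| scheme | quantity | default threshold |
| --- | --- | --- |
| R12MART | φ⁴/(256Δ³) type I, φ⁴/(64Δ³) type II (cm⁻¹) | 1.0 |
| R12CVPT | φ/(2√2 Δ) | 0.1–0.5 band |
| R12WFRQ | Martin index / Δ² (weighting exponent configurable) | — |
| R12COEF | first-order coefficient: φ/(4Δ) type I, φ/(2√2 Δ) type II | 0.1 |
| R11HRS / R22HRS | Van Vleck coupling |W| (cm⁻¹) | 10 / 20 |
| R11WFRQ | |W|/Δ² | — |
| R11COEF | second-order coefficient of the partner fundamental | 0.3 |

Notes on conventions that vary across implementations:

* The Martin prefactors (256 vs 64) follow the original convention and
  were checked against literature benchmark values for the strong
  methyloxirane resonance (index 0.86 ≈ 0.8
  at φ=33, Δ=17.5; ratio > 500 after the solvent shift to φ=38, Δ=2.6) —
  and the acceptance ratio is prefactor-independent anyway.
* R12CVPT is implemented as the uniform first-order form for both triad
  types; the factor it differs from R12COEF for overtone partners then
  comes out as √2, which this package derives from the harmonic-oscillator
  matrix elements rather than asserting.
* R12WFRQ divides Martin's index by Δ² by analogy with the explicitly
  defined R11WFRQ rule; the exponent is a config knob (`wfrq_power`).

DD couplings W are not transcribed closed forms: they are computed
numerically as Van Vleck second-order effective-Hamiltonian elements,
⟨a|H₂|b⟩ + ½Σ_u⟨a|H₁|u⟩⟨u|H₁|b⟩[1/(E_a−E_u)+1/(E_b−E_u)], over sparse
harmonic-oscillator algebra.  R11COEF likewise is the literal second-order
RSPT coefficient.  Both were checked against λ-scaled dense
diagonalizations (3-digit agreement in the perturbative limit).

Acceptance is energy-test OR intensity-test; an exact degeneracy (Δ = 0)
short-circuits denominator-based schemes to acceptance.  The database
records all computed indices and the triggering scheme per entry and can be
amended by the user (add/remove).  First- and second-order coefficients are
cached at build time and reused by the pseudoeigenvectors.

## Variational step and assignment

Polyads are the connected components (networkx) of the graph whose edges
are accepted resonances over the N + N(N+1)/2 state space (fundamentals +
2-quanta states).  Per polyad, a symmetric matrix with DVPT2 energies on
the diagonal and first-order Fermi elements (φ/4 or φ/(2√2)) /
Darling–Dennison W off-diagonal is diagonalized (`numpy.linalg.eigh`).
Eigenvector phases are fixed by making the largest-magnitude component
positive, so moment projection is reproducible.  Orthonormality (10⁻¹⁰) and
trace conservation (10⁻⁸ cm⁻¹) are asserted on every block.  A global
sparse-matrix mode is retained behind a flag for cross-validation only.
Each eigenstate is labeled by the basis state with the largest squared
component; exact ties break toward the lower-energy basis state and are
logged.

## Transition moments

A property surface carries equilibrium values, first/second derivatives and
semidiagonal third derivatives over q (S = +1, e.g. electric dipole) or p
(S = −1, e.g. magnetic dipole), with prefactors (s₀,s₁,s₂,s₃) defaulting to
a plain Taylor series (1, 1, ½, 1/6) and overridable per property to match
other conventions.  For S = −1 the third-derivative indices do not fully
permute; only stored P_{i,jj} patterns are used, and missing blocks drop
with a per-surface completeness warning.

Moments are assembled as explicit second-order RSPT sums (see the module
docstring of `gvpt2.moments` for the term list) using sparse
harmonic-oscillator algebra with complex amplitudes, so momentum-type
operators keep their 90° phase and rotatory strengths are simply
R = Im(μ·m̄).  This design makes deperturbation literal: every energy
denominator appears explicitly, terms whose state pair is an accepted
resonance are dropped and ledgered (this single mechanism covers both the
DVPT2 scheme and the modified resonant-form expressions needed when a
Darling–Dennison resonance touches a fundamental), and a near-singular
denominator (< 10⁻⁶ cm⁻¹) that is *not* covered by the database raises a
hard error pointing at the resonance configuration — moments are where
untreated resonances produce unbounded artifacts, so silent smoothing is
deliberately not offered there.  Cost scales with the number of stored
force constants, not with the cube of the mode count, which fits the sparse
fields this package targets; a dense 100+-mode force field would call for
transcribed closed forms instead (known limitation).

Validation against the oracle: fundamentals to ~10⁻⁵ relative, 2-quanta
bands to ~0.2% at weak coupling, both property types.

GVPT2 moments are the eigenvector-weighted combinations of the deperturbed
moments; orthonormality conserves the polyad sum of squared moment norms to
10⁻¹⁰ relative.  Pseudoeigenvectors (Cartesian effective modes) weight the
normal-mode columns with the cached perturbative coefficients — second-order
(1–1) coefficients for fundamentals, first-order (Fermi) coefficients for
2-quanta states — excluding accepted resonances; the reverse coefficient
c_{j←i} ≈ −c_{i←j} approximation (exact up to the slight asymmetry of RSPT
internal denominators) is used for pairs cached in one direction.

## Spectra

Stick strengths: dipole strength D = |⟨0|μ|f⟩|² in 10⁻⁴⁰ esu²cm²
(derivatives in e·a₀, conversion 2.541746×10⁻¹⁸ esu·cm), rotatory strength
R = Im(⟨0|μ|f⟩·⟨f|m|0⟩) in 10⁻⁴⁴ esu²cm² (magnetic derivatives in Bohr
magnetons, 9.274010×10⁻²¹ esu·cm).  Molar absorptivity uses
D = 9.184×10⁻³⁹ ∫(ε/ν̃)dν̃ and Δε uses R = 2.296×10⁻³⁹ ∫(Δε/ν̃)dν̃; the
constants live in one table in `gvpt2.spectra` with unit tests.
Broadening kernels (Lorentzian/Gaussian) are unit-area and parameterized by
HWHM; the default grid step of 0.2 cm⁻¹ resolves the narrowest HWHM in
common use (2 cm⁻¹).  Shifts commute with convolution (tested), so whether
a region shift is applied before or after broadening is immaterial.

## Duschinsky gate

For hybrid schemes, J = (L^H)ᵀL^L after an internal mass-weighted Kabsch
(Eckart) superposition of the geometries; the check passes when every
row/column of J has exactly one squared element > 0.9.  K is computed and
reported with a configurable warning threshold but never used for
pass/fail: any true geometric difference already contaminates J.

## Synthetic systems and the oracle

The generator emulates a quartic-force-field dataset for a mid-size
semirigid molecule.  Defaults: 24 modes (a 10-atom molecule), background
frequencies uniform on 400–1800 cm⁻¹, zero-mean background cubic and
diagonal quartic constants of scale 5 cm⁻¹ (≈ 2N random semidiagonal
cubics), electric-dipole first derivatives of scale 0.05 e·a₀ with second
and third derivatives 10× and 100× smaller, magnetic first derivatives of
5×10⁻³ μ_B.  Planted features realize their gaps exactly by construction
(ωᵢ = 2ωⱼ + Δ etc.) and their couplings through the corresponding constant
(cubic φ for Fermi; K_iiij = 8W for a 1–1 DD pair, which makes the
first-order Van Vleck coupling exactly W).  Same seed ⇒ byte-identical
bundle.  What the generator does **not** emulate: symmetry selection rules,
correlated force-constant structure, mode-dense CH-stretch manifolds, and
solvent effects — so passing detection suites demonstrates the machinery on
isolated, well-separated resonances, not performance on pathological
real-molecule topologies.

The oracle diagonalizes exactly the same truncated quartic polynomial
Hamiltonian in a dense product basis (≤ 3 modes, ≤ 20 quanta per mode,
convergence guarded by the ground-state shift on basis increment,
0.01 cm⁻¹), with property operators expanded to the same Taylor order; by
construction oracle-vs-VPT2 differences measure perturbation error only.
Coriolis terms are excluded from oracle fixtures (ζ = 0); the ζ-dependent
χ term is unit-tested against its closed form instead.

## Problem sizes

Test-suite and acceptance computations are sized for a laptop-class single
core: 2–3-mode oracles (≤ 441–9261 basis functions), 8–24-mode synthetic
bundles, 50-seed detection ensembles, and 72-mode candidate enumerations;
the full suite runs in about a minute.

## Known limitations

* 3-quanta states, their moments, and 1–3 resonances are out of scope; hot
  bands are ignored throughout.
* 11–11 DD resonances are ignored by default (off-semidiagonal quartics).
* Linear molecules are supported by the data model (3N−5) but exercised
  only at unit level.
* Raman/ROA invariant combinations are an extension point: the generic
  tensor plumbing (any `n_components`) works, but no published-convention
  prefactors are claimed.
* Absolute ZPE excludes the Watson mass-dependent term and the Coriolis
  ZPE contribution.
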