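"""Brute-force variational reference for small systems.

Diagonalizes the (J = 0) vibrational Hamiltonian -- harmonic part plus the
cubic/quartic potential actually stored in the bundle -- in a dense product
harmonic-oscillator basis, and evaluates transition moments of the
Taylor-expanded property operators between the numerical eigenvectors.

The potential is the truncated quartic polynomial itself, i.e. exactly the
operator the perturbative treatment sees, so any discrepancy between the
oracle and VPT2/GVPT2 measures perturbation error only.  Coriolis terms are
not included (fixtures for oracle comparisons use zeta = 0; the
zeta-dependent chi contributions are unit-tested against their closed form
instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .model import PropertySurface, VibData
from .moments import property_components
from .states import VibState


class ConvergenceError(RuntimeError):
    pass


MAX_MODES = 3
MAX_QUANTA = 20


def _q_matrix(nmax: int) -> np.ndarray:
    n = nmax + 1
    m = np.zeros((n, n))
    for v in range(n - 1):
        m[v, v + 1] = m[v + 1, v] = math.sqrt((v + 1) / 2.0)
    return m


def _p_matrix(nmax: int) -> np.ndarray:
    n = nmax + 1
    m = np.zeros((n, n), dtype=complex)
    for v in range(n - 1):
        m[v + 1, v] = 1j * math.sqrt((v + 1) / 2.0)
        m[v, v + 1] = -1j * math.sqrt((v + 1) / 2.0)
    return m


def _kron_all(mats) -> np.ndarray:
    return reduce(np.kron, mats)


@dataclass
class OracleResult:
    energies: dict[VibState, float]          # relative to the oracle ground state
    zpe: float                               # absolute ground-state energy, cm-1
    moments: dict[tuple[str, VibState], np.ndarray]   # (property, state) -> components
    basis_quanta: int
    ground_shift_on_increment: float

    def energy(self, state: VibState) -> float:
        return self.energies[state]


def variational_oracle(
    bundle: VibData,
    n_max_quanta: int = 12,
    states: list[VibState] | None = None,
    convergence_tol: float = 0.01,
) -> OracleResult:
    """Exact (dense-basis) energies and transition moments for <= 3 modes.

    ``states`` defaults to all fundamentals, first overtones and 1+1
    combinations.  Eigenstates are matched to harmonic labels by maximum
    squared overlap with the corresponding basis vector.  Raises
    ``ConvergenceError`` when enlarging the basis by one quantum per mode
    still shifts the ground-state energy by more than ``convergence_tol``.
    """
    n = bundle.n_modes
    if n > MAX_MODES:
        raise ValueError(f"oracle limited to {MAX_MODES} modes, got {n}")
    if not 2 <= n_max_quanta <= MAX_QUANTA:
        raise ValueError(f"n_max_quanta must be in [2, {MAX_QUANTA}]")

    e_small, _, _ = _diagonalize(bundle, n_max_quanta - 1)
    e_full, vals, vecs = _diagonalize(bundle, n_max_quanta)
    shift = abs(e_full - e_small)
    if shift > convergence_tol:
        raise ConvergenceError(
            f"ground-state energy moved {shift:.4f} cm-1 on basis increment; "
            "increase n_max_quanta"
        )

    if states is None:
        states = [VibState.fundamental(i) for i in range(1, n + 1)]
        states += [VibState.overtone(i) for i in range(1, n + 1)]
        states += [VibState.combination(i, j)
                   for i in range(1, n + 1) for j in range(i + 1, n + 1)]

    dims = [n_max_quanta + 1] * n
    size = int(np.prod(dims))

    def basis_index(state: VibState) -> int:
        q = state.as_dict()
        idx = 0
        for m in range(1, n + 1):
            idx = idx * dims[m - 1] + q.get(m, 0)
        return idx

    # assign: for each target state pick the eigenvector with max overlap
    energies: dict[VibState, float] = {}
    columns: dict[VibState, int] = {}
    ground_col = int(np.argmax(np.abs(vecs[basis_index(VibState.ground()), :])))
    e0 = vals[ground_col]
    for s in states:
        row = basis_index(s)
        col = int(np.argmax(np.abs(vecs[row, :])))
        columns[s] = col
        energies[s] = float(vals[col] - e0)

    moments: dict[tuple[str, VibState], np.ndarray] = {}
    for surf in bundle.properties:
        ops = _property_matrices(surf, n, n_max_quanta)
        g = vecs[:, ground_col]
        for s in states:
            f = vecs[:, columns[s]]
            comp = np.array([g.conj() @ (op @ f) for op in ops])
            moments[(surf.name, s)] = comp
    return OracleResult(
        energies=energies,
        zpe=float(e0),
        moments=moments,
        basis_quanta=n_max_quanta,
        ground_shift_on_increment=shift,
    )


def _diagonalize(bundle: VibData, nmax: int):
    n = bundle.n_modes
    w = bundle.harmonic.omega
    dims = [nmax + 1] * n
    q1 = _q_matrix(nmax)
    eye = np.eye(nmax + 1)

    def mode_ops(powers: dict[int, int]) -> np.ndarray:
        mats = []
        for m in range(1, n + 1):
            p = powers.get(m, 0)
            mats.append(np.linalg.matrix_power(q1, p) if p else eye)
        return _kron_all(mats)

    h = np.zeros((int(np.prod(dims)), int(np.prod(dims))))
    # harmonic part
    for m in range(1, n + 1):
        nm = np.diag(np.arange(nmax + 1) + 0.5) * w[m - 1]
        mats = [nm if mm == m else eye for mm in range(1, n + 1)]
        h += _kron_all(mats)
    # cubic
    from .operators import cubic_operator, quartic_operator
    for mono in cubic_operator(bundle.field) + quartic_operator(bundle.field):
        h += float(mono.coeff.real if isinstance(mono.coeff, complex) else mono.coeff) \
            * mode_ops(dict(mono.factors))
    vals, vecs = np.linalg.eigh(h)
    return float(vals[0]), vals, vecs


def _property_matrices(surf: PropertySurface, n: int, nmax: int) -> list[np.ndarray]:
    """Dense matrices of the Taylor-expanded property operator, one per
    component, in the same product basis as the Hamiltonian."""
    xi = _q_matrix(nmax) if surf.S == +1 else _p_matrix(nmax)
    eye = np.eye(nmax + 1)
    dtype = float if surf.S == +1 else complex

    def mode_ops(powers: dict[int, int]) -> np.ndarray:
        mats = []
        for m in range(1, n + 1):
            p = powers.get(m, 0)
            mats.append(np.linalg.matrix_power(xi, p) if p else eye.astype(dtype))
        return _kron_all(mats)

    size = (nmax + 1) ** n
    out = [np.zeros((size, size), dtype=complex) for _ in range(surf.n_components)]
    for coeff_vec, powers in property_components(surf, n):
        block = mode_ops(powers)
        for c in range(surf.n_components):
            if coeff_vec[c]:
                out[c] = out[c] + coeff_vec[c] * block
    return out
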