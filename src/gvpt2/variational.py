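"""The GVPT2 variational step.

Each polyad yields a small symmetric matrix with the deperturbed (DVPT2)
energies on the diagonal and the accepted Fermi / Darling-Dennison couplings
off-diagonal.  Its eigenvalues are the GVPT2 energies; the orthonormal
eigenvectors define the transformation from DVPT2 to GVPT2 states, reused to
project the deperturbed transition moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np

from .polyad import Polyad, PolyadDB
from .states import VibState

logger = logging.getLogger("gvpt2")

ORTHO_TOL = 1e-10
TRACE_TOL = 1e-8


@dataclass
class PolyadSolution:
    states: list[VibState]            # DVPT2 basis states of the block
    matrix: np.ndarray                # symmetric block (cm-1)
    eigenvalues: np.ndarray           # ascending GVPT2 energies (cm-1)
    eigenvectors: np.ndarray          # columns; phase-fixed


@dataclass
class GVPT2Result:
    solutions: list[PolyadSolution]
    passthrough: dict[VibState, float]       # singleton states, unchanged
    #: (polyad index, eigenvector column) -> (dominant DVPT2 state, overlap)
    assignment: dict[tuple[int, int], tuple[VibState, float]] = dfield(
        default_factory=dict)

    def energy_of(self, state: VibState) -> float:
        """GVPT2 energy of the variational state best representing ``state``.

        For a state inside a polyad this is the eigenvalue of the eigenvector
        with the largest squared component on it; singletons pass through.
        """
        if state in self.passthrough:
            return self.passthrough[state]
        for ip, sol in enumerate(self.solutions):
            if state in sol.states:
                row = sol.states.index(state)
                col = int(np.argmax(sol.eigenvectors[row, :] ** 2))
                return float(sol.eigenvalues[col])
        raise KeyError(f"state {state.label()} not in result")

    def mixing_of(self, state: VibState) -> float:
        """Squared weight of ``state`` in its best variational state."""
        if state in self.passthrough:
            return 1.0
        for sol in self.solutions:
            if state in sol.states:
                row = sol.states.index(state)
                return float(np.max(sol.eigenvectors[row, :] ** 2))
        raise KeyError(f"state {state.label()} not in result")


def _dominant_row(weights: np.ndarray) -> tuple[int, bool]:
    """Index of the largest squared component; exact ties break toward the
    lower-index (lower-energy) basis state."""
    mx = weights.max()
    ties = np.nonzero(weights >= mx - 1e-12)[0]
    return int(ties[0]), len(ties) > 1


def _fix_phases(vecs: np.ndarray) -> np.ndarray:
    vecs = vecs.copy()
    for c in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, c])))
        if vecs[k, c] < 0:
            vecs[:, c] = -vecs[:, c]
    return vecs


def assemble_and_diagonalize(
    polyaddb: PolyadDB,
    dvpt2_energies: dict[VibState, float],
    global_matrix: bool = False,
) -> GVPT2Result:
    """Diagonalize every polyad block.

    ``dvpt2_energies`` must supply an energy for every state of the space.
    ``global_matrix=True`` assembles one global matrix instead; it is
    retained for cross-validation only (block results are identical up to
    numerical noise, and the global route scales poorly).
    """
    for s in polyaddb.all_states():
        if s not in dvpt2_energies:
            raise ValueError(f"no DVPT2 energy for state {s.label()}")

    if global_matrix:
        return _solve_global(polyaddb, dvpt2_energies)

    solutions = [_solve_block(p, dvpt2_energies) for p in polyaddb.polyads]
    passthrough = {s: float(dvpt2_energies[s]) for s in polyaddb.singletons}
    result = GVPT2Result(solutions=solutions, passthrough=passthrough)
    result.assignment = assign_states(result)
    return result


def _solve_block(p: Polyad, energies: dict[VibState, float]) -> PolyadSolution:
    n = p.size
    m = np.zeros((n, n))
    pos = {s: i for i, s in enumerate(p.states)}
    for i, s in enumerate(p.states):
        m[i, i] = energies[s]
    for key, v in p.couplings.items():
        a, b = tuple(key)
        i, j = pos[a], pos[b]
        m[i, j] = m[j, i] = v
    vals, vecs = np.linalg.eigh(m)
    vecs = _fix_phases(vecs)
    gram = vecs.T @ vecs - np.eye(n)
    if np.abs(gram).max() > ORTHO_TOL:
        raise AssertionError("eigenvectors lost orthonormality")
    if abs(vals.sum() - np.trace(m)) > TRACE_TOL * max(1.0, abs(np.trace(m))):
        raise AssertionError("trace not conserved by diagonalization")
    return PolyadSolution(states=list(p.states), matrix=m,
                          eigenvalues=vals, eigenvectors=vecs)


def _solve_global(polyaddb: PolyadDB, energies: dict[VibState, float]) -> GVPT2Result:
    states = polyaddb.all_states()
    pos = {s: i for i, s in enumerate(states)}
    n = len(states)
    m = np.zeros((n, n))
    for s, i in pos.items():
        m[i, i] = energies[s]
    for p in polyaddb.polyads:
        for key, v in p.couplings.items():
            a, b = tuple(key)
            m[pos[a], pos[b]] = m[pos[b], pos[a]] = v
    vals, vecs = np.linalg.eigh(m)
    vecs = _fix_phases(vecs)
    sol = PolyadSolution(states=states, matrix=m, eigenvalues=vals, eigenvectors=vecs)
    result = GVPT2Result(solutions=[sol], passthrough={})
    result.assignment = assign_states(result)
    return result


def assign_states(result: GVPT2Result) -> dict[tuple[int, int], tuple[VibState, float]]:
    """Label every GVPT2 eigenstate by its dominant DVPT2 basis state.

    Keyed by (polyad index, eigenvector column); the value is the basis state
    with the largest squared eigenvector component and that overlap fraction.
    Exact ties break toward the lower-energy basis state and are logged.
    """
    out: dict[tuple[int, int], tuple[VibState, float]] = {}
    for ip, sol in enumerate(result.solutions):
        for col in range(len(sol.states)):
            weights = sol.eigenvectors[:, col] ** 2
            row, tied = _dominant_row(weights)
            if tied:
                logger.info(
                    "degenerate overlap in polyad %d (column %d): tie broken "
                    "toward %s", ip, col, sol.states[row].label(),
                )
            out[(ip, col)] = (sol.states[row], float(weights[row]))
    return out
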