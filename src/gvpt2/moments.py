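"""VPT2 / DVPT2 transition moments, GVPT2 projection, pseudoeigenvectors.

Moments are assembled as explicit Rayleigh-Schroedinger sums over sparse
harmonic-oscillator wave functions.  Writing P-hat for the Taylor-expanded
property operator (orders 0..2 in the perturbation) and psi1/psi2 for the
perturbed wave functions of the initial |I> = |0> and final |F> states, the
second-order transition moment is

    M = <I|P0|F>
      + <I|P1|F> + <psi1(I)|P0|F> + <I|P0|psi1(F)>
      + <I|P2|F> + <psi1(I)|P1|F> + <I|P1|psi1(F)> + <psi1(I)|P0|psi1(F)>
      + <psi2(I)|P0|F> + <I|P0|psi2(F)>
      - (1/2) (||psi1(I)||^2 + ||psi1(F)||^2) <I|P0|F>

where P0 carries the equilibrium value and first derivatives, P1 the second
derivatives and P2 the semidiagonal third derivatives of the property.  Every
energy denominator appears explicitly, so deperturbation is literal: each
term whose denominator corresponds to an accepted Fermi or Darling-Dennison
resonance is omitted and recorded, which realizes both the DVPT2 scheme and
its resonance-aware variants in one mechanism.  A near-zero denominator that
is *not* covered by the resonance database raises a hard error pointing the
user at the resonance configuration (moments are where untreated resonances
produce unbounded artifacts).

For momentum-type properties (S = -1, e.g. the magnetic dipole for VCD) the
operator is expanded over the conjugate momenta; amplitudes are complex and
the 90-degree phase is kept explicitly, so rotatory strengths come out as
Im(mu_el . conj(m_mag)) with no further bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield

import numpy as np

from .model import AnharmonicField, HarmonicModel, PropertySurface, VibData
from .operators import (
    Monomial,
    QKey,
    WaveFn,
    apply_operator,
    cubic_operator,
    first_order_coefficients,
    norm2,
    overlap,
    quartic_operator,
    second_order_coefficients,
)
from .resonance import ResonanceDB
from .states import VibState
from .variational import GVPT2Result

logger = logging.getLogger("gvpt2")


# ---------------------------------------------------------------------------
# property operator expansion
# ---------------------------------------------------------------------------

def property_components(
    surf: PropertySurface, n_modes: int
) -> list[tuple[np.ndarray, dict[int, int]]]:
    """Expand a property surface into monomials of xi (= q for S=+1, p for
    S=-1): list of (component-coefficient vector, {mode: power}).

    The combinatorial multiplicity of the Taylor sum is absorbed: P_ij with
    i != j appears as (P_ij + P_ji) on the unordered pair, semidiagonal
    P_ijj patterns with multiplicity 3.
    """
    out: list[tuple[np.ndarray, dict[int, int]]] = []
    if surf.P0 is not None and np.any(surf.P0):
        out.append((surf.s0 * surf.P0.astype(float), {}))
    if surf.P1 is not None:
        for i in range(1, surf.P1.shape[0] + 1):
            vec = surf.s1 * surf.P1[i - 1]
            if np.any(vec):
                out.append((vec, {i: 1}))
    if surf.P2 is not None:
        n = surf.P2.shape[0]
        for i in range(1, n + 1):
            vec = surf.s2 * surf.P2[i - 1, i - 1]
            if np.any(vec):
                out.append((vec, {i: 2}))
            for j in range(i + 1, n + 1):
                vec = surf.s2 * (surf.P2[i - 1, j - 1] + surf.P2[j - 1, i - 1])
                if np.any(vec):
                    out.append((vec, {i: 1, j: 1}))
    for (i, j), vec3 in surf.P3_semidiag.items():
        if not np.any(vec3):
            continue
        if i == j:
            out.append((surf.s3 * vec3, {i: 3}))
        else:
            out.append((3.0 * surf.s3 * vec3, {i: 1, j: 2}))
    return out


def _property_operators_by_order(
    surf: PropertySurface, n_modes: int
) -> list[list[tuple[np.ndarray, Monomial]]]:
    """Group the expansion by perturbative order: [P0-hat, P1-hat, P2-hat].

    Each entry is a list of (component vector, unit monomial); the component
    vector scales the monomial per Cartesian component.
    """
    kind = "q" if surf.S == +1 else "p"
    orders: list[list[tuple[np.ndarray, Monomial]]] = [[], [], []]
    for vec, powers in property_components(surf, n_modes):
        degree = sum(powers.values())
        order = max(0, degree - 1)
        mono = Monomial(coeff=1.0, factors=tuple(sorted(powers.items())), kind=kind)
        orders[order].append((vec, mono))
    return orders


def _apply_property(
    terms: list[tuple[np.ndarray, Monomial]], psi: WaveFn, n_components: int
) -> list[WaveFn]:
    """Apply each component of a property-order operator to psi."""
    outs: list[WaveFn] = [dict() for _ in range(n_components)]
    for vec, mono in terms:
        res = apply_operator(psi, [mono])
        for c in range(n_components):
            if vec[c]:
                acc = outs[c]
                for k, a in res.items():
                    acc[k] = acc.get(k, 0.0) + vec[c] * a
    return outs


# ---------------------------------------------------------------------------
# transition moments
# ---------------------------------------------------------------------------

@dataclass
class TransitionMoment:
    bra: VibState
    ket: VibState
    property: str
    value: np.ndarray                      # complex, per component
    level: str
    removed_terms: list[tuple[QKey, QKey]] = dfield(default_factory=list)
    incomplete: bool = False               # property surface missing blocks

    def strength(self) -> float:
        """Squared norm of the moment (property units squared)."""
        return float(np.sum(np.abs(self.value) ** 2))


def _resonance_predicate(resdb: ResonanceDB | None):
    if resdb is None:
        return lambda a, b: False
    return resdb.is_pair_keys


class MomentContext:
    """Reusable per-(bundle, resdb, level) pieces: the Hamiltonian monomials,
    the perturbed ground-state wave function, and per-final-state psi caches.
    Passing one context to repeated :func:`transition_moment` calls avoids
    recomputing the ground-state expansion for every band."""

    def __init__(self, bundle: VibData, resdb: ResonanceDB | None, level: str):
        self.level = level
        self.is_res = _resonance_predicate(resdb if level == "DVPT2" else None)
        self.h1 = cubic_operator(bundle.field)
        self.h2 = quartic_operator(bundle.field)
        self.removed_i: list[tuple[QKey, QKey]] = []
        w = bundle.harmonic.omega
        self.psi1_i = first_order_coefficients((), self.h1, w, self.is_res,
                                               self.removed_i)
        self.psi2_i = second_order_coefficients((), self.h1, self.h2, w,
                                                self.psi1_i, self.is_res,
                                                self.removed_i)
        self.norm_i = norm2(self.psi1_i)
        self._omega = w
        self._prop_orders: dict[str, list] = {}
        self._psi_f: dict[QKey, tuple[WaveFn, WaveFn, list]] = {}

    def property_orders(self, surface: PropertySurface, n: int):
        if surface.name not in self._prop_orders:
            self._prop_orders[surface.name] = _property_operators_by_order(surface, n)
        return self._prop_orders[surface.name]

    def final_state(self, fkey: QKey) -> tuple[WaveFn, WaveFn, list]:
        if fkey not in self._psi_f:
            removed: list[tuple[QKey, QKey]] = []
            psi1 = first_order_coefficients(fkey, self.h1, self._omega,
                                            self.is_res, removed)
            psi2 = second_order_coefficients(fkey, self.h1, self.h2,
                                             self._omega, psi1, self.is_res,
                                             removed)
            self._psi_f[fkey] = (psi1, psi2, removed)
        return self._psi_f[fkey]


def transition_moment(
    final: VibState,
    bundle: VibData,
    surface: PropertySurface | str,
    resdb: ResonanceDB | None = None,
    level: str = "VPT2",
    context: MomentContext | None = None,
) -> TransitionMoment:
    """Ground-state transition moment <0|P|final> at the requested level.

    level = 'harmonic' : double-harmonic term only;
            'VPT2'     : full second order, no removal (hard error on a
                         near-singular denominator);
            'DVPT2'    : second order with accepted-resonance terms removed.
    """
    if isinstance(surface, str):
        surface = bundle.property_by_name(surface)
    level = level.upper() if level.lower() != "harmonic" else "harmonic"
    n = bundle.n_modes
    final.validate(n)
    nc = surface.n_components
    w = bundle.harmonic.omega
    fkey: QKey = tuple(sorted(final.as_dict().items()))
    ikey: QKey = ()
    if context is not None and context.level != level:
        raise ValueError("context was built for a different level")
    ctx = context or MomentContext(bundle, resdb, level)
    orders = ctx.property_orders(surface, n)

    def elem(bra: WaveFn, terms, ket: WaveFn) -> np.ndarray:
        outs = _apply_property(terms, ket, nc)
        return np.array([overlap(bra, o) for o in outs])

    bra0: WaveFn = {ikey: 1.0}
    ket0: WaveFn = {fkey: 1.0}
    value = elem(bra0, orders[0], ket0)
    removed: list[tuple[QKey, QKey]] = []
    incomplete = surface.P2 is None or not surface.P3_semidiag

    if level != "harmonic":
        removed.extend(ctx.removed_i)
        psi1_i, psi2_i = ctx.psi1_i, ctx.psi2_i
        psi1_f, psi2_f, removed_f = ctx.final_state(fkey)
        removed.extend(removed_f)

        value = value + elem(bra0, orders[1], ket0)
        value = value + elem(psi1_i, orders[0], ket0)
        value = value + elem(bra0, orders[0], psi1_f)

        value = value + elem(bra0, orders[2], ket0)
        value = value + elem(psi1_i, orders[1], ket0)
        value = value + elem(bra0, orders[1], psi1_f)
        value = value + elem(psi1_i, orders[0], psi1_f)
        value = value + elem(psi2_i, orders[0], ket0)
        value = value + elem(bra0, orders[0], psi2_f)
        value = value - 0.5 * (ctx.norm_i + norm2(psi1_f)) * elem(bra0, orders[0], ket0)

    if incomplete and level != "harmonic":
        logger.debug(
            "property %r: second/third derivative blocks missing; anharmonic "
            "correction to <0|P|%s> may be incomplete", surface.name, final.label(),
        )
    return TransitionMoment(
        bra=VibState.ground(), ket=final, property=surface.name,
        value=value.astype(complex), level=level, removed_terms=removed,
        incomplete=incomplete,
    )


def tm_fundamental(
    i: int,
    bundle: VibData,
    surface: PropertySurface | str,
    resdb: ResonanceDB | None = None,
    level: str = "VPT2",
) -> TransitionMoment:
    """Transition moment of the fundamental of mode i from the ground state."""
    return transition_moment(VibState.fundamental(i), bundle, surface, resdb, level)


def tm_two_quanta(
    state: VibState,
    bundle: VibData,
    surface: PropertySurface | str,
    resdb: ResonanceDB | None = None,
    level: str = "VPT2",
) -> TransitionMoment:
    """Transition moment of a first overtone or 1+1 combination band."""
    if state.total_quanta != 2:
        raise ValueError(f"{state.label()} is not a 2-quanta state")
    return transition_moment(state, bundle, surface, resdb, level)


# ---------------------------------------------------------------------------
# GVPT2 projection
# ---------------------------------------------------------------------------

def project_gvpt2(
    moments: dict[VibState, np.ndarray],
    gvpt2: GVPT2Result,
) -> dict[tuple[int, int], np.ndarray]:
    """Project deperturbed moments onto the variational (GVPT2) states.

    For polyad p with eigenvector matrix V, the moment of eigenstate (p, col)
    is sum_row V[row, col] * M[state_row].  Orthonormality of V conserves the
    polyad sum of squared moment norms.  Keys are (polyad index, column);
    singleton states keep their moments and are not returned here.
    """
    out: dict[tuple[int, int], np.ndarray] = {}
    for ip, sol in enumerate(gvpt2.solutions):
        for s in sol.states:
            if s not in moments:
                raise ValueError(f"no deperturbed moment supplied for state {s.label()}")
        block = np.stack([np.asarray(moments[s], dtype=complex) for s in sol.states])
        proj = sol.eigenvectors.T @ block        # (cols, components)
        for col in range(len(sol.states)):
            out[(ip, col)] = proj[col]
    return out


# ---------------------------------------------------------------------------
# pseudoeigenvectors
# ---------------------------------------------------------------------------

def pseudo_eigenvector(
    state: VibState,
    harm: HarmonicModel,
    field: AnharmonicField,
    resdb: ResonanceDB,
    use_cache: bool = True,
) -> np.ndarray:
    """Cartesian effective mode of a perturbed VPT2 state.

    Fundamentals mix with other fundamentals through the second-order
    coefficients (the quantities scored by R11COEF); 2-quanta states acquire
    fundamental character through the first-order (Fermi) coefficients.
    Coefficients of accepted (deperturbed) resonances are excluded.  The
    coefficients are normally served from the cache built with the resonance
    database; ``use_cache=False`` recomputes them.
    """
    if harm.L is None:
        raise ValueError("harmonic model carries no normal-mode matrix")
    n = harm.n_modes
    L = harm.L
    vec = np.zeros(L.shape[0])
    q = state.as_dict()
    if state.total_quanta == 1:
        (i,) = state.modes
        vec = L[:, i - 1].copy()
        for j in range(1, n + 1):
            if j == i:
                continue
            if resdb.is_pair(VibState.fundamental(i), VibState.fundamental(j)):
                continue
            c = _dd2_coefficient(i, j, harm, field, resdb, use_cache)
            vec = vec + c * L[:, j - 1]
        return vec
    if state.total_quanta == 2:
        modes = sorted(q)
        if len(modes) == 1:
            j = k = modes[0]
        else:
            j, k = modes
        for i in range(1, n + 1):
            if i in (j, k):
                continue
            if resdb.is_pair(VibState.fundamental(i), state):
                continue
            c1 = _fermi1_coefficient(i, j, k, harm, field, resdb, use_cache)
            # coefficient of |1_i> in the perturbed 2-quanta state has the
            # opposite denominator sign of the cached (i; j,k) coefficient
            vec = vec - c1 * L[:, i - 1]
        return vec
    raise ValueError("pseudoeigenvectors defined for 1- and 2-quanta states only")


def _fermi1_coefficient(i, j, k, harm, field, resdb, use_cache) -> float:
    key = ("fermi1", i, j, k)
    if use_cache and key in resdb.coef_cache:
        c = resdb.coef_cache[key]
        return 0.0 if math.isinf(abs(c)) else c
    from .resonance import ResonanceKind, fermi_first_order_element
    phi = field.get_cubic(i, j, k)
    if phi == 0.0:
        return 0.0
    kind = ResonanceKind.FERMI_I if j == k else ResonanceKind.FERMI_II
    delta = harm.omega[i - 1] - harm.omega[j - 1] - harm.omega[k - 1]
    if delta == 0.0:
        return 0.0
    return fermi_first_order_element(kind, phi) / delta


def _dd2_coefficient(i, j, harm, field, resdb, use_cache) -> float:
    lo, hi = min(i, j), max(i, j)
    key = ("dd2", lo, hi)
    if use_cache and key in resdb.coef_cache:
        c = resdb.coef_cache[key]
    else:
        from .resonance import ResonanceCandidate, ResonanceKind, dd_second_order_coefficient
        cand = ResonanceCandidate(
            kind=ResonanceKind.DD11,
            bra=VibState.fundamental(lo),
            ket=VibState.fundamental(hi),
            delta=float(harm.omega[lo - 1] - harm.omega[hi - 1]),
            indices=(lo, hi),
        )
        c = dd_second_order_coefficient(cand, harm, field)
        if math.isinf(abs(c)):
            c = 0.0
    # cache stores the coefficient of |1_hi> in psi(|1_lo>); the reverse
    # mixing flips with the denominator sign
    return c if i == lo else -c
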