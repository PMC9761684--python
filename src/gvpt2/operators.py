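"""Sparse harmonic-oscillator operator algebra.

All perturbative machinery (transition moments, Darling-Dennison couplings,
wave-function coefficients) is built on analytic matrix elements of the
dimensionless normal coordinate q = (b + b†)/sqrt(2) and its conjugate
momentum p = i (b† - b)/sqrt(2) between product harmonic-oscillator states.
States are sparse tuples of (mode, quanta); wave functions are dictionaries
state -> complex amplitude.  The anharmonic potential

    V = (1/6) sum_ijk k_ijk q_i q_j q_k  +  (1/24) sum_ijkl K_ijkl q_i q_j q_k q_l

(sums over all index orderings, constants fully symmetric) is expanded into a
list of monomials with the combinatorial multiplicity absorbed in the
coefficient, so each stored constant appears exactly once.

This route trades the speed of transcribed closed-form expressions for
term-by-term control over every energy denominator, which is what the
deperturbation (DVPT2) and resonance-aware moment variants require, and it
scales with the number of stored force constants rather than with the cube of
the mode count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

from .model import AnharmonicField

QKey = tuple[tuple[int, int], ...]   # sorted ((mode, quanta), ...)
WaveFn = dict[QKey, complex]

GROUND: QKey = ()

#: hard-error threshold for untreated near-singular denominators (cm-1)
SINGULAR_TOL = 1e-6


class SingularDenominatorError(ZeroDivisionError):
    """A perturbative denominator is (near) zero and the state pair is not in
    the resonance database; the user must amend the resonance configuration."""


def key_from_counts(counts: Mapping[int, int]) -> QKey:
    return tuple(sorted((m, n) for m, n in counts.items() if n))


def key_energy(key: QKey, omega: np.ndarray) -> float:
    """Harmonic energy above the ground state (cm-1)."""
    return float(sum(n * omega[m - 1] for m, n in key))


def shift_mode(key: QKey, mode: int, dn: int) -> QKey | None:
    """Key with quanta of ``mode`` changed by dn, or None if it would go < 0."""
    d = dict(key)
    n = d.get(mode, 0) + dn
    if n < 0:
        return None
    if n == 0:
        d.pop(mode, None)
    else:
        d[mode] = n
    return tuple(sorted(d.items()))


def apply_q(psi: WaveFn, mode: int) -> WaveFn:
    """Apply q_mode = (b + b†)/sqrt(2)."""
    out: WaveFn = {}
    for key, amp in psi.items():
        v = dict(key).get(mode, 0)
        up = shift_mode(key, mode, +1)
        out[up] = out.get(up, 0.0) + amp * math.sqrt((v + 1) / 2.0)
        if v:
            dn = shift_mode(key, mode, -1)
            out[dn] = out.get(dn, 0.0) + amp * math.sqrt(v / 2.0)
    return out


def apply_p(psi: WaveFn, mode: int) -> WaveFn:
    """Apply p_mode = i (b† - b)/sqrt(2)."""
    out: WaveFn = {}
    for key, amp in psi.items():
        v = dict(key).get(mode, 0)
        up = shift_mode(key, mode, +1)
        out[up] = out.get(up, 0.0) + amp * 1j * math.sqrt((v + 1) / 2.0)
        if v:
            dn = shift_mode(key, mode, -1)
            out[dn] = out.get(dn, 0.0) + amp * (-1j) * math.sqrt(v / 2.0)
    return out


# ---------------------------------------------------------------------------
# polynomial operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Monomial:
    """coeff * prod_m xi_m^power, with xi = q (coordinate) or p (momentum)."""
    coeff: complex
    factors: tuple[tuple[int, int], ...]   # ((mode, power), ...)
    kind: str = "q"                        # "q" or "p"


def apply_monomial(psi: WaveFn, mono: Monomial) -> WaveFn:
    cur = psi
    op = apply_q if mono.kind == "q" else apply_p
    for mode, power in mono.factors:
        for _ in range(power):
            cur = op(cur, mode)
    if mono.coeff == 1:
        return dict(cur)
    return {k: mono.coeff * a for k, a in cur.items()}


def apply_operator(psi: WaveFn, terms: Iterable[Monomial]) -> WaveFn:
    out: WaveFn = {}
    for mono in terms:
        for k, a in apply_monomial(psi, mono).items():
            out[k] = out.get(k, 0.0) + a
    return {k: a for k, a in out.items() if a != 0}


def overlap(bra: WaveFn, ket: WaveFn) -> complex:
    if len(bra) > len(ket):
        bra, ket = {k: v.conjugate() for k, v in ket.items()}, {
            k: v.conjugate() for k, v in bra.items()
        }
    return sum(amp.conjugate() * ket[k] for k, amp in bra.items() if k in ket)


def norm2(psi: WaveFn) -> float:
    return float(sum(abs(a) ** 2 for a in psi.values()))


def _multiplicity(idx: tuple[int, ...]) -> int:
    n = len(idx)
    denom = 1
    for cnt in Counter(idx).values():
        denom *= math.factorial(cnt)
    return math.factorial(n) // denom


def cubic_operator(field: AnharmonicField) -> list[Monomial]:
    """H1 = (1/6) sum_{ijk} k_ijk q_i q_j q_k as monomials over stored triples."""
    terms = []
    for idx, val in field.cubic.items():
        if val == 0.0:
            continue
        coeff = val * _multiplicity(idx) / 6.0
        factors = tuple(sorted(Counter(idx).items()))
        terms.append(Monomial(coeff=coeff, factors=factors))
    return terms


def quartic_operator(field: AnharmonicField) -> list[Monomial]:
    """H2 = (1/24) sum_{ijkl} K_ijkl q_i q_j q_k q_l over stored quadruples."""
    terms = []
    for idx, val in field.quartic.items():
        if val == 0.0:
            continue
        coeff = val * _multiplicity(idx) / 24.0
        factors = tuple(sorted(Counter(idx).items()))
        terms.append(Monomial(coeff=coeff, factors=factors))
    return terms


# ---------------------------------------------------------------------------
# perturbative wave functions with per-denominator resonance control
# ---------------------------------------------------------------------------

#: predicate (state_key, intermediate_key) -> True when the pair is an
#: accepted resonance whose terms must be deperturbed (removed)
ResonancePredicate = Callable[[QKey, QKey], bool]


def _never(_a: QKey, _b: QKey) -> bool:
    return False


def first_order_coefficients(
    state: QKey,
    h1: list[Monomial],
    omega: np.ndarray,
    is_resonant: ResonancePredicate = _never,
    removed: list[tuple[QKey, QKey]] | None = None,
    singular_tol: float = SINGULAR_TOL,
) -> WaveFn:
    """|psi^(1)> = sum_u |u> <u|H1|state> / (E_state - E_u).

    Terms whose denominator corresponds to an accepted resonance are omitted
    (and recorded in ``removed``); a near-zero denominator that is *not*
    covered by the resonance database raises ``SingularDenominatorError``.
    """
    e0 = key_energy(state, omega)
    coeffs: WaveFn = {}
    for u, amp in apply_operator({state: 1.0}, h1).items():
        if u == state:
            continue
        d = e0 - key_energy(u, omega)
        if is_resonant(state, u):
            if removed is not None:
                removed.append((state, u))
            continue
        if abs(d) < singular_tol:
            raise SingularDenominatorError(
                f"denominator {d:.2e} cm-1 between {state} and {u}; "
                "add the pair to the resonance configuration"
            )
        coeffs[u] = amp / d
    return coeffs


def second_order_coefficients(
    state: QKey,
    h1: list[Monomial],
    h2: list[Monomial],
    omega: np.ndarray,
    psi1: WaveFn | None = None,
    is_resonant: ResonancePredicate = _never,
    removed: list[tuple[QKey, QKey]] | None = None,
    singular_tol: float = SINGULAR_TOL,
) -> WaveFn:
    """|psi^(2)> coefficients at intermediate normalisation.

    c_u = [ sum_w H1_uw H1_w,state / (E-E_w)  +  H2_u,state ] / (E-E_u)

    with u, w != state.  Resonant w-terms were already dropped in psi1;
    resonant u-pairs are dropped here, term by term.
    """
    if psi1 is None:
        psi1 = first_order_coefficients(
            state, h1, omega, is_resonant, removed, singular_tol
        )
    e0 = key_energy(state, omega)
    num: WaveFn = apply_operator(psi1, h1)
    for u, amp in apply_operator({state: 1.0}, h2).items():
        num[u] = num.get(u, 0.0) + amp
    coeffs: WaveFn = {}
    for u, amp in num.items():
        if u == state or amp == 0:
            continue
        d = e0 - key_energy(u, omega)
        if is_resonant(state, u):
            if removed is not None:
                removed.append((state, u))
            continue
        if abs(d) < singular_tol:
            raise SingularDenominatorError(
                f"second-order denominator {d:.2e} cm-1 between {state} and {u}"
            )
        coeffs[u] = amp / d
    return coeffs


# ---------------------------------------------------------------------------
# HDCPT2-style regularisation of resonant terms
# ---------------------------------------------------------------------------

def hdcpt2_term(num: float, delta: float, alpha: float = 1.0) -> float:
    """Regularised value of a resonance-prone term ``num / delta``.

    Writes num/delta = lam^2 sgn(num)/delta with lam^2 = |num| and blends the
    plain second-order term with a bounded degeneracy-corrected form,

        Lambda * num/delta + (1 - Lambda) * num * delta / (delta^2 + 4 lam^2),

    Lambda = 1 - exp(-delta^2 / (alpha * lam^2)).  The result is finite and
    continuous for every (num, delta), odd in delta, bounded by sqrt(lam^2)/4,
    and converges rapidly to num/delta away from resonance (relative deviation
    exp(-delta^2/lam^2) at |delta| >> lam).
    """
    lam2 = abs(num)
    if lam2 == 0.0:
        return 0.0
    if delta == 0.0:
        return 0.0
    x = delta * delta / (alpha * lam2)
    lam_w = 1.0 - math.exp(-x) if x < 50 else 1.0
    plain = num / delta
    corrected = num * delta / (delta * delta + 4.0 * lam2)
    return lam_w * plain + (1.0 - lam_w) * corrected


# ---------------------------------------------------------------------------
# Van Vleck effective couplings (Darling-Dennison terms)
# ---------------------------------------------------------------------------

def effective_coupling(
    a: QKey,
    b: QKey,
    h1: list[Monomial],
    h2: list[Monomial],
    omega: np.ndarray,
    regularize: bool = True,
) -> float:
    """Second-order effective-Hamiltonian element between near-degenerate
    states |a> and |b> (the Darling-Dennison coupling, in cm-1):

        W_ab = <a|H2|b> + (1/2) sum_{u not in {a,b}} <a|H1|u><u|H1|b>
                            * [1/(E_a - E_u) + 1/(E_b - E_u)]

    Internal Fermi-like denominators are rewritten in a non-resonant
    (regularised) form so W stays finite for any input.
    """
    ea, eb = key_energy(a, omega), key_energy(b, omega)
    ha = apply_operator({a: 1.0}, h1)
    hb = apply_operator({b: 1.0}, h1)
    w = overlap({a: 1.0}, apply_operator({b: 1.0}, h2))
    total = complex(w)
    for u, amp_a in ha.items():
        if u == a or u == b or u not in hb:
            continue
        num = (amp_a.conjugate() * hb[u]).real
        for e_ref in (ea, eb):
            d = e_ref - key_energy(u, omega)
            if regularize:
                total += 0.5 * hdcpt2_term(num, d)
            else:
                total += 0.5 * num / d
    return float(total.real)
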