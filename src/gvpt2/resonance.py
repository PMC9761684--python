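"""Identification of Fermi and Darling-Dennison resonances.

Candidate generation is a cheap energy-window prefilter over the full
combinatorial space (|omega_i - omega_j - omega_k| <= window for Fermi triads,
analogous differences for Darling-Dennison pairs).  Each surviving candidate
is then scored by one scheme designed for energies and optionally one for
intensities; passing *either* test inserts the resonance into the database
(logical OR).

Schemes
-------
Fermi (first-order, cubic-driven):
  R12MART  Martin's test: the deviation of the 2x2 variational treatment from
           plain second order, phi^4 / (256 |Delta|^3) for overtone partners
           (type I) and phi^4 / (64 |Delta|^3) for combination partners
           (type II), in cm-1.
  R12CVPT  divergence measure of the canonical Van Vleck transformation,
           |phi| / (2 sqrt2 |Delta|), dimensionless.
  R12WFRQ  Martin's index weighted by the energy gap (default |Delta|^-2).
  R12COEF  magnitude of the first-order wave-function coefficient that enters
           the transition-moment sums: |phi|/(4|Delta|) for type I,
           |phi|/(2 sqrt2 |Delta|) for type II.

Darling-Dennison (second-order):
  R11HRS / R22HRS   magnitude of the effective (contact-transformed) coupling
                    between the near-degenerate states, in cm-1.
  R11WFRQ           same coupling divided by Delta^2.
  R11COEF           magnitude of the second-order wave-function coefficient
                    mixing the two fundamentals (should be < 1 for a
                    perturbative state; the indicative upper bound for its
                    threshold).

An exact degeneracy (Delta = 0) short-circuits every denominator-based test
to acceptance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield
from enum import Enum
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

from .model import AnharmonicField, HarmonicModel
from .operators import (
    QKey,
    cubic_operator,
    effective_coupling,
    hdcpt2_term,
    key_energy,
    apply_operator,
    overlap,
    quartic_operator,
)
from .states import VibState

logger = logging.getLogger("gvpt2")

SQRT2 = math.sqrt(2.0)


class ResonanceKind(str, Enum):
    FERMI_I = "FERMI_I"
    FERMI_II = "FERMI_II"
    DD11 = "DD11"
    DD22 = "DD22"
    DD211 = "DD211"


@dataclass(frozen=True)
class ResonanceCandidate:
    kind: ResonanceKind
    bra: VibState
    ket: VibState
    delta: float                 # harmonic energy difference E(bra)-E(ket), cm-1
    indices: tuple[int, ...]     # mode tuple: (i, j, k) Fermi, (i, j) DD11, ...
    coupling: float = 0.0        # relevant constant / effective coupling, cm-1

    def pair_key(self) -> frozenset:
        return frozenset((self.bra, self.ket))


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_fermi_candidates(
    omega: np.ndarray, window: float = math.inf
) -> list[ResonanceCandidate]:
    """All triads (i; j <= k), i not in {j, k}, with |w_i - w_j - w_k| <= window.

    Type I are overtone partners (j == k, w_i ~ 2 w_j); type II combination
    partners.  Triads with i in {j, k} are excluded: w_i ~ w_i + w_k would
    require w_k ~ 0, which is unphysical.
    """
    if window <= 0:
        raise ValueError("window must be positive (use math.inf for counting)")
    w = np.asarray(omega, dtype=float)
    n = w.size
    out: list[ResonanceCandidate] = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if j == i:
                continue
            for k in range(j, n + 1):
                if k == i:
                    continue
                delta = w[i - 1] - w[j - 1] - w[k - 1]
                if abs(delta) <= window:
                    kind = ResonanceKind.FERMI_I if j == k else ResonanceKind.FERMI_II
                    out.append(ResonanceCandidate(
                        kind=kind,
                        bra=VibState.fundamental(i),
                        ket=VibState.combination(j, k),
                        delta=float(delta),
                        indices=(i, j, k),
                    ))
    return out


def count_fermi_triads(n_modes: int) -> int:
    """Closed form: N * [C(N-1, 2) + (N-1)] = N (N-1) N / 2 ... computed exactly."""
    n = n_modes
    return n * ((n - 1) * (n - 2) // 2 + (n - 1))


def two_quanta_states(n_modes: int) -> list[VibState]:
    """All N + N(N+1)/2 states with up to two quanta (excluding the ground
    state): fundamentals, first overtones and 1+1 combinations."""
    out = [VibState.fundamental(i) for i in range(1, n_modes + 1)]
    out += [VibState.overtone(i) for i in range(1, n_modes + 1)]
    out += [
        VibState.combination(i, j)
        for i in range(1, n_modes + 1)
        for j in range(i + 1, n_modes + 1)
    ]
    return out


def _iter_two_quanta_pairs(n: int) -> Iterator[tuple[VibState, VibState]]:
    states = [VibState.overtone(i) for i in range(1, n + 1)] + [
        VibState.combination(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
    ]
    return combinations(states, 2)


def count_two_quanta_pairs(n_modes: int) -> int:
    """Closed form C(M, 2) with M = N(N+1)/2 two-quanta states."""
    m = n_modes * (n_modes + 1) // 2
    return m * (m - 1) // 2


def enumerate_dd_candidates(
    omega: np.ndarray,
    kind: ResonanceKind | str,
    window: float = math.inf,
    restricted: bool = True,
) -> list[ResonanceCandidate]:
    """Darling-Dennison candidates within the energy window.

    DD11: unordered pairs of distinct fundamentals.
    DD22: pairs of distinct 2-quanta states; by default restricted to
    overtone-overtone (2-2) and overtone-combination (2-11) patterns, the
    couplings computable from a semidiagonal quartic field.  Set
    ``restricted=False`` to span the full pair space (counting only).
    """
    kind = ResonanceKind(kind)
    if window <= 0:
        raise ValueError("window must be positive")
    w = np.asarray(omega, dtype=float)
    n = w.size
    out: list[ResonanceCandidate] = []

    def energy(s: VibState) -> float:
        return s.harmonic_energy(w)

    if kind is ResonanceKind.DD11:
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                delta = w[i - 1] - w[j - 1]
                if abs(delta) <= window:
                    out.append(ResonanceCandidate(
                        kind=kind,
                        bra=VibState.fundamental(i),
                        ket=VibState.fundamental(j),
                        delta=float(delta),
                        indices=(i, j),
                    ))
        return out

    if kind is ResonanceKind.DD22:
        if restricted:
            for i in range(1, n + 1):
                for k in range(i + 1, n + 1):
                    delta = 2 * w[i - 1] - 2 * w[k - 1]
                    if abs(delta) <= window:
                        out.append(ResonanceCandidate(
                            kind=kind,
                            bra=VibState.overtone(i),
                            ket=VibState.overtone(k),
                            delta=float(delta),
                            indices=(i, i, k, k),
                        ))
            for i in range(1, n + 1):
                for k in range(1, n + 1):
                    for l in range(k + 1, n + 1):
                        if i in (k, l):
                            continue
                        delta = 2 * w[i - 1] - (w[k - 1] + w[l - 1])
                        if abs(delta) <= window:
                            out.append(ResonanceCandidate(
                                kind=ResonanceKind.DD211,
                                bra=VibState.overtone(i),
                                ket=VibState.combination(k, l),
                                delta=float(delta),
                                indices=(i, i, k, l),
                            ))
        else:
            for a, b in _iter_two_quanta_pairs(n):
                delta = energy(a) - energy(b)
                if abs(delta) <= window:
                    out.append(ResonanceCandidate(
                        kind=kind, bra=a, ket=b, delta=float(delta),
                        indices=tuple(a.modes) + tuple(b.modes),
                    ))
        return out
    raise ValueError(f"unsupported enumeration kind {kind}")


def count_dd_pairs(n_modes: int, kind: ResonanceKind | str) -> int:
    kind = ResonanceKind(kind)
    if kind is ResonanceKind.DD11:
        return n_modes * (n_modes - 1) // 2
    if kind is ResonanceKind.DD22:
        return count_two_quanta_pairs(n_modes)
    raise ValueError(f"no closed-form count for {kind}")


# ---------------------------------------------------------------------------
# scheme indices
# ---------------------------------------------------------------------------

FERMI_SCHEMES = ("R12MART", "R12CVPT", "R12WFRQ", "R12COEF")
DD_SCHEMES = ("R11HRS", "R11WFRQ", "R11COEF", "R22HRS")


def fermi_first_order_element(kind: ResonanceKind, phi: float) -> float:
    """<1_i|H1|partner>: phi/4 for an overtone partner, phi/(2 sqrt2) for a
    combination partner."""
    return phi / 4.0 if kind is ResonanceKind.FERMI_I else phi / (2.0 * SQRT2)


def fermi_index(
    candidate: ResonanceCandidate,
    field: AnharmonicField,
    scheme: str,
    wfrq_power: int = 2,
) -> float:
    """Resonance index of a Fermi candidate under the requested scheme.

    Monotone increasing in |phi| and decreasing in |Delta|; returns ``inf``
    for an exact degeneracy (auto-accept).
    """
    if scheme not in FERMI_SCHEMES:
        raise ValueError(f"unknown Fermi scheme {scheme!r}")
    i, j, k = candidate.indices
    phi = abs(field.get_cubic(i, j, k))
    if phi == 0.0:
        return 0.0
    delta = abs(candidate.delta)
    if delta == 0.0:
        logger.info("exact degeneracy for triad %s: auto-accepted", candidate.indices)
        return math.inf
    if scheme == "R12MART":
        pref = 256.0 if candidate.kind is ResonanceKind.FERMI_I else 64.0
        return phi**4 / (pref * delta**3)
    if scheme == "R12WFRQ":
        pref = 256.0 if candidate.kind is ResonanceKind.FERMI_I else 64.0
        return phi**4 / (pref * delta ** (3 + wfrq_power))
    if scheme == "R12CVPT":
        return phi / (2.0 * SQRT2 * delta)
    # R12COEF: first-order coefficient |<partner|H1|1_i>| / |Delta|
    return abs(fermi_first_order_element(candidate.kind, phi)) / delta


def dd_coupling(
    candidate: ResonanceCandidate,
    harm: HarmonicModel,
    field: AnharmonicField,
    regularize: bool = True,
) -> float:
    """Effective Darling-Dennison coupling W (cm-1) for the candidate pair."""
    h1 = cubic_operator(field)
    h2 = quartic_operator(field)
    a = dict(candidate.bra.quanta)
    b = dict(candidate.ket.quanta)
    return effective_coupling(
        tuple(sorted(a.items())), tuple(sorted(b.items())),
        h1, h2, harm.omega, regularize=regularize,
    )


def dd_second_order_coefficient(
    candidate: ResonanceCandidate,
    harm: HarmonicModel,
    field: AnharmonicField,
) -> float:
    """Second-order RSPT coefficient of |ket> in the perturbed |bra>.

    c = [ sum_u H1_{ket,u} H1_{u,bra} / (E_bra - E_u)  +  H2_{ket,bra} ]
        / (E_bra - E_ket)

    with internal Fermi-like denominators rewritten in regularised form.
    Signed; returns ``inf`` on exact degeneracy.
    """
    h1 = cubic_operator(field)
    h2 = quartic_operator(field)
    w = harm.omega
    a: QKey = tuple(sorted(dict(candidate.bra.quanta).items()))
    b: QKey = tuple(sorted(dict(candidate.ket.quanta).items()))
    ea, eb = key_energy(a, w), key_energy(b, w)
    if ea == eb:
        return math.inf
    ha = apply_operator({a: 1.0}, h1)
    hb = apply_operator({b: 1.0}, h1)
    num = complex(overlap({b: 1.0}, apply_operator({a: 1.0}, h2)))
    for u, amp_a in ha.items():
        if u in (a, b) or u not in hb:
            continue
        term = (hb[u].conjugate() * amp_a).real
        num += hdcpt2_term(term, ea - key_energy(u, w))
    return float(num.real) / (ea - eb)


def dd_index(
    candidate: ResonanceCandidate,
    harm: HarmonicModel,
    field: AnharmonicField,
    scheme: str,
    coupling: float | None = None,
) -> float:
    """Darling-Dennison resonance index under the requested scheme.

    ``coupling`` may carry a precomputed effective coupling to avoid
    recomputation during database construction.
    """
    if scheme not in DD_SCHEMES:
        raise ValueError(f"unknown DD scheme {scheme!r}")
    delta = abs(candidate.delta)
    if scheme in ("R11HRS", "R22HRS"):
        w = dd_coupling(candidate, harm, field) if coupling is None else coupling
        return abs(w)
    if delta == 0.0:
        logger.info("exact degeneracy for DD pair %s: auto-accepted", candidate.indices)
        return math.inf
    if scheme == "R11WFRQ":
        w = dd_coupling(candidate, harm, field) if coupling is None else coupling
        return abs(w) / delta**2
    # R11COEF
    return abs(dd_second_order_coefficient(candidate, harm, field))


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

@dataclass
class KindConfig:
    """Window and thresholds for one resonance kind (energies in cm-1)."""
    window: float
    energy_scheme: str | None = None
    energy_threshold: float = math.inf
    intensity_scheme: str | None = None
    intensity_threshold: float = math.inf


@dataclass
class ResonanceConfig:
    """Default protocol: R12MART/R12COEF for Fermi, R11HRS/R11COEF for 1-1
    DD and R22HRS for 2-2 DD, with the recommended thresholds."""
    fermi: KindConfig = dfield(default_factory=lambda: KindConfig(
        window=200.0, energy_scheme="R12MART", energy_threshold=1.0,
        intensity_scheme="R12COEF", intensity_threshold=0.1))
    dd11: KindConfig = dfield(default_factory=lambda: KindConfig(
        window=100.0, energy_scheme="R11HRS", energy_threshold=10.0,
        intensity_scheme="R11COEF", intensity_threshold=0.3))
    dd22: KindConfig = dfield(default_factory=lambda: KindConfig(
        window=100.0, energy_scheme="R22HRS", energy_threshold=20.0))

    def validate(self) -> None:
        for name, cfg, valid in (
            ("fermi", self.fermi, FERMI_SCHEMES),
            ("dd11", self.dd11, DD_SCHEMES),
            ("dd22", self.dd22, DD_SCHEMES),
        ):
            for sch in (cfg.energy_scheme, cfg.intensity_scheme):
                if sch is not None and sch not in valid:
                    raise ValueError(f"unknown scheme {sch!r} for {name}")


@dataclass
class AcceptedResonance:
    candidate: ResonanceCandidate
    indices_by_scheme: dict[str, float]
    triggered_by: tuple[str, ...]
    user_added: bool = False


class ResonanceDB:
    """Accepted resonances indexed by state pair, with per-scheme indices,
    the triggering scheme(s), and a cache of perturbative coefficients.

    Entries can be amended after automatic generation (``add``/``remove``),
    replacing or complementing the automated identification.
    """

    def __init__(self) -> None:
        self._entries: dict[frozenset, AcceptedResonance] = {}
        self.coef_cache: dict[tuple, float] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[AcceptedResonance]:
        return iter(self._entries.values())

    def entries(self) -> list[AcceptedResonance]:
        return list(self._entries.values())

    def add(
        self,
        candidate: ResonanceCandidate,
        indices_by_scheme: dict[str, float] | None = None,
        triggered_by: Iterable[str] = (),
        user_added: bool = False,
    ) -> None:
        key = candidate.pair_key()
        self._entries[key] = AcceptedResonance(
            candidate=candidate,
            indices_by_scheme=dict(indices_by_scheme or {}),
            triggered_by=tuple(triggered_by) or (("user",) if user_added else ()),
            user_added=user_added,
        )

    def remove(self, bra: VibState, ket: VibState) -> bool:
        return self._entries.pop(frozenset((bra, ket)), None) is not None

    def get(self, bra: VibState, ket: VibState) -> AcceptedResonance | None:
        return self._entries.get(frozenset((bra, ket)))

    def is_pair(self, bra: VibState, ket: VibState) -> bool:
        return frozenset((bra, ket)) in self._entries

    def is_pair_keys(self, a: QKey, b: QKey) -> bool:
        return frozenset((VibState(a), VibState(b))) in self._entries

    def is_fermi(self, i: int, j: int, k: int) -> bool:
        """Whether the triad omega_i ~ omega_j + omega_k is accepted."""
        return self.is_pair(VibState.fundamental(i), VibState.combination(j, k))

    def fermi_entries(self) -> list[AcceptedResonance]:
        return [e for e in self if e.candidate.kind in
                (ResonanceKind.FERMI_I, ResonanceKind.FERMI_II)]

    def dd_entries(self) -> list[AcceptedResonance]:
        return [e for e in self if e.candidate.kind in
                (ResonanceKind.DD11, ResonanceKind.DD22, ResonanceKind.DD211)]

    def to_records(self) -> list[dict]:
        out = []
        for e in self:
            c = e.candidate
            out.append({
                "kind": c.kind.value,
                "bra": c.bra.as_dict(),
                "ket": c.ket.as_dict(),
                "delta": c.delta,
                "coupling": c.coupling,
                "indices": list(c.indices),
                "scheme_indices": {
                    k: (None if math.isinf(v) else v)
                    for k, v in e.indices_by_scheme.items()
                },
                "triggered_by": list(e.triggered_by),
                "user_added": e.user_added,
            })
        return out


class _VanVleckCache:
    """Caches H1/H2 applications per state for fast pairwise couplings."""

    def __init__(self, field: AnharmonicField, omega: np.ndarray) -> None:
        self.h1 = cubic_operator(field)
        self.h2 = quartic_operator(field)
        self.omega = omega
        self._h1app: dict[QKey, dict] = {}
        self._h2app: dict[QKey, dict] = {}

    def h1_applied(self, key: QKey) -> dict:
        if key not in self._h1app:
            self._h1app[key] = apply_operator({key: 1.0}, self.h1)
        return self._h1app[key]

    def h2_applied(self, key: QKey) -> dict:
        if key not in self._h2app:
            self._h2app[key] = apply_operator({key: 1.0}, self.h2)
        return self._h2app[key]

    def coupling(self, a: QKey, b: QKey) -> float:
        """Van Vleck effective coupling with regularised internal denominators."""
        ha, hb = self.h1_applied(a), self.h1_applied(b)
        ea, eb = key_energy(a, self.omega), key_energy(b, self.omega)
        total = complex(self.h2_applied(a).get(b, 0.0))
        for u, amp_a in ha.items():
            if u == a or u == b or u not in hb:
                continue
            num = (amp_a.conjugate() * hb[u]).real
            total += 0.5 * hdcpt2_term(num, ea - key_energy(u, self.omega))
            total += 0.5 * hdcpt2_term(num, eb - key_energy(u, self.omega))
        return float(total.real)

    def coef2(self, a: QKey, b: QKey) -> float:
        """Signed second-order RSPT coefficient of |b> in perturbed |a>."""
        ea, eb = key_energy(a, self.omega), key_energy(b, self.omega)
        if ea == eb:
            return math.inf
        ha, hb = self.h1_applied(a), self.h1_applied(b)
        num = complex(self.h2_applied(a).get(b, 0.0))
        for u, amp_a in ha.items():
            if u in (a, b) or u not in hb:
                continue
            term = (hb[u].conjugate() * amp_a).real
            num += hdcpt2_term(term, ea - key_energy(u, self.omega))
        return float(num.real) / (ea - eb)


def _qkey(state: VibState) -> QKey:
    return tuple(sorted(state.as_dict().items()))


def build_resonance_db(
    harm: HarmonicModel,
    field: AnharmonicField,
    config: ResonanceConfig | None = None,
) -> ResonanceDB:
    """Automatic a-priori resonance identification.

    For each kind, candidates inside the energy window are scored; a candidate
    passing the energy test OR the intensity test is inserted with the scheme
    indices and the trigger recorded.  First-order Fermi coefficients and
    second-order DD coefficients are cached for later use (pseudoeigenvectors,
    moment bookkeeping).  Deterministic for fixed input.
    """
    config = config or ResonanceConfig()
    config.validate()
    db = ResonanceDB()
    w = harm.omega

    def check(value: float, threshold: float) -> bool:
        return value >= threshold

    # --- Fermi ------------------------------------------------------
    cfg = config.fermi
    for cand in enumerate_fermi_candidates(w, cfg.window):
        i, j, k = cand.indices
        phi = field.get_cubic(i, j, k)
        if phi == 0.0:
            continue
        element = fermi_first_order_element(cand.kind, phi)
        coef = (math.inf if cand.delta == 0.0 else element / cand.delta)
        db.coef_cache[("fermi1", i, j, k)] = coef
        indices: dict[str, float] = {}
        triggered = []
        for label, scheme, thr in (
            ("energy", cfg.energy_scheme, cfg.energy_threshold),
            ("intensity", cfg.intensity_scheme, cfg.intensity_threshold),
        ):
            if scheme is None:
                continue
            idx = fermi_index(cand, field, scheme)
            indices[scheme] = idx
            if check(idx, thr):
                triggered.append(scheme)
        if triggered:
            cand = ResonanceCandidate(
                kind=cand.kind, bra=cand.bra, ket=cand.ket, delta=cand.delta,
                indices=cand.indices, coupling=float(element),
            )
            db.add(cand, indices, triggered)

    # --- Darling-Dennison (shared Van Vleck cache) ------------------
    vv = _VanVleckCache(field, w)

    def score_dd(cand: ResonanceCandidate, cfg: KindConfig):
        a, b = _qkey(cand.bra), _qkey(cand.ket)
        coupling = vv.coupling(a, b)
        delta = abs(cand.delta)
        indices: dict[str, float] = {}
        triggered = []
        c2 = None
        for scheme, thr in (
            (cfg.energy_scheme, cfg.energy_threshold),
            (cfg.intensity_scheme, cfg.intensity_threshold),
        ):
            if scheme is None:
                continue
            if scheme in ("R11HRS", "R22HRS"):
                idx = abs(coupling)
            elif delta == 0.0:
                idx = math.inf
            elif scheme == "R11WFRQ":
                idx = abs(coupling) / delta**2
            else:  # R11COEF
                c2 = vv.coef2(a, b)
                idx = abs(c2)
            indices[scheme] = idx
            if check(idx, thr):
                triggered.append(scheme)
        return coupling, indices, triggered, c2

    cfg = config.dd11
    for cand in enumerate_dd_candidates(w, ResonanceKind.DD11, cfg.window):
        coupling, indices, triggered, c2 = score_dd(cand, cfg)
        i, j = cand.indices
        if c2 is None:
            c2 = vv.coef2(_qkey(cand.bra), _qkey(cand.ket))
        db.coef_cache[("dd2", i, j)] = (0.0 if math.isinf(abs(c2)) else c2)
        if triggered:
            db.add(ResonanceCandidate(
                kind=cand.kind, bra=cand.bra, ket=cand.ket, delta=cand.delta,
                indices=cand.indices, coupling=coupling,
            ), indices, triggered)

    cfg = config.dd22
    for cand in enumerate_dd_candidates(w, ResonanceKind.DD22, cfg.window):
        coupling, indices, triggered, _ = score_dd(cand, cfg)
        if triggered and (coupling != 0.0 or abs(cand.delta) == 0.0):
            db.add(ResonanceCandidate(
                kind=cand.kind, bra=cand.bra, ket=cand.ket, delta=cand.delta,
                indices=cand.indices, coupling=coupling,
            ), indices, triggered)
    logger.info("resonance database built: %d accepted", len(db))
    return db
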