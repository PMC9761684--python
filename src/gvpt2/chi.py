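"""Anharmonicity-constant matrix (chi), zero-point energy and VPT2 state
energies.

The working equations are the standard second-order perturbative results for
the Watson Hamiltonian restricted to J = 0 (the mass-dependent Watson term is
dropped, as it cancels in transition energies):

    E(v) = eps0 + sum_i omega_i (v_i + 1/2)
                + sum_{i<=j} chi_ij (v_i + 1/2)(v_j + 1/2)

with the chi elements assembled from the quartic force field, squares of
cubic constants over frequency-sum/difference denominators, and Coriolis
contributions.  Every difference-type denominator is tracked with the Fermi
triad it corresponds to, which makes the deperturbed (DVPT2) variant a
term-by-term removal and lets the HDCPT2-style regularisation rewrite the
same terms in a bounded, continuous form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

from .model import AnharmonicField, HarmonicModel
from .operators import hdcpt2_term
from .states import VibState

if TYPE_CHECKING:  # pragma: no cover
    from .resonance import ResonanceDB

logger = logging.getLogger("gvpt2")


class EnergyLevel(str, Enum):
    VPT2 = "VPT2"
    DVPT2 = "DVPT2"
    HDCPT2 = "HDCPT2"


class SingularChiError(ZeroDivisionError):
    pass


@dataclass
class ChiMatrix:
    chi: np.ndarray                  # (n, n) symmetric, cm-1
    eps0: float                      # anharmonic ZPE above sum(omega)/2, cm-1
    omega: np.ndarray
    removed_terms: list[tuple[str, tuple[int, ...]]] = dfield(default_factory=list)
    regularization: str = "none"

    @property
    def n_modes(self) -> int:
        return self.chi.shape[0]

    def zpe(self) -> float:
        """Total anharmonic zero-point energy (Watson term excluded), cm-1."""
        return float(self.omega.sum() / 2.0 + self.eps0)

    def to_json(self) -> dict:
        return {
            "chi_cm-1": self.chi.tolist(),
            "eps0_cm-1": self.eps0,
            "omega_cm-1": self.omega.tolist(),
            "regularization": self.regularization,
            "removed_terms": [[kind, list(idx)] for kind, idx in self.removed_terms],
        }

    def to_csv(self, path) -> None:
        """Chi matrix as CSV (modes 1..n), with eps0 and the removed-term
        ledger in trailing comment lines."""
        import csv
        from pathlib import Path

        with Path(path).open("w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["mode"] + [str(i) for i in range(1, self.n_modes + 1)])
            for i in range(self.n_modes):
                wr.writerow([str(i + 1)] + [f"{x:.10g}" for x in self.chi[i]])
        with Path(path).open("a") as fh:
            fh.write(f"# eps0_cm-1,{self.eps0:.10g}\n")
            for kind, idx in self.removed_terms:
                fh.write(f"# removed,{kind},{':'.join(map(str, idx))}\n")


def _resonant_value(
    num: float,
    delta: float,
    triad: tuple[int, int, int],
    mode: EnergyLevel,
    resdb: "ResonanceDB | None",
    removed: list[tuple[str, tuple[int, ...]]],
) -> float:
    """Value of a resonance-prone term num/delta under the requested scheme.

    ``triad`` = (i, j, k) means the denominator is omega_i - omega_j - omega_k.
    """
    if mode is EnergyLevel.DVPT2 and resdb is not None and resdb.is_fermi(*triad):
        removed.append(("fermi", triad))
        return 0.0
    if mode is EnergyLevel.HDCPT2:
        return hdcpt2_term(num, delta)
    if delta == 0.0:
        raise SingularChiError(
            f"exact resonance omega_{triad[0]} = omega_{triad[1]} + omega_{triad[2]} "
            "in plain VPT2; use DVPT2/HDCPT2 or amend the resonance list"
        )
    return num / delta


def compute_chi(
    harm: HarmonicModel,
    field: AnharmonicField,
    resdb: "ResonanceDB | None" = None,
    mode: EnergyLevel | str = EnergyLevel.VPT2,
) -> ChiMatrix:
    """Assemble the chi matrix and the anharmonic ZPE correction.

    mode = VPT2   : plain second order (raises on exact resonance);
    mode = DVPT2  : terms whose denominator matches an accepted Fermi
                    resonance in ``resdb`` are omitted and recorded;
    mode = HDCPT2 : every difference denominator is replaced by the bounded
                    degeneracy-corrected hybrid, finite for any input.
    """
    mode = EnergyLevel(mode)
    if mode is EnergyLevel.DVPT2 and resdb is None:
        raise ValueError("DVPT2 requires a resonance database")
    n = harm.n_modes
    w = harm.omega
    chi = np.zeros((n, n))
    removed: list[tuple[str, tuple[int, ...]]] = []

    def k3(i, j, k):
        return field.get_cubic(i, j, k)

    # diagonal elements
    for i in range(1, n + 1):
        val = field.get_quartic(i, i, i, i) / 16.0
        for j in range(1, n + 1):
            kij = k3(i, i, j)
            if kij == 0.0:
                continue
            if j == i:
                val -= 5.0 * kij * kij / (48.0 * w[i - 1])
                continue
            # 2/w_j and 1/(2w_i + w_j) pieces are never resonant; the
            # 1/(2w_i - w_j) piece corresponds to the type-I triad (j; i, i)
            val -= kij * kij / 16.0 * (2.0 / w[j - 1] + 0.5 / (2 * w[i - 1] + w[j - 1]))
            val += _resonant_value(
                kij * kij / 32.0,
                2 * w[i - 1] - w[j - 1],
                (j, i, i),
                mode,
                resdb,
                removed,
            )
        chi[i - 1, i - 1] = val

    # off-diagonal elements
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            val = field.get_quartic(i, i, j, j) / 4.0
            for k in range(1, n + 1):
                kik = k3(i, i, k)
                kjk = k3(j, j, k)
                if kik and kjk:
                    val -= kik * kjk / (4.0 * w[k - 1])
                kijk = k3(i, j, k)
                if kijk:
                    # -(k^2/8) [1/s + 1/d1 + 1/d2 - 1/d3] with
                    # d1 = w_j+w_k-w_i etc.; rewritten over the Fermi-triad
                    # gaps Delta = w_a - w_b - w_c the signs flip
                    c = kijk * kijk / 8.0
                    val -= c / (w[i - 1] + w[j - 1] + w[k - 1])
                    if k != i:
                        # -1/d1 -> + c / (w_i - w_j - w_k): Fermi triad (i; j, k)
                        val += _resonant_value(
                            c, w[i - 1] - w[j - 1] - w[k - 1], (i, j, k),
                            mode, resdb, removed,
                        )
                    if k != j:
                        # -1/d2 -> + c / (w_j - w_i - w_k): Fermi triad (j; i, k)
                        val += _resonant_value(
                            c, w[j - 1] - w[i - 1] - w[k - 1], (j, i, k),
                            mode, resdb, removed,
                        )
                    if k != i and k != j:
                        # +1/d3 -> - c / (w_k - w_i - w_j): Fermi triad (k; i, j)
                        val -= _resonant_value(
                            c, w[k - 1] - w[i - 1] - w[j - 1], (k, i, j),
                            mode, resdb, removed,
                        )
            if harm.zeta is not None and harm.B_eq is not None:
                z2 = float(np.sum(harm.B_eq * harm.zeta[:, i - 1, j - 1] ** 2))
                val += z2 * (w[i - 1] / w[j - 1] + w[j - 1] / w[i - 1])
            chi[i - 1, j - 1] = chi[j - 1, i - 1] = val

    eps0 = _zpe_correction(field, w)
    if mode is EnergyLevel.HDCPT2 and not np.all(np.isfinite(chi)):
        raise AssertionError("HDCPT2 chi must be finite")  # defensive
    return ChiMatrix(
        chi=chi,
        eps0=eps0,
        omega=w.copy(),
        removed_terms=removed,
        regularization="HDCPT2" if mode is EnergyLevel.HDCPT2 else "none",
    )


def _zpe_correction(field: AnharmonicField, w: np.ndarray) -> float:
    """Second-order correction to the zero-point energy (no Watson term, no
    Coriolis ZPE contribution; see the package methods note)."""
    n = w.size
    val = 0.0
    for idx, K in field.quartic.items():
        s = set(idx)
        if len(s) == 1:
            val += K / 32.0
        elif len(s) == 2 and idx[0] == idx[1] and idx[2] == idx[3]:
            val += K / 16.0
    for (a, b, c), k in field.cubic.items():
        if k == 0.0:
            continue
        if a == b == c:
            val -= k * k / (144.0 * w[a - 1])
        elif a == b:  # k_iij pattern (i=a repeated, j=c)
            val -= k * k / (16.0 * (w[c - 1] + 2 * w[a - 1]))
        elif b == c:  # k_ijj with i=a, j=b
            val -= k * k / (16.0 * (w[a - 1] + 2 * w[b - 1]))
        else:
            val -= k * k / (8.0 * (w[a - 1] + w[b - 1] + w[c - 1]))
    # single-quantum intermediates pool every k_ppi
    for i in range(1, n + 1):
        tot = sum(field.get_cubic(p, p, i) for p in range(1, n + 1))
        if tot:
            val -= tot * tot / (32.0 * w[i - 1])
    return float(val)


def state_energy(chi: ChiMatrix, state: VibState) -> float:
    """Anharmonic energy of ``state`` relative to the ground state (cm-1),

        E(v) - E(0) = sum_i v_i omega_i
                    + sum_{i<=j} chi_ij [ (v_i+1/2)(v_j+1/2) - 1/4 ].
    """
    state.validate(chi.n_modes)
    w = chi.omega
    e = state.harmonic_energy(w)
    q = state.as_dict()
    modes = list(q)
    for a, i in enumerate(modes):
        vi = q[i]
        e += chi.chi[i - 1, i - 1] * ((vi + 0.5) ** 2 - 0.25)
        # cross terms with all other modes: only excited ones shift the
        # (1/2)(1/2) ground-state product
        for j in modes[a + 1:]:
            vj = q[j]
            e += chi.chi[i - 1, j - 1] * ((vi + 0.5) * (vj + 0.5) - 0.25)
        # modes at v=0 contribute chi_ij * (vi+1/2 - 1/2) * 1/2
        for j in range(1, chi.n_modes + 1):
            if j not in q:
                e += chi.chi[i - 1, j - 1] * 0.5 * vi
    return float(e)
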