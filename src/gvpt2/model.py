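"""Core domain containers: harmonic model, anharmonic force field, property
surfaces, and the VibData bundle tying them together.

Unit conventions
----------------
* energies, harmonic wavenumbers, cubic and quartic force constants: cm-1,
  expressed over dimensionless (reduced) normal coordinates;
* rotational constants: cm-1;
* property derivatives: atomic units (conversion to spectroscopic units is
  deferred to the spectra stage);
* normal-mode matrix L: mass-weighted Cartesian displacements per unit of
  dimensionless normal coordinate, columns normalised to unit Euclidean norm
  with the phase fixed so the largest-magnitude element is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("gvpt2")

ZETA_ANTISYM_TOL = 1e-8


class MissingConstantError(KeyError):
    """A force constant required by the working equations is unavailable."""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


def canonical_triple(i: int, j: int, k: int) -> tuple[int, int, int]:
    return tuple(sorted((i, j, k)))  # type: ignore[return-value]


def canonical_quad(i: int, j: int, k: int, l: int) -> tuple[int, int, int, int]:
    return tuple(sorted((i, j, k, l)))  # type: ignore[return-value]


def is_semidiagonal(idx: Sequence[int]) -> bool:
    """True when a quartic index pattern has at most 3 distinct indices.

    Two-step numerical differentiation (Hessians at geometries displaced along
    one mode at a time, twice) yields only K_{ab,cc} patterns, i.e. at least
    one repeated index.
    """
    return len(set(idx)) <= 3


@dataclass
class HarmonicModel:
    """Harmonic description: wavenumbers, normal modes, rotational constants
    and Coriolis couplings."""

    n_atoms: int
    omega: np.ndarray                      # (n_modes,) cm-1, ascending
    L: np.ndarray | None = None            # (3*n_atoms, n_modes)
    B_eq: np.ndarray | None = None         # (3,) cm-1
    zeta: np.ndarray | None = None         # (3, n_modes, n_modes)
    geometry: np.ndarray | None = None     # (n_atoms, 3) Angstrom
    linear: bool = False

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 1:
            raise ValidationError("omega must be a vector")
        neg = np.nonzero(self.omega <= 0)[0]
        if neg.size:
            raise ValidationError(
                "non-positive harmonic wavenumbers at modes "
                + ", ".join(str(i + 1) for i in neg)
            )
        if np.any(np.diff(self.omega) < 0):
            raise ValidationError("omega must be sorted ascending")
        n_expected = 3 * self.n_atoms - (5 if self.linear else 6)
        # tiny fixtures (1-3 modes) are allowed to carry fewer modes than the
        # 3N-6 count implies; more than that is a shape error
        if self.n_modes > max(n_expected, 1):
            raise ValidationError(
                f"{self.n_modes} modes inconsistent with {self.n_atoms} atoms"
            )
        if self.L is not None:
            self.L = np.asarray(self.L, dtype=float)
            if self.L.shape != (3 * self.n_atoms, self.n_modes):
                raise ValidationError(
                    f"L shape {self.L.shape} != {(3 * self.n_atoms, self.n_modes)}"
                )
            self.L = fix_mode_phases(normalize_columns(self.L))
        if self.B_eq is not None:
            self.B_eq = np.asarray(self.B_eq, dtype=float).reshape(3)
        if self.zeta is not None:
            self.zeta = np.asarray(self.zeta, dtype=float)
            if self.zeta.shape != (3, self.n_modes, self.n_modes):
                raise ValidationError(f"zeta shape {self.zeta.shape} invalid")
            asym = np.abs(self.zeta + self.zeta.transpose(0, 2, 1)).max()
            if asym > ZETA_ANTISYM_TOL:
                raise ValidationError(
                    f"Coriolis zeta not antisymmetric (max |z_ij + z_ji| = {asym:.2e})"
                )
        if self.geometry is not None:
            self.geometry = np.asarray(self.geometry, dtype=float).reshape(self.n_atoms, 3)

    @property
    def n_modes(self) -> int:
        return self.omega.size


def n_normal_modes(n_atoms: int, linear: bool = False) -> int:
    """3N-6 (nonlinear) or 3N-5 (linear) vibrational degrees of freedom."""
    return 3 * n_atoms - (5 if linear else 6)


def normalize_columns(L: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(L, axis=0)
    if np.any(norms == 0):
        raise ValidationError("zero normal-mode column")
    return L / norms


def fix_mode_phases(L: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each column positive.

    Removes the sign ambiguity of normal modes that would otherwise flip the
    signs of cubic force constants between runs.
    """
    L = L.copy()
    for c in range(L.shape[1]):
        k = np.argmax(np.abs(L[:, c]))
        if L[k, c] < 0:
            L[:, c] = -L[:, c]
    return L


class AnharmonicField:
    """Cubic k_ijk and semidiagonal quartic K_ijkl force constants (cm-1).

    Values are stored once per canonically sorted index tuple and retrieved
    for any index permutation (full permutational symmetry).  Off-semidiagonal
    quartic elements are *unavailable* by default rather than zero, mirroring
    the limits of two-step numerical differentiation; set
    ``has_full_quartic=True`` (or ``missing_as_zero=True`` on query) to change
    this behaviour.
    """

    def __init__(
        self,
        cubic: Mapping[tuple[int, int, int], float] | None = None,
        quartic: Mapping[tuple[int, int, int, int], float] | None = None,
        has_full_quartic: bool = False,
    ) -> None:
        self.cubic: dict[tuple[int, int, int], float] = {}
        self.quartic: dict[tuple[int, int, int, int], float] = {}
        self.has_full_quartic = bool(has_full_quartic)
        for idx, v in (cubic or {}).items():
            self.set_cubic(*idx, value=float(v))
        for idx, v in (quartic or {}).items():
            self.set_quartic(*idx, value=float(v))

    # -- cubic --------------------------------------------------------
    def set_cubic(self, i: int, j: int, k: int, value: float) -> None:
        self.cubic[canonical_triple(i, j, k)] = float(value)

    def get_cubic(self, i: int, j: int, k: int, default: float = 0.0) -> float:
        return self.cubic.get(canonical_triple(i, j, k), default)

    # -- quartic ------------------------------------------------------
    def set_quartic(self, i: int, j: int, k: int, l: int, value: float) -> None:
        idx = canonical_quad(i, j, k, l)
        if not is_semidiagonal(idx) and not self.has_full_quartic:
            raise ValidationError(
                f"quartic {idx} is off-semidiagonal; set has_full_quartic=True to store it"
            )
        self.quartic[idx] = float(value)

    def get_quartic(
        self, i: int, j: int, k: int, l: int, missing_as_zero: bool = False
    ) -> float:
        idx = canonical_quad(i, j, k, l)
        if idx in self.quartic:
            return self.quartic[idx]
        if is_semidiagonal(idx) or self.has_full_quartic or missing_as_zero:
            return 0.0
        raise MissingConstantError(
            f"quartic constant K{idx} is off-semidiagonal and unavailable"
        )

    def quartic_available(self, i: int, j: int, k: int, l: int) -> bool:
        return self.has_full_quartic or is_semidiagonal(canonical_quad(i, j, k, l))

    # -- bookkeeping --------------------------------------------------
    def modes_touched(self) -> set[int]:
        out: set[int] = set()
        for idx in self.cubic:
            out.update(idx)
        for idx in self.quartic:
            out.update(idx)
        return out

    def max_mode(self) -> int:
        touched = self.modes_touched()
        return max(touched) if touched else 0

    def copy(self) -> "AnharmonicField":
        return AnharmonicField(dict(self.cubic), dict(self.quartic), self.has_full_quartic)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnharmonicField):
            return NotImplemented
        return (
            self.cubic == other.cubic
            and self.quartic == other.quartic
            and self.has_full_quartic == other.has_full_quartic
        )


@dataclass
class PropertySurface:
    """Taylor data of a molecular property over the normal coordinates.

    ``S`` is +1 for properties that are functions of the coordinates (electric
    dipole) and -1 for functions of the conjugate momenta (magnetic dipole);
    for S=-1 the semidiagonal third derivatives do not fully permute and only
    the stored P_{i,jj} patterns are available.  The prefactors s0/s1/s2/s3
    default to a plain Taylor expansion (1, 1, 1/2, 1/6); other conventions
    can be supplied per property.
    """

    name: str
    n_components: int
    S: int = +1
    P0: np.ndarray | None = None           # (components,)
    P1: np.ndarray | None = None           # (n_modes, components)
    P2: np.ndarray | None = None           # (n_modes, n_modes, components)
    # P_{i,jj} patterns: {(i, j): vector of components}
    P3_semidiag: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    s0: float = 1.0
    s1: float = 1.0
    s2: float = 0.5
    s3: float = 1.0 / 6.0
    units: str = "au"

    def __post_init__(self) -> None:
        if self.S not in (+1, -1):
            raise ValidationError("S must be +1 or -1")
        if self.P0 is not None:
            self.P0 = np.asarray(self.P0, dtype=float).reshape(self.n_components)
        if self.P1 is not None:
            self.P1 = np.asarray(self.P1, dtype=float)
            if self.P1.shape[1] != self.n_components:
                raise ValidationError(f"P1 shape {self.P1.shape} invalid")
        if self.P2 is not None:
            self.P2 = np.asarray(self.P2, dtype=float)
            n = self.P2.shape[0]
            if self.P2.shape != (n, n, self.n_components):
                raise ValidationError(f"P2 shape {self.P2.shape} invalid")
            if self.S == +1:
                asym = np.abs(self.P2 - self.P2.transpose(1, 0, 2)).max()
                if asym > 1e-8:
                    raise ValidationError(
                        f"P2 not index-symmetric for S=+1 property (max asym {asym:.2e})"
                    )
        self.P3_semidiag = {
            (int(i), int(j)): np.asarray(v, dtype=float).reshape(self.n_components)
            for (i, j), v in self.P3_semidiag.items()
        }

    @property
    def n_modes(self) -> int:
        if self.P1 is not None:
            return self.P1.shape[0]
        if self.P2 is not None:
            return self.P2.shape[0]
        return 0

    def third_available(self, i: int, j: int, k: int) -> bool:
        """Whether P_ijk is available; only P_{i,jj} patterns are stored."""
        if len({i, j, k}) == 3:
            return False
        if j == k:
            return (i, j) in self.P3_semidiag
        if i == j:
            return (k, i) in self.P3_semidiag
        if i == k:
            return (j, i) in self.P3_semidiag
        return False

    def get_third(self, i: int, j: int, k: int) -> np.ndarray:
        """P_ijk component vector for a semidiagonal pattern.

        For S=+1 the indices permute freely; for S=-1 only the stored
        (odd-index, repeated-pair) pattern is defined and other orders raise.
        """
        if j == k and (i, j) in self.P3_semidiag:
            return self.P3_semidiag[(i, j)]
        if self.S == +1:
            if i == j and (k, i) in self.P3_semidiag:
                return self.P3_semidiag[(k, i)]
            if i == k and (j, i) in self.P3_semidiag:
                return self.P3_semidiag[(j, i)]
        raise MissingConstantError(
            f"third derivative P_({i},{j},{k}) of property {self.name!r} unavailable"
        )

    def copy(self) -> "PropertySurface":
        return PropertySurface(
            name=self.name,
            n_components=self.n_components,
            S=self.S,
            P0=None if self.P0 is None else self.P0.copy(),
            P1=None if self.P1 is None else self.P1.copy(),
            P2=None if self.P2 is None else self.P2.copy(),
            P3_semidiag={k: v.copy() for k, v in self.P3_semidiag.items()},
            s0=self.s0, s1=self.s1, s2=self.s2, s3=self.s3,
            units=self.units,
        )


@dataclass
class VibData:
    """The full input bundle: harmonic model + force field + property surfaces."""

    harmonic: HarmonicModel
    field: AnharmonicField
    properties: list[PropertySurface] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.properties is None:
            self.properties = []
        n = self.harmonic.n_modes
        mx = self.field.max_mode()
        if mx > n:
            raise ValidationError(
                f"force field touches mode {mx} but only {n} modes are declared"
            )
        for p in self.properties:
            if p.n_modes and p.n_modes != n:
                raise ValidationError(
                    f"property {p.name!r} has {p.n_modes} modes, expected {n}"
                )

    @property
    def n_modes(self) -> int:
        return self.harmonic.n_modes

    def property_by_name(self, name: str) -> PropertySurface:
        for p in self.properties:
            if p.name == name:
                return p
        raise KeyError(f"no property surface named {name!r}")


# ---------------------------------------------------------------------------
# force-field validation from redundant numerical estimates
# ---------------------------------------------------------------------------

@dataclass
class RedundancyReport:
    deviations: dict[tuple[int, ...], float]
    canonical: dict[tuple[int, ...], float]
    tol: float

    @property
    def passed(self) -> bool:
        return all(d < self.tol for d in self.deviations.values())

    @property
    def max_deviation(self) -> float:
        return max(self.deviations.values(), default=0.0)


def validate_force_field(
    estimates: Mapping[tuple[int, ...], Iterable[float]], tol: float = 1.0
) -> RedundancyReport:
    """Check agreement between redundant numerical estimates of force constants.

    Anharmonic constants obtained by displacement along different normal
    coordinates should agree; fluctuations flag an unconverged minimum or an
    unstable electronic-structure step.  Deviations (max - min within a group)
    below ``tol`` cm-1 pass, and the canonical value is the group mean.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    deviations: dict[tuple[int, ...], float] = {}
    canonical: dict[tuple[int, ...], float] = {}
    for idx, group in estimates.items():
        vals = [float(v) for v in group]
        if not vals:
            raise ValueError(f"empty estimate group for constant {idx}")
        deviations[tuple(idx)] = max(vals) - min(vals)
        canonical[tuple(idx)] = sum(vals) / len(vals)
    for idx, dev in deviations.items():
        if dev >= tol:
            logger.warning("force constant %s deviates by %.3f cm-1 (tol %.3f)", idx, dev, tol)
    return RedundancyReport(deviations=deviations, canonical=canonical, tol=tol)


# ---------------------------------------------------------------------------
# active-mode masking (reduced-dimensionality treatment)
# ---------------------------------------------------------------------------

def mask_active_modes(bundle: VibData, active: set[int]) -> VibData:
    """Restrict the anharmonic treatment to a subset of 'active' modes.

    Every cubic/quartic constant and property derivative carrying any index
    outside ``active`` is zeroed (dropped); harmonic data are untouched.  This
    reproduces the usual way large-amplitude motions (e.g. methyl torsions)
    are excluded from a quartic-force-field treatment.  Idempotent.
    """
    active = {int(a) for a in active}
    if not active:
        raise ValueError("active set is empty: nothing to treat anharmonically")
    n = bundle.n_modes
    if not active <= set(range(1, n + 1)):
        raise ValueError(f"active modes {sorted(active - set(range(1, n + 1)))} out of range")

    fld = AnharmonicField(has_full_quartic=bundle.field.has_full_quartic)
    for idx, v in bundle.field.cubic.items():
        if set(idx) <= active:
            fld.cubic[idx] = v
    for idx, v in bundle.field.quartic.items():
        if set(idx) <= active:
            fld.quartic[idx] = v

    props: list[PropertySurface] = []
    for p in bundle.properties:
        q = p.copy()
        if q.P1 is not None:
            for m in range(1, q.P1.shape[0] + 1):
                if m not in active:
                    q.P1[m - 1, :] = 0.0
        if q.P2 is not None:
            for m in range(1, q.P2.shape[0] + 1):
                if m not in active:
                    q.P2[m - 1, :, :] = 0.0
                    q.P2[:, m - 1, :] = 0.0
        q.P3_semidiag = {
            (i, j): v for (i, j), v in q.P3_semidiag.items() if {i, j} <= active
        }
        props.append(q)
    return VibData(harmonic=bundle.harmonic, field=fld, properties=props)
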