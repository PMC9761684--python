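"""Vibrational states as sparse vectors of quanta in the harmonic basis.

Mode indices are 1-based throughout the public API, following the
spectroscopic convention ("mode 18" is the 18th mode in ascending
harmonic-wavenumber order).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class VibState:
    """A harmonic-basis vibrational state |v> as a sparse map mode -> quanta.

    The ground state is the empty map.  Instances are immutable and hashable
    so they can key resonance and polyad tables.
    """

    quanta: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        items = tuple(sorted((int(m), int(n)) for m, n in dict(self.quanta).items() if n != 0))
        for m, n in items:
            if m < 1:
                raise ValueError(f"mode index {m} is not 1-based positive")
            if n < 0:
                raise ValueError(f"negative quantum count {n} for mode {m}")
        object.__setattr__(self, "quanta", items)

    # -- constructors -------------------------------------------------
    @classmethod
    def ground(cls) -> "VibState":
        return cls(())

    @classmethod
    def fundamental(cls, i: int) -> "VibState":
        return cls(((i, 1),))

    @classmethod
    def overtone(cls, i: int) -> "VibState":
        return cls(((i, 2),))

    @classmethod
    def combination(cls, i: int, j: int) -> "VibState":
        if i == j:
            return cls.overtone(i)
        return cls(((i, 1), (j, 1)))

    @classmethod
    def from_dict(cls, d: dict[int, int]) -> "VibState":
        return cls(tuple(d.items()))

    # -- queries ------------------------------------------------------
    def as_dict(self) -> dict[int, int]:
        return dict(self.quanta)

    def count(self, mode: int) -> int:
        return dict(self.quanta).get(mode, 0)

    @property
    def total_quanta(self) -> int:
        return sum(n for _, n in self.quanta)

    @property
    def modes(self) -> tuple[int, ...]:
        return tuple(m for m, _ in self.quanta)

    def harmonic_energy(self, omega) -> float:
        """Energy above the harmonic ground state, sum_i v_i * omega_i (cm-1)."""
        return float(sum(n * omega[m - 1] for m, n in self.quanta))

    def validate(self, n_modes: int) -> None:
        for m, _ in self.quanta:
            if not 1 <= m <= n_modes:
                raise ValueError(f"mode index {m} outside [1, {n_modes}]")

    def label(self) -> str:
        """Spectroscopic label, e.g. '0' (ground), 'v18', '2v4', 'v2+v11'."""
        if not self.quanta:
            return "0"
        parts = []
        for m, n in self.quanta:
            parts.append(f"v{m}" if n == 1 else f"{n}v{m}")
        return "+".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"VibState({self.label()})"
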