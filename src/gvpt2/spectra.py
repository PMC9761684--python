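"""Stick spectra, broadening, and spectroscopic unit conversions.

Dipole strengths are carried in the customary 1e-40 esu^2 cm^2 and rotatory
strengths in 1e-44 esu^2 cm^2.  IR intensity enters the molar absorptivity as
nu * D and VCD as nu * R with the textbook prefactors pinned in one place
below (they are applied only at this stage; everything upstream stays in
atomic units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

# ---------------------------------------------------------------------------
# pinned conversion constants
# ---------------------------------------------------------------------------

#: electric dipole, atomic units (e a0) -> esu cm
DIPOLE_AU_TO_ESU_CM = 2.541746e-18
#: magnetic dipole, Bohr magnetons -> esu cm equivalent (CGS-Gaussian)
MAGNETIC_AU_TO_ESU_CM = 9.274010e-21
#: D[esu^2 cm^2] = EPS_TO_D * integral( eps(nu)/nu dnu );  Chiroptical convention
EPS_TO_DIPOLE = 9.184e-39
#: R[esu^2 cm^2] = EPS_TO_R * integral( delta_eps(nu)/nu dnu )
EPS_TO_ROTATORY = 2.296e-39


def dipole_strength(mu: np.ndarray) -> float:
    """|<0|mu|f>|^2 in 1e-40 esu^2 cm^2, mu in atomic units."""
    return float(np.sum(np.abs(mu) ** 2) * DIPOLE_AU_TO_ESU_CM**2 * 1e40)


def rotatory_strength(mu: np.ndarray, mag: np.ndarray) -> float:
    """Im(<0|mu|f> . <f|m|0>) in 1e-44 esu^2 cm^2.

    ``mu`` (electric, e a0) is real up to numerical noise; ``mag`` (magnetic,
    Bohr magnetons) is the complex amplitude <0|m|f>, so <f|m|0> is its
    conjugate.
    """
    dot = complex(np.sum(np.asarray(mu) * np.conj(np.asarray(mag))))
    return float(dot.imag * DIPOLE_AU_TO_ESU_CM * MAGNETIC_AU_TO_ESU_CM * 1e44)


def ir_stick_strength(nu: float, d_40: float) -> float:
    """Integrated molar absorptivity (L mol-1 cm-2) of one IR stick."""
    return nu * d_40 * 1e-40 / EPS_TO_DIPOLE


def vcd_stick_strength(nu: float, r_44: float) -> float:
    """Integrated differential molar absorptivity of one VCD stick."""
    return nu * r_44 * 1e-44 / EPS_TO_ROTATORY


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StickSpectrum:
    sticks: list[tuple[float, float]]        # (position cm-1, signed strength)
    kind: str = "generic"                    # IR | VCD | generic

    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.sticks])

    def strengths(self) -> np.ndarray:
        return np.array([s for _, s in self.sticks])


@dataclass
class BandShape:
    grid: np.ndarray
    values: np.ndarray
    kind: str = "generic"
    broadening: str = "lorentzian"
    hwhm: float = 0.0
    shift: float = 0.0
    metadata: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve contains non-finite values")


# ---------------------------------------------------------------------------
# broadening
# ---------------------------------------------------------------------------

DEFAULT_GRID_STEP = 0.2  # cm-1; resolves the narrowest HWHM in common use (2 cm-1)


def default_grid(sticks: StickSpectrum | list, hwhm: float,
                 pad_hwhm: float = 10.0, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    pos = sticks.positions() if isinstance(sticks, StickSpectrum) else np.array(
        [p for p, _ in sticks])
    lo = float(pos.min()) - pad_hwhm * hwhm
    hi = float(pos.max()) + pad_hwhm * hwhm
    return np.arange(lo, hi + step, step)


def _lorentz(x: np.ndarray, x0: float, hwhm: float) -> np.ndarray:
    return (hwhm / math.pi) / ((x - x0) ** 2 + hwhm**2)


def _gauss(x: np.ndarray, x0: float, hwhm: float) -> np.ndarray:
    sigma = hwhm / math.sqrt(2.0 * math.log(2.0))
    return np.exp(-((x - x0) ** 2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))


def convolve(
    sticks: StickSpectrum | list,
    shape: str = "lorentzian",
    hwhm: float = 2.0,
    grid: np.ndarray | None = None,
    shift: float = 0.0,
) -> BandShape:
    """Broaden a stick spectrum with unit-area kernels.

    Each stick contributes strength * kernel(position + shift); the result is
    linear in the strengths and equivariant under shifting (shifting sticks
    then convolving equals translating the convolved curve, grid permitting).
    """
    if hwhm <= 0:
        raise ValueError("hwhm must be positive")
    shape = shape.lower()
    if shape not in ("lorentzian", "gaussian"):
        raise ValueError(f"unknown broadening shape {shape!r}")
    if isinstance(sticks, list):
        sticks = StickSpectrum(sticks=list(sticks))
    if grid is None:
        grid = default_grid(sticks, hwhm)
    grid = np.asarray(grid, dtype=float)
    kernel = _lorentz if shape == "lorentzian" else _gauss
    vals = np.zeros_like(grid)
    for pos, strength in sticks.sticks:
        if strength == 0.0:
            continue
        vals += strength * kernel(grid, pos + shift, hwhm)
    return BandShape(grid=grid, values=vals, kind=sticks.kind,
                     broadening=shape, hwhm=hwhm, shift=shift)


# ---------------------------------------------------------------------------
# curve comparison
# ---------------------------------------------------------------------------

def compare_curves(a: BandShape, b: BandShape) -> dict[str, float]:
    """Normalized inner product and signed-area difference of two curves.

    Curves are linearly resampled on the overlap of their grids; disjoint
    ranges raise.  The inner product is symmetric, 1.0 for identical curves
    and -1.0 for a curve against its negation.
    """
    lo = max(a.grid[0], b.grid[0])
    hi = min(a.grid[-1], b.grid[-1])
    if hi <= lo:
        raise ValueError("curve ranges are disjoint")
    step = min(np.min(np.diff(a.grid)), np.min(np.diff(b.grid)))
    x = np.arange(lo, hi + step / 2, step)
    ya = np.interp(x, a.grid, a.values)
    yb = np.interp(x, b.grid, b.values)
    na = math.sqrt(float(np.trapezoid(ya * ya, x)))
    nb = math.sqrt(float(np.trapezoid(yb * yb, x)))
    if na == 0.0 or nb == 0.0:
        ov = 0.0
    else:
        ov = float(np.trapezoid(ya * yb, x)) / (na * nb)
    area_diff = float(np.trapezoid(ya - yb, x))
    return {"overlap": ov, "signed_area_difference": area_diff}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def bandshape_to_csv(shape: BandShape, path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["wavenumber_cm-1", shape.kind])
        for x, y in zip(shape.grid, shape.values):
            wr.writerow([f"{x:.6g}", f"{y:.10g}"])
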