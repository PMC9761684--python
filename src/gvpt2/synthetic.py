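"""Synthetic vibrational systems with planted resonances.

The generator emulates the data a quartic-force-field calculation on a
medium-size semirigid molecule would deliver -- harmonic wavenumbers spread
over the mid-IR, sparse zero-mean cubic/semidiagonal-quartic backgrounds of a
few cm-1, and dipole surfaces of typical atomic-unit magnitudes -- and then
plants Fermi or 1-1 Darling-Dennison resonances with exact energy gaps and
requested coupling magnitudes.  Bundles are reproducible: the same plan and
seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .model import AnharmonicField, HarmonicModel, PropertySurface, VibData
from .resonance import ResonanceKind


class InfeasiblePlanError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedFeature:
    """One resonance to realize exactly: kind, target gap Delta (cm-1) and
    coupling magnitude (cm-1).

    For FERMI_I the gap is omega_i - 2 omega_j, for FERMI_II
    omega_i - (omega_j + omega_k), for DD11 omega_i - omega_j; the coupling is
    the cubic constant phi (Fermi) or the effective quartic-driven coupling W
    (DD11, realized through K_iiij = 8 W).
    """
    kind: ResonanceKind
    delta: float
    coupling: float
    base_omega: float | None = None     # partner frequency; drawn when None


@dataclass
class ResonancePlan:
    n_modes: int = 24
    planted: list[PlantedFeature] = dfield(default_factory=list)
    omega_range: tuple[float, float] = (400.0, 1800.0)
    cubic_scale: float = 5.0            # zero-mean background magnitude, cm-1
    quartic_scale: float = 5.0
    n_background_cubic: int | None = None   # default 2 * n_modes
    dipole_scale: float = 0.05          # first-derivative magnitude, e a0
    magnetic_scale: float = 5e-3        # Bohr magnetons
    with_properties: bool = True
    seed: int = 0


@dataclass(frozen=True)
class RealizedFeature:
    kind: ResonanceKind
    modes: tuple[int, ...]              # (i, j, k) Fermi / (i, j) DD11, 1-based
    delta: float
    coupling: float


@dataclass
class GeneratedBundle:
    bundle: VibData
    features: list[RealizedFeature]


def _required_modes(f: PlantedFeature) -> int:
    return 3 if f.kind is ResonanceKind.FERMI_II else 2


def generate(plan: ResonancePlan) -> GeneratedBundle:
    """Realize a plan into a validated VibData bundle plus a manifest of the
    planted features with their final (sorted-order) mode indices."""
    rng = np.random.default_rng(plan.seed)
    lo, hi = plan.omega_range
    if hi <= lo or lo <= 0:
        raise InfeasiblePlanError(f"bad omega range {plan.omega_range}")
    need = sum(_required_modes(f) for f in plan.planted)
    if need > plan.n_modes:
        raise InfeasiblePlanError(
            f"plan needs {need} modes for planted features but n_modes={plan.n_modes}"
        )

    # frequencies of planted partners first, tracked by a tag
    tagged: list[tuple[float, int, int]] = []   # (omega, feature idx, role)
    for fi, f in enumerate(plan.planted):
        if f.kind is ResonanceKind.FERMI_I:
            wj = f.base_omega or float(rng.uniform(lo + 0.25 * (hi - lo), 0.45 * (lo + hi)))
            wi = 2.0 * wj + f.delta
            if wi <= 0 or wj <= 0:
                raise InfeasiblePlanError(f"feature {fi}: derived frequency non-positive")
            tagged += [(wi, fi, 0), (wj, fi, 1)]
        elif f.kind is ResonanceKind.FERMI_II:
            wj = f.base_omega or float(rng.uniform(lo, 0.5 * (lo + hi)))
            wk = float(rng.uniform(lo, 0.5 * (lo + hi)))
            wi = wj + wk + f.delta
            if min(wi, wj, wk) <= 0:
                raise InfeasiblePlanError(f"feature {fi}: derived frequency non-positive")
            tagged += [(wi, fi, 0), (wj, fi, 1), (wk, fi, 2)]
        elif f.kind is ResonanceKind.DD11:
            wj = f.base_omega or float(rng.uniform(lo, hi))
            wi = wj + f.delta
            if min(wi, wj) <= 0:
                raise InfeasiblePlanError(f"feature {fi}: derived frequency non-positive")
            tagged += [(wi, fi, 0), (wj, fi, 1)]
        else:
            raise InfeasiblePlanError(f"cannot plant resonance kind {f.kind}")

    n_bg = plan.n_modes - len(tagged)
    bg = rng.uniform(lo, hi, size=n_bg)
    all_w = np.array([w for w, _, _ in tagged] + list(bg))
    if np.unique(all_w).size != all_w.size:
        all_w = all_w + rng.uniform(0, 1e-9, size=all_w.size)  # break exact ties
    order = np.argsort(all_w, kind="stable")
    omega = all_w[order]
    # position (1-based) of each original entry after sorting
    pos = np.empty_like(order)
    pos[order] = np.arange(1, plan.n_modes + 1)

    feature_modes: dict[int, dict[int, int]] = {}
    for t, (_, fi, role) in enumerate(tagged):
        feature_modes.setdefault(fi, {})[role] = int(pos[t])

    n_atoms = max(2, -(-(plan.n_modes + 6) // 3))   # smallest N with 3N-6 >= n_modes
    rot = np.sort(rng.uniform(0.1, 2.0, size=3))[::-1]
    harm = HarmonicModel(n_atoms=n_atoms, omega=omega, B_eq=rot)

    field = AnharmonicField()
    n = plan.n_modes
    # background: diagonal quartics and a sparse set of cubics
    if plan.quartic_scale > 0:
        for i in range(1, n + 1):
            field.set_quartic(i, i, i, i, float(rng.normal(0.0, plan.quartic_scale)))
    if plan.cubic_scale > 0:
        for i in range(1, n + 1):
            field.set_cubic(i, i, i, float(rng.normal(0.0, plan.cubic_scale)))
        n_bg_cubic = plan.n_background_cubic
        if n_bg_cubic is None:
            n_bg_cubic = 2 * n
        for _ in range(n_bg_cubic):
            i, j, k = (int(x) + 1 for x in rng.integers(0, n, size=3))
            field.set_cubic(i, j, k, float(rng.normal(0.0, plan.cubic_scale)))

    realized: list[RealizedFeature] = []
    for fi, f in enumerate(plan.planted):
        roles = feature_modes[fi]
        if f.kind is ResonanceKind.FERMI_I:
            i, j = roles[0], roles[1]
            field.set_cubic(i, j, j, f.coupling)
            realized.append(RealizedFeature(f.kind, (i, j, j), f.delta, f.coupling))
        elif f.kind is ResonanceKind.FERMI_II:
            i, j, k = roles[0], roles[1], roles[2]
            jj, kk = sorted((j, k))
            field.set_cubic(i, jj, kk, f.coupling)
            realized.append(RealizedFeature(f.kind, (i, jj, kk), f.delta, f.coupling))
        else:  # DD11: drive the effective coupling through K_iiij = 8 W
            i, j = roles[0], roles[1]
            field.set_quartic(i, i, i, j, 8.0 * f.coupling)
            realized.append(RealizedFeature(f.kind, tuple(sorted((i, j))), f.delta, f.coupling))

    props: list[PropertySurface] = []
    if plan.with_properties:
        p2 = rng.normal(0.0, plan.dipole_scale / 10.0, size=(n, n, 3))
        p2 = 0.5 * (p2 + p2.transpose(1, 0, 2))
        props.append(PropertySurface(
            name="electric_dipole", n_components=3, S=+1,
            P0=rng.normal(0.0, 0.2, size=3),
            P1=rng.normal(0.0, plan.dipole_scale, size=(n, 3)),
            P2=p2,
            P3_semidiag={(i, i): rng.normal(0.0, plan.dipole_scale / 100.0, size=3)
                         for i in range(1, n + 1)},
        ))
        props.append(PropertySurface(
            name="magnetic_dipole", n_components=3, S=-1,
            P1=rng.normal(0.0, plan.magnetic_scale, size=(n, 3)),
            P2=rng.normal(0.0, plan.magnetic_scale / 10.0, size=(n, n, 3)),
        ))
    return GeneratedBundle(
        bundle=VibData(harmonic=harm, field=field, properties=props),
        features=realized,
    )
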