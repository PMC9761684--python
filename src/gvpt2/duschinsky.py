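"""Duschinsky consistency check between two electronic-structure levels.

Hybrid schemes pair a high-level harmonic description with a lower-level
anharmonic force field.  That is only meaningful when the two sets of normal
modes describe the same motions: the lower-level mass-weighted coordinates
are expressed on the basis of the higher-level ones,

    Q^L = J Q^H + K,     J = (L^H)^T L^L,

and the modes are declared equivalent when every row and column of J has
exactly one squared element above a threshold (0.9 by default).  K measures
the equilibrium-geometry displacement; it is reported but never used for the
pass/fail decision (any real geometric difference already contaminates J).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np


@dataclass
class DuschinskyResult:
    J: np.ndarray                      # (n_modes, n_modes)
    K: np.ndarray                      # (n_modes,)
    max_sq_row: np.ndarray
    max_sq_col: np.ndarray
    warnings: list[str] = dfield(default_factory=list)


@dataclass
class CorrespondenceReport:
    passed: bool
    mapping: dict[int, int]            # high-level mode -> low-level mode (1-based)
    offending_rows: list[int]
    offending_cols: list[int]
    threshold: float


def _eckart_align(geom: np.ndarray, ref: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted Kabsch superposition of ``geom`` onto ``ref``."""
    w = masses[:, None]
    gc = geom - (w * geom).sum(0) / masses.sum()
    rc = ref - (w * ref).sum(0) / masses.sum()
    h = (w * gc).T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return gc @ rot.T


def duschinsky(
    L_high: np.ndarray,
    L_low: np.ndarray,
    geom_high: np.ndarray | None = None,
    geom_low: np.ndarray | None = None,
    masses: np.ndarray | None = None,
    k_warn: float = 0.1,
) -> DuschinskyResult:
    """Duschinsky rotation J and shift K between two mode sets.

    Geometries (n_atoms, 3) are optional; when provided with masses they are
    brought to a common Eckart frame before K is formed.  Atom ordering and
    masses must match between the levels.
    """
    L_high = np.asarray(L_high, dtype=float)
    L_low = np.asarray(L_low, dtype=float)
    if L_high.shape != L_low.shape:
        raise ValueError(f"mode-matrix shapes differ: {L_high.shape} vs {L_low.shape}")
    warnings: list[str] = []
    j = L_high.T @ L_low
    n_modes = j.shape[0]
    k = np.zeros(n_modes)
    if geom_high is not None and geom_low is not None:
        gh = np.asarray(geom_high, dtype=float)
        gl = np.asarray(geom_low, dtype=float)
        if gh.shape != gl.shape:
            raise ValueError("geometry shapes (atom counts) differ between levels")
        if masses is None:
            masses = np.ones(gh.shape[0])
        masses = np.asarray(masses, dtype=float)
        gl_aligned = _eckart_align(gl, gh, masses)
        gh_centered = _eckart_align(gh, gh, masses)
        disp = (np.sqrt(masses)[:, None] * (gl_aligned - gh_centered)).ravel()
        k = L_high.T @ disp
        if np.linalg.norm(k) > k_warn:
            warnings.append(
                f"|K| = {np.linalg.norm(k):.3g} exceeds {k_warn}: equilibrium "
                "geometries differ noticeably between levels"
            )
    j2 = j**2
    row_sums = j2.sum(axis=1)
    col_sums = j2.sum(axis=0)
    if np.abs(row_sums - 1).max() > 1e-6 or np.abs(col_sums - 1).max() > 1e-6:
        warnings.append(
            "J is not orthogonal (row/col squared sums deviate from 1): the "
            "two mode sets do not span the same space"
        )
    return DuschinskyResult(
        J=j, K=k,
        max_sq_row=j2.max(axis=1),
        max_sq_col=j2.max(axis=0),
        warnings=warnings,
    )


def check_correspondence(
    result: DuschinskyResult, threshold: float = 0.9
) -> CorrespondenceReport:
    """Pass iff every row and column of J has exactly one squared element
    above ``threshold``; the resulting mode mapping is returned on pass."""
    j2 = result.J**2
    n = j2.shape[0]
    bad_rows = [r + 1 for r in range(n) if int((j2[r, :] > threshold).sum()) != 1]
    bad_cols = [c + 1 for c in range(n) if int((j2[:, c] > threshold).sum()) != 1]
    passed = not bad_rows and not bad_cols
    mapping: dict[int, int] = {}
    if passed:
        for r in range(n):
            mapping[r + 1] = int(np.argmax(j2[r, :])) + 1
    return CorrespondenceReport(
        passed=passed, mapping=mapping,
        offending_rows=bad_rows, offending_cols=bad_cols,
        threshold=threshold,
    )


def report_json(result: DuschinskyResult, report: CorrespondenceReport) -> dict:
    return {
        "passed": report.passed,
        "threshold": report.threshold,
        "mapping": report.mapping,
        "offending_rows": report.offending_rows,
        "offending_cols": report.offending_cols,
        "max_sq_row": result.max_sq_row.tolist(),
        "max_sq_col": result.max_sq_col.tolist(),
        "K_norm": float(np.linalg.norm(result.K)),
        "warnings": result.warnings,
    }
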