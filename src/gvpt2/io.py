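"""VibData file I/O.

The interchange format is versioned JSON with blocks mirroring the sections a
quantum-chemistry driver would emit in formatted text: HARMONIC, CUBIC
(rows ``[i, j, k, value]``), QUARTIC, and one PROPERTY block per surface.
Energies and force constants are exchanged exclusively in cm-1 over
dimensionless normal coordinates; property derivatives in atomic units.
Floats are serialised at full repr precision, so save -> load round-trips
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .model import (
    AnharmonicField,
    HarmonicModel,
    PropertySurface,
    ValidationError,
    VibData,
)

logger = logging.getLogger("gvpt2")

FORMAT_NAME = "vibdata"
FORMAT_VERSION = 1


class ParseError(ValueError):
    pass


HDF5_SUFFIXES = {".h5", ".hdf5"}


def save_vibdata(bundle: VibData, path: str | Path) -> None:
    """Write a bundle; JSON by default, HDF5 for ``.h5``/``.hdf5`` paths
    (preferred for large bundles)."""
    if Path(path).suffix.lower() in HDF5_SUFFIXES:
        _save_hdf5(bundle, Path(path))
        return
    h = bundle.harmonic
    doc: dict = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "units": {"energy": "cm-1", "property": "au"},
        "harmonic": {
            "n_atoms": h.n_atoms,
            "linear": h.linear,
            "omega": h.omega.tolist(),
        },
    }
    if h.L is not None:
        doc["harmonic"]["L"] = h.L.tolist()
    if h.B_eq is not None:
        doc["harmonic"]["B_eq"] = h.B_eq.tolist()
    if h.zeta is not None:
        doc["harmonic"]["zeta"] = h.zeta.tolist()
    if h.geometry is not None:
        doc["harmonic"]["geometry"] = h.geometry.tolist()
    doc["cubic"] = [[*idx, v] for idx, v in sorted(bundle.field.cubic.items())]
    doc["quartic"] = [[*idx, v] for idx, v in sorted(bundle.field.quartic.items())]
    doc["has_full_quartic"] = bundle.field.has_full_quartic
    doc["properties"] = []
    for p in bundle.properties:
        pd: dict = {
            "name": p.name,
            "n_components": p.n_components,
            "S": p.S,
            "s0": p.s0, "s1": p.s1, "s2": p.s2, "s3": p.s3,
            "units": p.units,
        }
        if p.P0 is not None:
            pd["P0"] = p.P0.tolist()
        if p.P1 is not None:
            pd["P1"] = p.P1.tolist()
        if p.P2 is not None:
            pd["P2"] = p.P2.tolist()
        if p.P3_semidiag:
            pd["P3_semidiag"] = [[i, j, *v.tolist()] for (i, j), v in sorted(p.P3_semidiag.items())]
        doc["properties"].append(pd)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_vibdata(path: str | Path) -> VibData:
    """Load and validate a VibData bundle.

    Missing optional blocks (zeta, properties, L) yield empty defaults with a
    logged warning; structural inconsistencies raise.
    """
    path = Path(path)
    if path.suffix.lower() in HDF5_SUFFIXES:
        return _load_hdf5(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}") from None
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise ParseError(f"{path}: missing or wrong format declaration (expected {FORMAT_NAME!r})")
    if doc.get("version") != FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported format version {doc.get('version')!r}")
    units = doc.get("units", {})
    if units.get("energy", "cm-1") != "cm-1":
        raise ParseError(f"{path}: energy units must be cm-1, got {units.get('energy')!r}")

    hd = doc.get("harmonic")
    if hd is None:
        raise ParseError(f"{path}: missing HARMONIC block")
    omega = np.asarray(hd.get("omega", []), dtype=float)
    n_modes = omega.size
    harm = HarmonicModel(
        n_atoms=int(hd["n_atoms"]),
        omega=omega,
        L=np.asarray(hd["L"], dtype=float) if "L" in hd else None,
        B_eq=np.asarray(hd["B_eq"], dtype=float) if "B_eq" in hd else None,
        zeta=np.asarray(hd["zeta"], dtype=float) if "zeta" in hd else None,
        geometry=np.asarray(hd["geometry"], dtype=float) if "geometry" in hd else None,
        linear=bool(hd.get("linear", False)),
    )
    if harm.zeta is None:
        logger.warning("%s: no Coriolis zeta block; assuming zero couplings", path.name)
    if harm.L is None:
        logger.warning("%s: no normal-mode matrix; pseudoeigenvectors unavailable", path.name)

    fld = AnharmonicField(has_full_quartic=bool(doc.get("has_full_quartic", False)))
    for row in doc.get("cubic", []):
        if len(row) != 4:
            raise ParseError(f"{path}: malformed CUBIC row {row!r}")
        i, j, k, v = row
        _check_mode_range((i, j, k), n_modes, path)
        fld.set_cubic(int(i), int(j), int(k), float(v))
    for row in doc.get("quartic", []):
        if len(row) != 5:
            raise ParseError(f"{path}: malformed QUARTIC row {row!r}")
        i, j, k, l, v = row
        _check_mode_range((i, j, k, l), n_modes, path)
        fld.set_quartic(int(i), int(j), int(k), int(l), float(v))

    props: list[PropertySurface] = []
    for pd in doc.get("properties", []):
        nc = int(pd["n_components"])
        p3 = {}
        for row in pd.get("P3_semidiag", []):
            i, j = int(row[0]), int(row[1])
            p3[(i, j)] = np.asarray(row[2:], dtype=float)
        props.append(PropertySurface(
            name=str(pd["name"]),
            n_components=nc,
            S=int(pd.get("S", +1)),
            P0=np.asarray(pd["P0"], dtype=float) if "P0" in pd else None,
            P1=np.asarray(pd["P1"], dtype=float) if "P1" in pd else None,
            P2=np.asarray(pd["P2"], dtype=float) if "P2" in pd else None,
            P3_semidiag=p3,
            s0=float(pd.get("s0", 1.0)),
            s1=float(pd.get("s1", 1.0)),
            s2=float(pd.get("s2", 0.5)),
            s3=float(pd.get("s3", 1.0 / 6.0)),
            units=str(pd.get("units", "au")),
        ))
    if not props:
        logger.warning("%s: no property surfaces; only energies can be computed", path.name)
    return VibData(harmonic=harm, field=fld, properties=props)


def _save_hdf5(bundle: VibData, path: Path) -> None:
    import h5py  # optional dependency, only needed for .h5 bundles

    h = bundle.harmonic
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = FORMAT_NAME
        fh.attrs["version"] = FORMAT_VERSION
        fh.attrs["energy_units"] = "cm-1"
        g = fh.create_group("harmonic")
        g.attrs["n_atoms"] = h.n_atoms
        g.attrs["linear"] = h.linear
        g.create_dataset("omega", data=h.omega)
        for name in ("L", "B_eq", "zeta", "geometry"):
            arr = getattr(h, name)
            if arr is not None:
                g.create_dataset(name, data=arr)
        fh.create_dataset("cubic", data=np.array(
            [[*idx, v] for idx, v in sorted(bundle.field.cubic.items())]
            or np.empty((0, 4))))
        fh.create_dataset("quartic", data=np.array(
            [[*idx, v] for idx, v in sorted(bundle.field.quartic.items())]
            or np.empty((0, 5))))
        fh.attrs["has_full_quartic"] = bundle.field.has_full_quartic
        pg = fh.create_group("properties")
        for p in bundle.properties:
            sub = pg.create_group(p.name)
            sub.attrs.update({"n_components": p.n_components, "S": p.S,
                              "s0": p.s0, "s1": p.s1, "s2": p.s2, "s3": p.s3,
                              "units": p.units})
            for name in ("P0", "P1", "P2"):
                arr = getattr(p, name)
                if arr is not None:
                    sub.create_dataset(name, data=arr)
            if p.P3_semidiag:
                sub.create_dataset("P3_semidiag", data=np.array(
                    [[i, j, *v] for (i, j), v in sorted(p.P3_semidiag.items())]))


def _load_hdf5(path: Path) -> VibData:
    import h5py

    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != FORMAT_NAME:
            raise ParseError(f"{path}: missing or wrong format declaration")
        if int(fh.attrs.get("version", -1)) != FORMAT_VERSION:
            raise ParseError(f"{path}: unsupported format version")
        g = fh["harmonic"]
        harm = HarmonicModel(
            n_atoms=int(g.attrs["n_atoms"]),
            omega=np.asarray(g["omega"]),
            L=np.asarray(g["L"]) if "L" in g else None,
            B_eq=np.asarray(g["B_eq"]) if "B_eq" in g else None,
            zeta=np.asarray(g["zeta"]) if "zeta" in g else None,
            geometry=np.asarray(g["geometry"]) if "geometry" in g else None,
            linear=bool(g.attrs.get("linear", False)),
        )
        fld = AnharmonicField(has_full_quartic=bool(fh.attrs["has_full_quartic"]))
        for row in np.asarray(fh["cubic"]).reshape(-1, 4):
            fld.set_cubic(int(row[0]), int(row[1]), int(row[2]), float(row[3]))
        for row in np.asarray(fh["quartic"]).reshape(-1, 5):
            fld.set_quartic(int(row[0]), int(row[1]), int(row[2]), int(row[3]),
                            float(row[4]))
        props = []
        for name, sub in fh["properties"].items():
            p3 = {}
            if "P3_semidiag" in sub:
                for row in np.asarray(sub["P3_semidiag"]):
                    p3[(int(row[0]), int(row[1]))] = np.asarray(row[2:])
            props.append(PropertySurface(
                name=name,
                n_components=int(sub.attrs["n_components"]),
                S=int(sub.attrs["S"]),
                P0=np.asarray(sub["P0"]) if "P0" in sub else None,
                P1=np.asarray(sub["P1"]) if "P1" in sub else None,
                P2=np.asarray(sub["P2"]) if "P2" in sub else None,
                P3_semidiag=p3,
                s0=float(sub.attrs["s0"]), s1=float(sub.attrs["s1"]),
                s2=float(sub.attrs["s2"]), s3=float(sub.attrs["s3"]),
                units=str(sub.attrs["units"]),
            ))
    return VibData(harmonic=harm, field=fld, properties=props)


def _check_mode_range(idx, n_modes: int, path: Path) -> None:
    for m in idx:
        if not 1 <= int(m) <= n_modes:
            raise ValidationError(
                f"{path}: force-constant index {int(m)} outside [1, {n_modes}]"
            )
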