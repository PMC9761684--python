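"""End-to-end run: data preparation, a-priori resonance analysis, energies,
transition moments, and convolved spectra.

Artifacts (all CSV/JSON, deterministic for fixed input and configuration):

* ``config.json``      -- effective configuration echo
* ``resonances.json``  -- the resonance database
* ``polyads.json``     -- polyad report
* ``energies.csv``     -- harmonic / DVPT2 / GVPT2 energies with assignments
* ``sticks_<prop>.csv``-- stick table per spectroscopy (band position,
  dipole strength in 1e-40 esu^2 cm^2, rotatory strength in 1e-44 esu^2 cm^2)
* ``spectrum_<kind>.csv`` -- broadened bandshapes
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path

import numpy as np

from .chi import EnergyLevel, compute_chi, state_energy
from .io import load_vibdata
from .model import VibData
from .moments import project_gvpt2, transition_moment
from .polyad import build_polyads
from .resonance import KindConfig, ResonanceConfig, ResonanceDB, build_resonance_db, two_quanta_states
from .spectra import (
    StickSpectrum,
    convolve,
    bandshape_to_csv,
    dipole_strength,
    ir_stick_strength,
    rotatory_strength,
    vcd_stick_strength,
)
from .states import VibState
from .variational import GVPT2Result, assemble_and_diagonalize

logger = logging.getLogger("gvpt2")


@dataclass
class SpectrumOptions:
    kinds: tuple[str, ...] = ("ir",)
    shape: str = "lorentzian"
    hwhm: float = 2.0
    shift: float = 0.0
    grid_step: float = 0.2


@dataclass
class RunConfig:
    input: str | None = None
    level: str = "GVPT2"                 # VPT2 | DVPT2 | GVPT2
    resonances: ResonanceConfig = dfield(default_factory=ResonanceConfig)
    spectra: SpectrumOptions = dfield(default_factory=SpectrumOptions)
    output_dir: str = "gvpt2_out"
    seed: int = 0

    _KNOWN = {"input", "level", "resonances", "spectra", "output_dir", "seed"}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls()
        for k in ("input", "level", "output_dir", "seed"):
            if k in d:
                setattr(cfg, k, d[k])
        if "resonances" in d:
            rc = ResonanceConfig()
            for kind, sub in d["resonances"].items():
                if kind not in ("fermi", "dd11", "dd22"):
                    raise ValueError(f"unknown resonance kind {kind!r}")
                setattr(rc, kind, KindConfig(**sub))
            cfg.resonances = rc
        if "spectra" in d:
            cfg.spectra = SpectrumOptions(**{
                **d["spectra"],
                "kinds": tuple(d["spectra"].get("kinds", ("ir",))),
            })
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    bundle: VibData
    resdb: ResonanceDB
    energies: dict[VibState, dict[str, float]]
    gvpt2: GVPT2Result | None
    sticks: dict[str, StickSpectrum]
    artifacts: dict[str, Path]
    warnings: list[str]


def run_pipeline(config: RunConfig, bundle: VibData | None = None) -> PipelineResult:
    """Execute the four-stage protocol and write all artifacts.

    ``bundle`` may be passed directly; otherwise ``config.input`` is loaded.
    """
    warnings: list[str] = []
    if bundle is None:
        if not config.input:
            raise ValueError("no input bundle")
        bundle = load_vibdata(config.input)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    level = config.level.upper()
    if level not in ("VPT2", "DVPT2", "GVPT2"):
        raise ValueError(f"unknown level {config.level!r}")

    # (i) data preparation is the bundle itself; (ii) resonance analysis
    if level == "VPT2":
        resdb = ResonanceDB()
    else:
        resdb = build_resonance_db(bundle.harmonic, bundle.field, config.resonances)

    # (iii) energies
    chi_mode = EnergyLevel.VPT2 if level == "VPT2" else EnergyLevel.DVPT2
    chi = compute_chi(bundle.harmonic, bundle.field, resdb, chi_mode)
    space = two_quanta_states(bundle.n_modes)
    dvpt2 = {s: state_energy(chi, s) for s in space}
    harm_e = {s: s.harmonic_energy(bundle.harmonic.omega) for s in space}

    gvpt2: GVPT2Result | None = None
    final_e = dict(dvpt2)
    if level == "GVPT2":
        pdb = build_polyads(resdb, space)
        gvpt2 = assemble_and_diagonalize(pdb, dvpt2)
        for s in space:
            final_e[s] = gvpt2.energy_of(s)

    energies = {
        s: {"harmonic": harm_e[s], "DVPT2": dvpt2[s], level: final_e[s]}
        for s in space
    }

    # (iv) transition moments and sticks
    moment_level = "VPT2" if level == "VPT2" else "DVPT2"
    from .moments import MomentContext
    ctx = MomentContext(bundle, resdb, moment_level) if bundle.properties else None
    prop_moments: dict[str, dict[VibState, np.ndarray]] = {}
    for surf in bundle.properties:
        vals: dict[VibState, np.ndarray] = {}
        incomplete = False
        for s in space:
            tm = transition_moment(s, bundle, surf, resdb, level=moment_level,
                                   context=ctx)
            vals[s] = tm.value
            incomplete = incomplete or tm.incomplete
        if incomplete:
            warnings.append(
                f"property {surf.name!r}: second/third-derivative blocks "
                "missing; anharmonic corrections to its moments are incomplete")
        prop_moments[surf.name] = vals

    sticks = _build_sticks(bundle, space, final_e, prop_moments, gvpt2)

    # ---- write artifacts -------------------------------------------
    cfg_path = outdir / "config.json"
    cfg_path.write_text(json.dumps(config.echo(), indent=1, sort_keys=True))
    artifacts["config"] = cfg_path

    res_path = outdir / "resonances.json"
    res_path.write_text(json.dumps(resdb.to_records(), indent=1))
    artifacts["resonances"] = res_path

    if level == "GVPT2":
        pol_path = outdir / "polyads.json"
        pol_path.write_text(json.dumps(build_polyads(resdb, space).to_records(), indent=1))
        artifacts["polyads"] = pol_path

    e_path = outdir / "energies.csv"
    with e_path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["state", "harmonic_cm-1", "DVPT2_cm-1", f"{level}_cm-1"])
        for s in space:
            wr.writerow([s.label(), f"{harm_e[s]:.6f}", f"{dvpt2[s]:.6f}", f"{final_e[s]:.6f}"])
    artifacts["energies"] = e_path

    for kind, st in sticks.items():
        sp = outdir / f"sticks_{kind}.csv"
        with sp.open("w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["position_cm-1", "strength"])
            for pos, val in st.sticks:
                wr.writerow([f"{pos:.6f}", f"{val:.10g}"])
        artifacts[f"sticks_{kind}"] = sp
        if kind in config.spectra.kinds and st.sticks:
            shape = convolve(st, config.spectra.shape, config.spectra.hwhm,
                             shift=config.spectra.shift)
            cp = outdir / f"spectrum_{kind}.csv"
            bandshape_to_csv(shape, cp)
            artifacts[f"spectrum_{kind}"] = cp

    if warnings:
        for w in sorted(set(warnings))[:20]:
            logger.warning(w)
    return PipelineResult(
        bundle=bundle, resdb=resdb, energies=energies, gvpt2=gvpt2,
        sticks=sticks, artifacts=artifacts, warnings=warnings,
    )


def _build_sticks(
    bundle: VibData,
    space: list[VibState],
    energies: dict[VibState, float],
    prop_moments: dict[str, dict[VibState, np.ndarray]],
    gvpt2: GVPT2Result | None,
) -> dict[str, StickSpectrum]:
    """IR (and VCD when a magnetic surface is present) stick spectra.

    With a variational result, deperturbed moments are projected onto the
    GVPT2 states; singletons pass through.
    """
    has_el = "electric_dipole" in prop_moments
    has_mag = "magnetic_dipole" in prop_moments
    out: dict[str, StickSpectrum] = {}
    if not has_el:
        return out

    records: list[tuple[float, np.ndarray, np.ndarray | None]] = []
    if gvpt2 is None:
        for s in space:
            mu = prop_moments["electric_dipole"][s]
            mg = prop_moments["magnetic_dipole"][s] if has_mag else None
            records.append((energies[s], mu, mg))
    else:
        proj_el = project_gvpt2(prop_moments["electric_dipole"], gvpt2)
        proj_mg = project_gvpt2(prop_moments["magnetic_dipole"], gvpt2) if has_mag else None
        for (ip, col), mu in proj_el.items():
            e = float(gvpt2.solutions[ip].eigenvalues[col])
            mg = proj_mg[(ip, col)] if proj_mg is not None else None
            records.append((e, mu, mg))
        for s in gvpt2.passthrough:
            mu = prop_moments["electric_dipole"][s]
            mg = prop_moments["magnetic_dipole"][s] if has_mag else None
            records.append((energies[s], mu, mg))

    records.sort(key=lambda r: r[0])
    ir = [(e, ir_stick_strength(e, dipole_strength(mu))) for e, mu, _ in records]
    out["ir"] = StickSpectrum(sticks=ir, kind="IR")
    if has_mag:
        vcd = [
            (e, vcd_stick_strength(e, rotatory_strength(mu, mg)))
            for e, mu, mg in records
        ]
        out["vcd"] = StickSpectrum(sticks=vcd, kind="VCD")
    return out
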