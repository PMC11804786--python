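"""Orchestration of the generate -> simulate -> analyze -> dissolve chain.

A single YAML/JSON configuration drives the whole pipeline; every stage
writes its outputs in standard formats (TIFF+JSON geometry, HDF5 fields,
CSV statistics) so any stage can be re-run from its predecessor's files
alone.  A JSON manifest records the configuration hash, per-artifact
checksums and convergence flags; one global seed fans out deterministic
per-stage sub-seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, analysis, dissolution, io, lbm
from .geometry import CoralParams, VoxelGeometry, generate_coral

log = logging.getLogger("coralflow")

STAGES = ("generate", "simulate", "analyze", "dissolve")


@dataclass
class Finding:
    """One configuration check result; ``level`` is 'error' or 'warning'."""

    level: str
    field: str
    message: str

    def __str__(self) -> str:
        return f"[{self.level}] {self.field}: {self.message}"


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic sub-seed per stage, derived from the global seed."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _flow_config(cfg: dict) -> lbm.FlowConfig:
    known = {f.name for f in dataclasses.fields(lbm.FlowConfig)}
    return lbm.FlowConfig(**{k: v for k, v in cfg.get("flow", {}).items() if k in known})


def _coral_params(cfg: dict, seed: int) -> CoralParams:
    geo = dict(cfg.get("geometry", {}).get("params", {}))
    geo.setdefault("seed", seed)
    if "shape" in geo:
        geo["shape"] = tuple(geo["shape"])
    return CoralParams(**geo)


def validate_config(cfg: dict) -> list[Finding]:
    """Static checks; errors block execution, warnings do not."""
    findings: list[Finding] = []
    stages = cfg.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            findings.append(Finding("error", "stages", f"unknown stage {s!r}"))
    geo = cfg.get("geometry", {})
    src = geo.get("file")
    if src is not None and not Path(src).exists():
        findings.append(Finding("error", "geometry.file", f"file not found: {src}"))
    if src is None and "generate" not in stages and {"simulate", "analyze"} & set(stages):
        findings.append(Finding("error", "geometry",
                                "no geometry file and no generate stage"))
    if src is None:
        try:
            params = _coral_params(cfg, cfg.get("seed", 0))
            params.validate()
        except (TypeError, ValueError) as exc:
            findings.append(Finding("error", "geometry.params", str(exc)))
            params = None
    else:
        params = None
    try:
        flow = _flow_config(cfg)
    except TypeError as exc:
        findings.append(Finding("error", "flow", str(exc)))
        return findings
    re = lbm.reynolds(flow.u_inlet, flow.width, flow.nu)
    if re > 150:
        findings.append(Finding("warning", "flow.u_inlet",
                                f"Re = {re:.0f} is above the desk-scale envelope "
                                "(<= 150); BGK on coarse grids may be unstable"))
    spacing = params.spacing if params is not None else geo.get("spacing", None)
    if spacing:
        dt, tau, u_lat = lbm.resolve_lattice_units(spacing, flow)
        if u_lat > 0.1:
            findings.append(Finding("warning", "flow.u_lattice",
                                    f"lattice inlet speed {u_lat:.3f} violates the "
                                    "low-Mach contract (< 0.1)"))
        if tau <= 0.5:
            findings.append(Finding("error", "flow", f"tau = {tau:.3f} <= 0.5 "
                                    "is BGK-unstable"))
    for sc in cfg.get("dissolution", {}).get("scenarios", []):
        if not 0 < sc.get("pH", 8.1) < 14:
            findings.append(Finding("error", "dissolution.scenarios",
                                    f"pH {sc.get('pH')} outside (0, 14)"))
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest dict (also written to ``manifest.json``).  A
    stage failure aborts downstream stages; the manifest records partial
    completion.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    findings = validate_config(cfg)
    errors = [f for f in findings if f.level == "error"]
    for f in findings:
        (log.error if f.level == "error" else log.warning)(str(f))
    if errors:
        raise ValueError("configuration errors:\n" + "\n".join(map(str, errors)))

    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(STAGES))
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages_completed": [],
        "artifacts": {},
        "convergence": None,
    }

    geometry: VoxelGeometry | None = None
    params: CoralParams | None = None
    field_: lbm.FlowField | None = None

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        if "generate" in stages:
            params = _coral_params(cfg, _stage_seed(seed, "generate"))
            log.info("generate: rasterizing synthetic coral %s", params.shape)
            geometry = generate_coral(params)
            gpath = outdir / "geometry.tif"
            io.write_geometry(geometry, gpath)
            record("geometry", gpath)
            record("geometry_sidecar", io.sidecar_path(gpath))
            manifest["stages_completed"].append("generate")
        elif cfg.get("geometry", {}).get("file"):
            geometry = io.read_geometry(cfg["geometry"]["file"])

        if "simulate" in stages:
            flow = _flow_config(cfg)
            log.info("simulate: Re = %.1f", lbm.reynolds(flow.u_inlet, flow.width, flow.nu))
            field_, trace = lbm.run_to_quasi_steady(geometry, flow)
            manifest["convergence"] = bool(trace["converged"])
            fpath = outdir / "field.h5"
            io.write_field(field_, fpath, trace)
            record("field", fpath)
            pd.DataFrame({
                "step": trace["step"], "time_s": trace["time"],
                "kinetic_energy": trace["kinetic_energy"],
            }).to_csv(outdir / "kinetic_energy.csv", index=False)
            record("kinetic_energy", outdir / "kinetic_energy.csv")
            if cfg.get("flow", {}).get("write_vtk", False):
                vpath = outdir / "field.vtk"
                io.write_vtk_image(vpath, field_.spacing,
                                   {"speed": field_.speed, "velocity": field_.velocity})
                record("field_vtk", vpath)
            manifest["stages_completed"].append("simulate")
        elif "analyze" in stages and (outdir / "field.h5").exists():
            field_ = io.read_field(outdir / "field.h5")

        if "analyze" in stages:
            acfg = cfg.get("analysis", {})
            if params is None:
                params = _coral_params(cfg, _stage_seed(seed, "generate"))
            regions = analysis.coral_regions(params)
            _, ens = analysis.vorticity_enstrophy(field_)
            pairs = [(regions["top_upstream"], regions["top_downstream"]),
                     (regions["bottom_upstream"], regions["bottom_downstream"])]
            rep = analysis.asymmetry_differences(field_, geometry, pairs)
            pd.DataFrame({
                "pair": [f"{a}-{b}" for a, b in rep.pairs],
                "pressure_diff": rep.pressure_diff, "pressure_sem": rep.pressure_sem,
                "velocity_diff": rep.velocity_diff, "velocity_sem": rep.velocity_sem,
                "enstrophy_diff": rep.enstrophy_diff, "enstrophy_sem": rep.enstrophy_sem,
            }).to_csv(outdir / "asymmetry.csv", index=False)
            record("asymmetry", outdir / "asymmetry.csv")

            sections = [regions[k] for k in
                        ("channel_tiptop", "channel_top", "channel_center", "channel_bottom")]
            ax = analysis.axial_decomposition(field_, geometry, sections)
            pd.DataFrame(
                [(k, v[0], v[1]) for k, v in ax.items()],
                columns=["section", "mean_speed_m_per_s", "mean_uz_over_speed"],
            ).to_csv(outdir / "axial_sections.csv", index=False)
            record("axial_sections", outdir / "axial_sections.csv")

            region = regions[acfg.get("residence_region", "channel_top")]
            starts = analysis.seed_particles(
                region, geometry,
                n=int(acfg.get("n_particles", 400)),
                radius=float(acfg.get("seed_radius", 6.0)),
                seed=_stage_seed(seed, "analyze"),
            )
            sls = analysis.trace_streamlines(
                field_, starts, geometry,
                max_steps=int(acfg.get("max_steps", 4000)),
            )
            stats = analysis.residence_time(
                sls, region, geometry,
                confidence=float(acfg.get("confidence", 0.95)),
            )
            Q = analysis.volume_flux(geometry.inner_pore_volume(), stats.mean)
            pd.DataFrame({
                "residence_time_s": stats.times,
            }).to_csv(outdir / "residence_times.csv", index=False)
            record("residence_times", outdir / "residence_times.csv")
            summary = pd.DataFrame([{
                "region": region.name, "t_bar_s": stats.mean,
                "n_streamlines": stats.n_streamlines,
                "confidence": stats.confidence,
                "inner_pore_volume_m3": geometry.inner_pore_volume(),
                "volume_flux_m3_per_s": Q,
            }])
            summary.to_csv(outdir / "residence_summary.csv", index=False)
            record("residence_summary", outdir / "residence_summary.csv")
            manifest["stages_completed"].append("analyze")

        if "dissolve" in stages:
            dcfg = cfg.get("dissolution", {})
            pipe = dissolution.PipeModel(**dcfg.get(
                "pipe", {"R_O": 0.006, "R_I": 0.001, "H": 0.04, "n0": 0.5}))
            records = []
            for sc in dcfg.get("scenarios", []):
                scenario = dissolution.AcidScenario(**sc)
                records.append(dissolution.project_scenario(pipe, scenario).as_record())
            if records:
                pd.DataFrame(records).to_csv(outdir / "dissolution.csv", index=False)
                record("dissolution", outdir / "dissolution.csv")
            manifest["stages_completed"].append("dissolve")
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
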