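"""End-to-end pipeline orchestration.

A :class:`RunConfig` fully describes a run (stages, tolerances, seeds,
paths); it is serialized into every output directory so a run can be
reproduced bit-for-bit for the deterministic stages and
seed-reproducibly for the stochastic ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import density, saxs, structures, synthetic, xl_mapping

log = logging.getLogger("oligoxl")


@dataclass
class RunConfig:
    """Parameters of a pipeline run."""

    stages: list[str] = field(default_factory=lambda: [
        "assembly", "xlmap", "saxs", "density"])
    seed: int = 0
    output_dir: str = "oligoxl_out"
    # inputs (None -> synthetic fixtures)
    pdb: str | None = None
    crosslinks: str | None = None
    saxs_curve: str | None = None
    # tolerances / parameters
    distance_threshold: float = xl_mapping.DEFAULT_THRESHOLD
    ppm: float = 10.0
    frag_tol: float = 0.05
    theta: float = 30.0
    dz: float = 35.0
    resolution: float = 10.0
    voxel: float = 3.0
    ga_generations: int = 200
    pool_size: int = 60

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageFailure(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write reports to the output dir.

    Returns a manifest dict (also written as ``manifest.json``); on a
    stage failure the partial outputs and manifest are preserved and a
    :class:`StageFailure` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest: dict = {"stages": {}, "inputs": {}}
    for key in ("pdb", "crosslinks", "saxs_curve"):
        p = getattr(config, key)
        if p is not None:
            path = Path(p)
            if not path.exists():
                raise FileNotFoundError(f"input path does not exist: {path}")
            manifest["inputs"][key] = {"path": str(path),
                                       "sha256_16": _hash_file(path)}

    for stage in config.stages:
        t0 = time.monotonic()
        try:
            result = _STAGES[stage](config, out)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageFailure(f"stage {stage!r} failed: {exc}") from exc
        wall = time.monotonic() - t0
        log.info("stage=%s wall=%.2fs", stage, wall)
        manifest["stages"][stage] = {"status": "ok", "wall_s": round(wall, 3),
                                     **result}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_assembly(config: RunConfig, out: Path) -> dict:
    if config.pdb:
        st = structures.read_structure(config.pdb)
        amap = structures.infer_assembly_map(st)
    else:
        st, amap, truth = synthetic.make_assembly_fixture(
            theta=config.theta, d=config.dz, seed=config.seed)
        truth.to_file(out / "assembly_truth.txt")
        structures.write_structure(st, out / "assembly.pdb")
    amap.to_tsv(out / "assembly_map.tsv")
    screw = structures.measure_screw(st, amap)
    (out / "screw.json").write_text(json.dumps(
        {"theta_deg": screw.theta_deg, "d_A": screw.d}, indent=2) + "\n")
    return {"theta_deg": round(screw.theta_deg, 4), "d_A": round(screw.d, 4)}


def _stage_xlmap(config: RunConfig, out: Path) -> dict:
    if config.crosslinks:
        records = xl_mapping.load_crosslink_table(config.crosslinks)
    else:
        records = xl_mapping.bundled_crosslink_table()
    report = xl_mapping.crosslink_report(records, config.distance_threshold)
    xl_mapping.report_to_tsv(report, out / "crosslink_report.tsv")
    check = xl_mapping.validate_constraints(records, config.distance_threshold)
    return {"n_crosslinks": len(records),
            "n_violations": len(check["violations"]),
            "n_unevaluable": len(check["unevaluable"])}


def _stage_saxs(config: RunConfig, out: Path) -> dict:
    rng_seed = config.seed
    if config.saxs_curve:
        curve = saxs.read_curve(config.saxs_curve)
        pools = synthetic.make_oligomer_pools(
            curve.q, n_per_state=config.pool_size, seed=rng_seed)
    else:
        curve, truth, pools = synthetic.make_saxs_mixture(
            {"dodecamer": 0.74, "hexamer": 0.26}, noise=0.01,
            seed=rng_seed, n_per_state=config.pool_size)
        truth.to_file(out / "saxs_truth.txt")
    saxs.write_curve(curve, out / "saxs_curve.dat")
    fit = saxs.guinier_fit(curve)
    ensemble = saxs.optimize_ensemble(
        pools, curve, generations=config.ga_generations, seed=rng_seed)
    saxs.write_curve(ensemble.curve, out / "saxs_fit.dat")
    lines = ["conformer\tstate\tweight"]
    for i, (m, w) in enumerate(zip(ensemble.members, ensemble.weights)):
        lines.append(f"{i}\t{m.state}\t{w:.4f}")
    (out / "ensemble.tsv").write_text("\n".join(lines) + "\n")
    return {"rg_nm": round(fit["rg"], 3), "chi2": round(ensemble.chi2, 4),
            "state_fractions": {k: round(v, 3)
                                for k, v in ensemble.state_fractions.items()}}


def _stage_density(config: RunConfig, out: Path) -> dict:
    if config.pdb:
        st = structures.read_structure(config.pdb)
        coords = st.ca_coords()
    else:
        st, _, _ = synthetic.make_assembly_fixture(
            theta=config.theta, d=config.dz, seed=config.seed)
        coords = st.ca_coords()
    base, half1, half2, truth = synthetic.make_map_fixture(
        coords, resolution=config.resolution, voxel=config.voxel,
        noise_sd=0.3, seed=config.seed)
    truth.to_file(out / "map_truth.txt")
    density.write_mrc(density.standardize(base), out / "map.mrc")
    curve = density.fsc(half1, half2)
    res = density.resolution_at(curve, 0.143)
    np.savetxt(out / "fsc.tsv",
               np.column_stack([curve["frequency"], curve["fsc"]]),
               header="frequency(1/A) fsc", fmt="%.6g")
    return {"fsc_resolution_A": round(res, 2)}


_STAGES = {
    "assembly": _stage_assembly,
    "xlmap": _stage_xlmap,
    "saxs": _stage_saxs,
    "density": _stage_density,
}
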