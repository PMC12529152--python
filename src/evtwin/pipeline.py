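"""End-to-end pipeline driver: cultivation → UFDF → MM-SEC → AEX → ledger.

Each stage consumes the previous stage's :class:`~evtwin.streams.StreamState`
and the run produces a manifest sufficient to re-run bit-identically.  A
single global seed fans out deterministically to per-stage seeds via
``numpy.random.SeedSequence(global_seed).spawn``, so stages can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

import evtwin
from evtwin import cultivation as cult
from evtwin import io as evio
from evtwin import ledger as ledger_mod
from evtwin import ufdf as ufdf_mod
from evtwin.streams import StreamState

STAGES = ("cultivation", "depth_filtration", "ufdf", "mmsec", "aex")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(STAGES, children)}


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the synthetic end-to-end process and return the manifest.

    The chromatography stages are represented by their step recovery/removal
    factors (configurable; defaults are the package's reference process
    values), keeping the pipeline fast; the full column model is exercised
    through :mod:`evtwin.chromatography` directly.
    """
    config = evio.validate_run_config(config)
    out_dir = Path(out_dir if out_dir is not None else config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config["seed"])
    manifest = {"package_version": evtwin.__version__,
                "config_hash": config_hash(config),
                "seed": config["seed"], "stage_seeds": seeds,
                "stages": {}, "outputs": []}

    def _record(stage, t_start, files):
        manifest["stages"][stage] = {"wall_clock_s": time.perf_counter() - t_start}
        manifest["outputs"].extend(str(f) for f in files)

    # --- cultivation ------------------------------------------------------
    t0 = time.perf_counter()
    csec = config["cultivation"]
    try:
        params = {"growth": cult.GROWTH_PARAMS, "collect": cult.COLLECT_PARAMS}
        schedule = cult.PhaseSchedule(
            growth_span_h=csec.get("growth_span_h", 120.0),
            collect_span_h=csec.get("collect_span_h", 120.0))
        init = cult.CultureState(vcd=csec.get("vcd0", 0.02),
                                 glc=csec.get("glc0", 25.0), lac=0.0, p=0.0)
        traj = cult.simulate_cultivation(init, schedule, params)
    except (ValueError, RuntimeError) as exc:
        raise StageError("cultivation", str(exc))
    traj_path = out_dir / "cultivation_trajectory.csv"
    evio.write_trajectory(traj, traj_path)
    _record("cultivation", t0, [traj_path])

    harvest = StreamState(
        volume_ml=csec.get("harvest_volume_ml", 1000.0),
        particles_per_ml=float(traj["particles_per_ml"].iloc[-1]),
        protein_ug_ml=csec.get("harvest_protein_ug_ml", 112.2),
        dna_ng_ml=csec.get("harvest_dna_ng_ml", 323.1))

    # --- depth filtration (factor step) ----------------------------------
    t0 = time.perf_counter()
    dsec = config.get("ledger", {})
    df_rec = dsec.get("depth_filtration_recovery", 0.702)
    df_prot = dsec.get("depth_filtration_protein_removal", 0.175)
    df_dna = dsec.get("depth_filtration_dna_removal", 0.252)
    depth_out = StreamState(
        volume_ml=harvest.volume_ml,
        particles_per_ml=harvest.particles_per_ml * df_rec,
        protein_ug_ml=harvest.protein_ug_ml * (1 - df_prot),
        dna_ng_ml=harvest.dna_ng_ml * (1 - df_dna))
    _record("depth_filtration", t0, [])

    # --- UFDF -------------------------------------------------------------
    t0 = time.perf_counter()
    usec = config["ufdf"]
    try:
        cfg = ufdf_mod.UFDFConfig(
            vcf1=usec.get("vcf1", 2.2), dv=usec.get("dv", 5.0),
            vcf2=usec.get("vcf2", 2.2),
            sieving={"particles": 0.0,
                     "protein": usec.get("sieving_protein", 0.17),
                     "dna": usec.get("sieving_dna", 0.20)})
        fit = ufdf_mod.FoulingFit([
            ufdf_mod.FoulingSegment(n=1.0, K_n=0.18175, J_R=15.995,
                                    v_start=0.0, v_end=11.0),
            ufdf_mod.FoulingSegment(n=0.0, K_n=0.00195, J_R=20.0513,
                                    v_start=11.0, v_end=float("inf"))])
        ufdf_out = ufdf_mod.simulate_ufdf(depth_out, cfg, fit=fit,
                                          j0=usec.get("j0", 89.9))
    except (ValueError, RuntimeError) as exc:
        raise StageError("ufdf", str(exc))
    flux_path = out_dir / "ufdf_flux.csv"
    if ufdf_out["flux_series"] is not None:
        evio.write_flux_series(ufdf_out["flux_series"], flux_path)
    _record("ufdf", t0, [flux_path])
    retentate = ufdf_out["retentate"]

    # --- chromatography stages (factor representation) --------------------
    streams = {"harvest": harvest, "depth_filtration": depth_out,
               "ufdf": retentate}
    prev = retentate
    for stage, defaults in (("mmsec", {"recovery": 0.863,
                                       "protein_removal": 0.629,
                                       "dna_removal": 0.479,
                                       "volume_factor": 1.0}),
                            ("aex", {"recovery": 0.624,
                                     "protein_removal": 0.929,
                                     "dna_removal": 0.958,
                                     "volume_factor": 1.0})):
        t0 = time.perf_counter()
        sec = config[stage]
        vol = prev.volume_ml * sec.get("volume_factor",
                                       defaults["volume_factor"])
        nxt = StreamState(
            volume_ml=vol,
            particles_per_ml=prev.particle_mass
            * sec.get("recovery", defaults["recovery"]) / vol,
            protein_ug_ml=prev.protein_mass_ug
            * (1 - sec.get("protein_removal", defaults["protein_removal"])) / vol,
            dna_ng_ml=prev.dna_mass_ng
            * (1 - sec.get("dna_removal", defaults["dna_removal"])) / vol)
        streams[stage] = nxt
        prev = nxt
        _record(stage, t0, [])

    # --- ledger -----------------------------------------------------------
    order = ["harvest", "depth_filtration", "ufdf", "mmsec", "aex"]
    steps = [ledger_mod.LedgerStep(name=b, stream_in=streams[a],
                                   stream_out=streams[b])
             for a, b in zip(order, order[1:])]
    summary = ledger_mod.run_ledger(steps)
    summary_path = out_dir / "ledger_summary.json"
    evio.write_report({k: v for k, v in summary.items() if k != "steps"},
                      summary_path)
    steps_path = out_dir / "ledger_steps.csv"
    evio.write_step_table(summary["steps"], steps_path)
    manifest["outputs"].extend([str(summary_path), str(steps_path)])
    manifest["overall_recovery"] = summary["overall_recovery"]
    manifest["protein_removal_mass"] = summary["protein_removal_mass"]
    manifest["dna_removal_mass"] = summary["dna_removal_mass"]
    manifest["stage_recoveries"] = {s.name: s.recovery for s in steps}

    manifest_path = out_dir / "manifest.json"
    evio.write_report(manifest, manifest_path)
    return manifest
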