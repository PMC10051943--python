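"""End-to-end orchestration: simulate/ingest -> fuse -> fit OU -> CRA ->
deconfound -> validate.

A run is driven by a :class:`PipelineConfig` (YAML on disk).  Every stage
writes its artifact into the output directory and the run is described by
a JSON manifest recording the config hash, the per-stage seeds (derived
from the master seed through ``numpy.random.SeedSequence.spawn``), stage
timings and artifact paths, so any stage can be re-run from its
predecessor's outputs and reproduces them bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio
from .factor import CauseMatrix, PPCAModel, ppc_score
from .fusion import ewe_fuse
from .ou import OUModel, Trajectory
from .outcome import RatingOutcomeModel, significance_table
from .recurrence import compare_emulation
from .reliability import (
    consensus_ratings,
    reliability_study,
    sample_raters,
    shift_benchmark,
)
from .synthetic import CohortSpec, generate_cohort, make_shifted_test_split

__all__ = ["PipelineConfig", "run_all", "STAGES"]

STAGES = ("simulate", "fuse", "fit-ou", "cra", "deconfound", "validate")


@dataclass
class PipelineConfig:
    """Configuration of one full run; round-trips through YAML unchanged."""

    # inputs: either CSV paths or a synthetic spec
    trajectories_csv: str | None = None
    ratings_csv: str | None = None
    synthetic: dict | None = None          # kwargs for CohortSpec
    # analysis settings
    dt: float = 0.04
    inference: str = "laplace"
    draws: int = 500
    k_confounder: int = 2
    target_rr: float = 0.05
    n_emulated: int = 5
    n_random: int = 5
    ppc_holdout: float = 0.2
    ppc_replicates: int = 100
    icc_variant: str = "single"
    n_sim_raters: int = 6
    shift: float = 3.5
    test_fraction: float = 0.3
    run_cra: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seeds(self) -> dict:
        """Independent per-stage seeds spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {
            stage: int(child.generate_state(1)[0] % 2**31)
            for stage, child in zip(STAGES, children)
        }


class StageError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage_simulate(config, out_dir, seed, manifest):
    if config.synthetic is not None:
        spec = CohortSpec(**{**config.synthetic, "seed": seed})
        gt, traj_df, ratings_df = generate_cohort(spec)
        traj_path = out_dir / "trajectories.csv"
        ratings_path = out_dir / "ratings.csv"
        dataio.write_trajectories(traj_df, traj_path)
        dataio.write_ratings(ratings_df, ratings_path)
        gt.to_json(out_dir / "ground_truth.json")
        manifest["artifacts"]["ground_truth"] = "ground_truth.json"
    else:
        for name, path in (
            ("trajectories", config.trajectories_csv),
            ("ratings", config.ratings_csv),
        ):
            if path is None or not Path(path).exists():
                raise StageError("simulate", f"missing {name} file: {path}")
        traj_path, ratings_path = Path(config.trajectories_csv), Path(config.ratings_csv)
    manifest["artifacts"]["trajectories"] = str(traj_path)
    manifest["artifacts"]["ratings"] = str(ratings_path)
    return traj_path, ratings_path


def _stage_fuse(config, out_dir, traj_path, manifest):
    df = dataio.read_trajectories(traj_path)
    nested = dataio.trajectories_from_frame(df)
    frames = []
    for sid, raters in nested.items():
        fused = ewe_fuse(list(raters.values()))
        frames.append(dataio.trajectory_to_frame(fused, sid, "EWE"))
    fused_df = pd.concat(frames, ignore_index=True)
    path = out_dir / "fused.csv"
    dataio.write_trajectories(fused_df, path)
    manifest["artifacts"]["fused"] = "fused.csv"
    return path


def _stage_fit_ou(config, out_dir, fused_path, seed, manifest):
    df = dataio.read_trajectories(fused_path)
    nested = dataio.trajectories_from_frame(df)
    rng = np.random.SeedSequence(seed)
    results = {}
    for (sid, raters), child in zip(sorted(nested.items()), rng.spawn(len(nested))):
        traj = raters["EWE"]
        results[sid] = OUModel(traj).fit(
            method=config.inference,
            draws=config.draws,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
    path = out_dir / "descriptors.json"
    dataio.write_descriptors(results, path)
    manifest["artifacts"]["descriptors"] = "descriptors.json"
    return results


def _stage_cra(config, out_dir, fused_path, ou_results, seed, manifest):
    df = dataio.read_trajectories(fused_path)
    nested = dataio.trajectories_from_frame(df)
    rng = np.random.SeedSequence(seed)
    rows = []
    for (sid, res), child in zip(sorted(ou_results.items()), rng.spawn(len(ou_results))):
        tab = compare_emulation(
            nested[sid]["EWE"],
            res,
            n_emulated=config.n_emulated,
            n_random=config.n_random,
            target_rr=config.target_rr,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        for group, row in tab.iterrows():
            rows.append({"subject_id": sid, "group": group, **row.to_dict()})
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "cra_metrics.csv", index=False)
    manifest["artifacts"]["cra_metrics"] = "cra_metrics.csv"
    return out


def _stage_deconfound(config, out_dir, descriptors, ratings_path, seed, manifest):
    ratings_df = dataio.read_ratings(ratings_path)
    P = CauseMatrix.from_descriptors(descriptors)
    rng = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng]
    factor = PPCAModel(P, k=config.k_confounder).fit(n_draws=config.draws, seed=seeds[0])
    chat = factor.confounders()
    score = ppc_score(
        P,
        k=config.k_confounder,
        holdout_fraction=config.ppc_holdout,
        n_replicates=config.ppc_replicates,
        seed=seeds[1],
    )
    cons = consensus_ratings(ratings_df).loc[P.subject_ids]
    models = {"causal": {}, "correlational": {}}
    report = {"ppc_score": score, "traits": {}}
    for j, trait in enumerate(cons.columns):
        z = cons[trait].to_numpy(float)
        causal = RatingOutcomeModel(z, P, confounders=chat).fit(
            draws=config.draws, seed=seeds[2] + j
        )
        correl = RatingOutcomeModel(z, P, truncated=False).fit(
            draws=config.draws, seed=seeds[2] + 100 + j
        )
        models["causal"][trait] = causal
        models["correlational"][trait] = correl
        report["traits"][trait] = {
            kind: {
                name: {
                    "mean": float(row["mean"]),
                    "hdi_lo": float(row["hdi_lo"]),
                    "hdi_hi": float(row["hdi_hi"]),
                    "significant": bool(row["significant"]),
                }
                for name, row in res.summary().iterrows()
            }
            for kind, res in (("causal", causal), ("correlational", correl))
        }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    manifest["artifacts"]["report"] = "report.json"
    return models, factor, chat, P, cons


def _stage_validate(config, out_dir, models, factor, chat, P, cons, ratings_path,
                    seed, manifest):
    ratings_df = dataio.read_ratings(ratings_path)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(3)]
    sim = sample_raters(
        models["causal"], P, chat, n_raters=config.n_sim_raters, seed=seeds[0],
        subject_ids=P.subject_ids,
    )
    icc_table = reliability_study(ratings_df, sim, variant=config.icc_variant)

    typical = make_shifted_test_split(chat, np.zeros(chat.shape[1]),
                                      config.test_fraction, seed=seeds[1])
    uncommon = make_shifted_test_split(chat, np.full(chat.shape[1], config.shift),
                                       config.test_fraction, seed=seeds[1])
    pll_table = shift_benchmark(
        P, cons, {"typical": typical, "uncommon": uncommon},
        k=config.k_confounder, seed=seeds[2], draws=config.draws,
    )
    validation = {
        "icc": icc_table.to_dict(orient="index"),
        "pll": pll_table.to_dict(orient="index"),
    }
    with open(out_dir / "validation.json", "w") as fh:
        json.dump(validation, fh, indent=1)
    manifest["artifacts"]["validation"] = "validation.json"
    return validation


def run_all(config, out_dir):
    """Execute every stage in order; returns the manifest dict.

    A failing stage halts the pipeline; the manifest (always written) then
    records the failed stage and the error message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seeds": seeds,
        "package_version": __import__("affectdyn").__version__,
        "stages": {},
        "artifacts": {},
        "failed_stage": None,
    }
    config.to_yaml(out_dir / "config.yaml")
    try:
        t0 = time.time()
        traj_path, ratings_path = _stage_simulate(config, out_dir, seeds["simulate"], manifest)
        manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 3)}

        t0 = time.time()
        fused_path = _stage_fuse(config, out_dir, traj_path, manifest)
        manifest["stages"]["fuse"] = {"seconds": round(time.time() - t0, 3)}

        t0 = time.time()
        ou_results = _stage_fit_ou(config, out_dir, fused_path, seeds["fit-ou"], manifest)
        manifest["stages"]["fit-ou"] = {"seconds": round(time.time() - t0, 3)}

        if config.run_cra:
            t0 = time.time()
            _stage_cra(config, out_dir, fused_path, ou_results, seeds["cra"], manifest)
            manifest["stages"]["cra"] = {"seconds": round(time.time() - t0, 3)}

        descriptors = {sid: res.descriptor() for sid, res in sorted(ou_results.items())}
        t0 = time.time()
        models, factor, chat, P, cons = _stage_deconfound(
            config, out_dir, descriptors, ratings_path, seeds["deconfound"], manifest
        )
        manifest["stages"]["deconfound"] = {"seconds": round(time.time() - t0, 3)}

        t0 = time.time()
        _stage_validate(
            config, out_dir, models, factor, chat, P, cons, ratings_path,
            seeds["validate"], manifest,
        )
        manifest["stages"]["validate"] = {"seconds": round(time.time() - t0, 3)}
    except StageError as err:
        manifest["failed_stage"] = err.stage
        manifest["error"] = str(err)
        _write_manifest(manifest, out_dir)
        raise
    except Exception as err:  # record which stage blew up, then re-raise
        done = set(manifest["stages"])
        pending = [s for s in STAGES if s not in done]
        manifest["failed_stage"] = pending[0] if pending else "unknown"
        manifest["error"] = str(err)
        _write_manifest(manifest, out_dir)
        raise
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest, out_dir):
    with open(Path(out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
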