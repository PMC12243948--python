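"""End-to-end orchestration: simulate -> align -> analyze -> report.

A validated YAML config drives the stages in dependency order (timeline
-> simulation -> optional SRM -> boundary / context / timing / behavior
analyses -> optional power curve).  Every output file is recorded in a
run manifest with a content hash, and all randomness is expanded from a
single master seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import behavior as beh
from . import boundaries as bnd
from . import context as ctx
from . import srm as srmmod
from . import timing as tim
from .eventseg import HmmConfig, fit
from .synth import SimSpec, _stable_seed, simulate_button_presses, simulate_cohort, simulate_ratings
from .timeline import Emotion, all_builtin_timelines, music_tr_labels

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


class SimCfg(BaseModel):
    n_subjects: int = Field(20, ge=2)
    n_units: int = Field(80, ge=2)
    n_features: int = Field(40, ge=2)
    snr: float = Field(0.5, ge=0)
    context_shift: float = Field(0.5, ge=0, le=1)
    timing_delay_tr: int = Field(4, ge=0)
    shared_voxel_map: bool = False


class SrmCfg(BaseModel):
    enabled: bool = True
    k: int = Field(20, ge=2)
    n_iter: int = Field(10, ge=0)


class StagesCfg(BaseModel):
    boundaries: bool = True
    context: bool = True
    timing: bool = True
    behavior: bool = True
    power: bool = False


class BehaviorCfg(BaseModel):
    n_raters: int = Field(36, ge=1)
    latency_context_penalty_s: float = Field(9.0, ge=0)
    focus_emotions: list[Literal["calm", "happy", "sad", "anxious", "nostalgic"]] = [
        e.value for e in Emotion
    ]


class PowerCfg(BaseModel):
    n_grid: list[int] = [5, 10, 20]
    n_reps: int = Field(10, ge=1)
    alpha: float = Field(0.005, gt=0, lt=1)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "emodyn_results"
    pieces: list[Literal["A", "B"]] = ["A", "B"]
    n_perm: int = Field(500, ge=1)
    context_half: Literal["full", "second"] = "full"
    sim: SimCfg = SimCfg()
    srm: SrmCfg = SrmCfg()
    stages: StagesCfg = StagesCfg()
    behavior: BehaviorCfg = BehaviorCfg()
    power: PowerCfg = PowerCfg()


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(outdir: Path, name: str, obj, manifest: dict) -> None:
    path = outdir / name
    path.write_text(json.dumps(obj, indent=2, default=float))
    manifest["outputs"][name] = _sha256(path)


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Run every enabled stage and return the results bundle.

    Also writes per-stage JSON outputs and a manifest (seed, parameter
    hash, output hashes) under ``config.out_dir``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "outputs": {},
    }
    results: dict = {}
    timelines = {
        k: tl for k, tl in all_builtin_timelines().items() if k[0] in config.pieces
    }
    spec = SimSpec(
        n_subjects=config.sim.n_subjects,
        n_units=config.sim.n_units,
        n_features=config.sim.n_features,
        snr=config.sim.snr,
        context_shift=config.sim.context_shift,
        timing_delay_tr=config.sim.timing_delay_tr,
        shared_voxel_map=config.sim.shared_voxel_map,
        seed=_stable_seed("pipeline-sim", config.seed),
    )
    ds = simulate_cohort(spec, timelines)
    results["simulate"] = {
        "n_subjects": ds.n_subjects,
        "versions": ds.versions.tolist(),
        "n_events": len(ds.keys),
    }

    # feature extraction: SRM space or raw units
    if config.srm.enabled:
        space = srmmod.fit_srm(
            [s["align"] for s in ds.subjects],
            k=min(config.srm.k, spec.n_units),
            n_iter=config.srm.n_iter,
            seed=_stable_seed("pipeline-srm", config.seed),
        )
        feats = {
            (i, piece): srmmod.transform(ds.subjects[i][piece], space, i)
            for i in range(ds.n_subjects)
            for piece in config.pieces
        }
        results["srm"] = {"k": space.k, "objective": space.fit_log}
    else:
        feats = {
            (i, piece): ds.subjects[i][piece].data
            for i in range(ds.n_subjects)
            for piece in config.pieces
        }

    def group_feats(piece, version):
        mats = [
            feats[(i, piece)]
            for i in range(ds.n_subjects)
            if ds.versions[i] == version
        ]
        return np.mean(mats, axis=0)

    if config.stages.boundaries:
        out = {}
        for (piece, version), tl in sorted(timelines.items()):
            g = group_feats(piece, version)
            labels = music_tr_labels(tl)
            bp = bnd.boundary_pattern_test(
                g, labels, n_perm=config.n_perm,
                seed=_stable_seed("bp", config.seed, piece, version),
            )
            seg = fit(g, HmmConfig(n_events=len(tl.events)))
            em = bnd.entropy_match_test(
                seg, ds.boundaries[(piece, version)], n_perm=config.n_perm,
                seed=_stable_seed("em", config.seed, piece, version),
                window_tr=1,
            )
            out[f"{piece}{version}"] = {
                "pattern_test": bp.to_dict(),
                "entropy_test": em.to_dict(),
            }
        results["boundaries"] = out
        _write(outdir, "boundaries.json", out, manifest)

    if config.stages.context:
        groups = {}
        for piece in config.pieces:
            pats = np.stack(
                [
                    ctx.event_mean_patterns(
                        feats[(i, piece)],
                        timelines[(piece, int(ds.versions[i]))],
                        half=config.context_half,
                    )
                    for i in range(ds.n_subjects)
                ]
            )
            groups[piece] = (ds.versions, pats)
        res = ctx.version_label_permutation_test(
            groups, n_perm=config.n_perm, seed=_stable_seed("ctx", config.seed)
        )
        results["context"] = res.to_dict()
        _write(outdir, "context.json", res.to_dict(), manifest)

    if config.stages.timing:
        gf = {
            (piece, v): group_feats(piece, v)
            for piece in config.pieces
            for v in (1, 2)
        }
        out = tim.valence_timing_contrast(
            gf, timelines, n_perm=config.n_perm,
            seed=_stable_seed("tim", config.seed),
        )
        results["timing"] = {
            "test": out["result"].to_dict(),
            "shift_seconds": out["shift_seconds"],
        }
        out["events"].to_csv(outdir / "timing_events.tsv", sep="\t", index=False)
        manifest["outputs"]["timing_events.tsv"] = _sha256(outdir / "timing_events.tsv")
        _write(outdir, "timing.json", results["timing"], manifest)

    if config.stages.behavior:
        presses = {
            k: simulate_button_presses(
                tl,
                latency_context_penalty_s=config.behavior.latency_context_penalty_s,
                n_raters=config.behavior.n_raters,
                seed=_stable_seed("press", config.seed, *k),
            )
            for k, tl in timelines.items()
        }
        out = {}
        for k, tl in sorted(timelines.items()):
            trans_times = np.array([e.onset_s for e in tl.events[1:]])
            r = beh.press_transition_test(
                presses[k], trans_times, tl.total_music_s,
                n_perm=config.n_perm, seed=_stable_seed("pt", config.seed, *k),
            )
            out[f"{k[0]}{k[1]}"] = r.to_dict()
        ttc = beh.time_to_threshold_contrast(
            presses, timelines, n_perm=config.n_perm,
            seed=_stable_seed("ttc", config.seed),
        )
        ratings = simulate_ratings(
            timelines,
            n_subjects=ds.n_subjects,
            context_effect=config.sim.context_shift,
            versions=ds.versions,
            seed=_stable_seed("rat", config.seed),
        )
        rcc = beh.rating_context_correlation(
            ratings, n_perm=config.n_perm, seed=_stable_seed("rcc", config.seed)
        )
        results["behavior"] = {
            "press_transition": out,
            "latency_contrast": {
                pol: ttc[pol].to_dict() for pol in ("positive", "negative")
            },
            "rating_context": rcc.to_dict(),
        }
        _write(outdir, "behavior.json", results["behavior"], manifest)

    if config.stages.power:
        from .power import power_curve

        pc = power_curve(
            spec,
            n_grid=config.power.n_grid,
            alpha=config.power.alpha,
            n_reps=config.power.n_reps,
            n_perm=min(config.n_perm, 200),
            seed=_stable_seed("pow", config.seed),
        )
        results["power"] = pc.to_dict(orient="records")
        _write(outdir, "power.json", results["power"], manifest)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
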