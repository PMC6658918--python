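"""End-to-end orchestration: simulate -> extract -> invert -> compare -> average -> stats.

A single JSON-serialisable :class:`RunConfig` drives every stage.  All
randomness derives from ``master_seed``; per-stage seeds are recorded in the
run manifest, and stages are skipped on re-run when their outputs exist and
the configuration hash is unchanged, so a completed run is idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import bma, family_bms, rfx_bms
from .design import (
    DesignConfig,
    build_block_schedule,
    build_design_matrix,
    events_to_inputs,
)
from .extraction import (
    VoiExclusionError,
    extract_subject_regions,
    framewise_displacement,
)
from .inversion import InversionConfig, make_priors, variational_laplace
from .modelspace import FamilyPartition, reduced_space
from .simulate import (
    SimulationConfig,
    default_ground_truth,
    simulate_group,
    write_dataset,
)
from .stats import (
    behavior_summary,
    correlate_behavior,
    filter_trials,
    one_sample_ttests,
    paired_ttest,
    rm_anova,
)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline"]

log = logging.getLogger("valdcm")

STAGES = ("simulate", "extract", "invert", "compare", "average", "stats")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name and offending context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class RunConfig:
    master_seed: int = 0
    output_root: str = "out"
    n_subjects: int = 12
    model_space: str = "per_connection_16"
    stages: tuple[str, ...] = STAGES
    design: DesignConfig = field(default_factory=DesignConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    bms_samples: int = 100_000

    @classmethod
    def from_json(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload.update(overrides or {})
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(payload)
        for key, sub_cls in (
            ("design", DesignConfig),
            ("simulation", SimulationConfig),
            ("inversion", InversionConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_known = set(sub_cls.__dataclass_fields__)
                sub_unknown = set(kwargs[key]) - sub_known
                if sub_unknown:
                    raise ConfigError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kwargs[key] = sub_cls(**kwargs[key])
        cfg = cls(**kwargs)
        if cfg.model_space not in ("full_256", "per_connection_16", "families_4_representatives"):
            raise ConfigError(f"unknown model_space {cfg.model_space!r}")
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; valid: {list(STAGES)}")
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_dict(self) -> dict:
        out = asdict(self)
        out["stages"] = list(self.stages)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_done(root: Path, stage: str, cfg_hash: str) -> bool:
    marker = root / f".stage_{stage}.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_stage(root: Path, stage: str, cfg_hash: str, seconds: float) -> None:
    (root / f".stage_{stage}.json").write_text(
        json.dumps({"config_hash": cfg_hash, "wall_time_s": round(seconds, 3)})
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages and return the run manifest.

    A re-run with an unchanged configuration whose stages all completed is a
    no-op: the previous manifest is returned and every stage is skipped.
    """
    root = Path(config.output_root)
    root.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = root / "run_manifest.json"
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
        if (
            previous is not None
            and previous.get("config_hash") == cfg_hash
            and all(_stage_done(root, s, cfg_hash) for s in config.stages)
        ):
            log.info("all stages up to date; skipping run")
            return previous

    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "stage_wall_time_s": {},
        "seeds": {"master": config.master_seed},
    }

    design = build_block_schedule(config.design)
    inputs = events_to_inputs(design)
    models = reduced_space(config.model_space)
    partition = FamilyPartition.from_models(models)

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        start = time.perf_counter()
        try:
            _run_stage(stage, config, root, design, inputs, models, partition, state)
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive wrapping
            raise StageError(stage, str(exc)) from exc
        elapsed = time.perf_counter() - start
        _mark_stage(root, stage, cfg_hash, elapsed)
        manifest["stage_wall_time_s"][stage] = round(elapsed, 3)
        log.info("stage=%s done in %.1fs", stage, elapsed)

    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _run_stage(stage, config, root, design, inputs, models, partition, state):
    if stage == "simulate":
        truth = default_ground_truth()
        subjects, manifest = simulate_group(
            truth,
            n_subjects=config.n_subjects,
            master_seed=config.master_seed,
            config=config.simulation,
            design_config=config.design,
        )
        write_dataset(subjects, manifest, root / "dataset", design)
        state["subjects"] = subjects
        state["truth"] = truth
        return

    subjects = state.get("subjects")
    if subjects is None and stage in ("extract", "invert", "stats"):
        raise StageError(stage, "simulate stage output unavailable; run with simulate enabled")

    if stage == "extract":
        X = build_design_matrix(design)
        out_dir = root / "regions_extracted"
        out_dir.mkdir(exist_ok=True)
        exclusions = []
        regions = {}
        for sub in subjects:
            fd = framewise_displacement(sub.motion)
            if fd.flagged:
                exclusions.append(
                    {"subject": sub.subject_id, "reason": "mean_fd", "region": None}
                )
                continue
            try:
                ts, _ = extract_subject_regions(
                    sub.voxel_ts, X, subject_id=sub.subject_id, tr=design.tr
                )
            except VoiExclusionError as exc:
                exclusions.append(
                    {"subject": exc.subject_id, "reason": "no_active_voxels",
                     "region": exc.region}
                )
                continue
            regions[sub.subject_id] = ts
            pd.DataFrame(ts.y, columns=list(ts.region_names)).to_csv(
                out_dir / f"{sub.subject_id}.tsv", sep="\t", index=False,
                float_format="%.8f",
            )
        with open(root / "exclusions.jsonl", "w") as fh:
            for row in exclusions:
                fh.write(json.dumps(row) + "\n")
        state["region_ts"] = regions
        return

    if stage == "invert":
        regions = state.get("region_ts")
        if not regions:
            raise StageError("invert", "no extracted region series available")
        results: dict[str, dict[int, object]] = {}
        fe = pd.DataFrame(
            index=sorted(regions), columns=[m.model_id for m in models], dtype=float
        )
        for sub_id in sorted(regions):
            results[sub_id] = {}
            for spec in models:
                priors = make_priors(spec, config.inversion)
                try:
                    res = variational_laplace(
                        regions[sub_id], spec, priors, inputs, design,
                        config=config.inversion,
                    )
                except Exception as exc:
                    raise StageError(
                        "invert", f"subject={sub_id} model_id={spec.model_id}: {exc}"
                    ) from exc
                results[sub_id][spec.model_id] = res
                fe.loc[sub_id, spec.model_id] = res.free_energy
        fe.to_csv(root / "free_energy.csv")
        with open(root / "inversions.json", "w") as fh:
            json.dump(
                {s: {str(mid): r.to_dict() for mid, r in by_model.items()}
                 for s, by_model in results.items()},
                fh, indent=1,
            )
        state["inversions"] = results
        state["free_energy"] = fe
        return

    if stage == "compare":
        fe = state.get("free_energy")
        if fe is None:
            raise StageError("compare", "free-energy matrix unavailable")
        model_ids = tuple(int(c) for c in fe.columns)
        evid = fe.to_numpy(dtype=float)
        model_bms = rfx_bms(
            evid, option_ids=model_ids, level="models",
            n_samples=config.bms_samples, seed=config.master_seed,
        )
        fam_bms = family_bms(
            evid, partition, model_ids=model_ids,
            n_samples=config.bms_samples, seed=config.master_seed,
        )
        state["model_bms"] = model_bms
        state["family_bms"] = fam_bms
        for name, res in (("bms_models", model_bms), ("bms_families", fam_bms)):
            with open(root / f"{name}.json", "w") as fh:
                json.dump(
                    {
                        "level": res.level,
                        "option_ids": list(res.option_ids),
                        "alpha": res.alpha.tolist(),
                        "expected_prob": res.expected_prob.tolist(),
                        "exceedance_prob": res.exceedance_prob.tolist(),
                        "n_samples": res.n_samples,
                        "seed": config.master_seed,
                    },
                    fh, indent=1,
                )
        return

    if stage == "average":
        model_bms = state.get("model_bms")
        inversions = state.get("inversions")
        fam = state.get("family_bms")
        if model_bms is None or inversions is None or fam is None:
            raise StageError("average", "comparison outputs unavailable")
        winning = fam.winner()
        if winning == "none":
            # the no-modulation family has a single model; average it alone
            pass
        averaged = bma(inversions, model_bms, winning, partition)
        averaged.subject_values.to_csv(root / "bma_parameters.csv")
        state["bma"] = averaged
        return

    if stage == "stats":
        averaged = state.get("bma")
        if averaged is None:
            raise StageError("stats", "BMA output unavailable")
        coupling_cols = [c for c in averaged.subject_values.columns if "→" in c]
        coupling = averaged.subject_values[coupling_cols]
        report = one_sample_ttests(coupling)
        table = report.table.copy()
        table.insert(1, "sd", coupling.std(axis=0, ddof=1))
        table = table.rename(columns={"estimate": "mean"})
        table.to_csv(root / "report.csv")

        frames = []
        for sub in subjects:
            tab = sub.behavior.copy()
            tab["subject"] = sub.subject_id
            frames.append(tab)
        behavior = pd.concat(frames, ignore_index=True)
        filtered, excluded_fraction = filter_trials(behavior)
        per_subject = behavior_summary(filtered)
        per_subject.to_csv(root / "behavior_by_subject.csv")
        group_summary = pd.concat(
            {"mean": per_subject.mean(axis=0), "sd": per_subject.std(axis=0, ddof=1)},
            axis=1,
        )
        group_summary.to_csv(root / "behavior_summary.csv")

        acc = per_subject["accuracy"]
        valence = acc[["positive", "negative", "neutral"]].dropna()
        F, (df1, df2), p_anova = rm_anova(valence)
        faces = acc[["positive", "negative", "neutral"]].mean(axis=1)
        t_fs, dof_fs, p_fs = paired_ttest(
            faces.to_numpy(), acc["shapes"].to_numpy()
        )
        with open(root / "behavior_tests.json", "w") as fh:
            json.dump(
                {
                    "excluded_fraction": excluded_fraction,
                    "valence_anova": {"F": F, "df": [df1, df2], "p": p_anova},
                    "faces_vs_shapes_accuracy": {"t": t_fs, "dof": dof_fs, "p": p_fs},
                },
                fh, indent=1,
            )

        # brain-behavior: each coupling parameter against each behavioral measure
        measures = per_subject.copy()
        measures.columns = [f"{kind}_{cond}" for kind, cond in measures.columns]
        common = coupling.index.intersection(measures.index)
        if len(common) >= 3:
            correlations = correlate_behavior(
                coupling.loc[common], measures.loc[common]
            )
            correlations.table.to_csv(root / "behavior_correlations.csv")
        state["report"] = report
        return

    raise StageError(stage, "unknown stage")
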