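"""Synthetic multi-subject datasets with known ground-truth connectivity.

The generator emulates the study conditions end to end so every downstream
stage can be validated against a known truth: a 33-subject group performing
the 6-min face-/shape-matching block task at TR = 2 s (175 volumes), region
BOLD in the four-node network (FFA, AMY, LPFC, MPFC), voxel-level VOI
neighbourhoods on a 2-mm grid, six-parameter head-motion random walks, and
trial-level behavioral responses with a small fraction of unusable trials
(no response, or responses faster than 100 ms).

The default group-mean coupling places simulations in the empirically
reported parameter regime: endogenous and modulatory means follow the group
BMA estimates of the bidirectional family (e.g. LPFC->AMY 0.1702,
AMY->MPFC 0.1122, negative-valence modulation of MPFC->AMY -0.2732), and the
generating model is the fully modulated member of the bidirectional family.
Noise is white Gaussian per region, scaled to a target signal-to-noise ratio
(signal SD / noise SD) of the region summary series.  The default SNR of 8
is calibrated so the end-to-end recovery properties hold: in this coupling
regime the top-down modulation effects on BOLD are second-order small (they
ride on the weak MPFC activity), family-level model selection needs roughly
SNR >= 3 at n = 12 to identify bidirectional modulation, and reliable
recovery of the weakly identified MPFC-source couplings needs more still.
An SNR of this size is the eigenvariate regime: averaging ~100 voxels of a
strong block design multiplies voxel-level SNR several-fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .design import (
    DesignConfig,
    TaskDesign,
    build_block_schedule,
    events_to_inputs,
    write_events_tsv,
    write_motion_params,
)
from .forward import (
    REGIONS,
    DCMParameters,
    HemodynamicParams,
    StabilityError,
    integrate_dcm,
    params_to_dict,
)
from .modelspace import (
    INPUT_NAMES,
    MODULATORS,
    ModelSpec,
    connection_index,
    make_model_spec,
)

__all__ = [
    "GroundTruth",
    "SyntheticSubject",
    "RegionTimeSeries",
    "BehaviorConfig",
    "SimulationConfig",
    "default_ground_truth",
    "draw_subject_params",
    "simulate_subject",
    "simulate_group",
    "simulate_behavior",
    "simulate_motion",
    "voi_voxel_offsets",
    "write_dataset",
]

#: group-mean coupling used as simulation truth (Hz); (source, target) -> value
DEFAULT_A_MEANS: dict[tuple[str, str], float] = {
    ("MPFC", "AMY"): 0.0727,
    ("MPFC", "LPFC"): -0.0823,
    ("LPFC", "MPFC"): -0.1471,
    ("AMY", "MPFC"): 0.1122,
    ("AMY", "LPFC"): 0.1207,
    ("LPFC", "AMY"): 0.1702,
    ("AMY", "FFA"): 0.0579,
    ("LPFC", "FFA"): 0.0018,
    ("FFA", "AMY"): -0.0561,
    ("FFA", "LPFC"): -0.1076,
}

#: group-mean modulatory coupling (Hz); (source, target, modulator) -> value
DEFAULT_B_MEANS: dict[tuple[str, str, str], float] = {
    ("MPFC", "AMY", "positive"): -0.1799,
    ("MPFC", "LPFC", "positive"): 0.0826,
    ("LPFC", "MPFC", "positive"): -0.1575,
    ("AMY", "MPFC", "positive"): -0.1434,
    ("MPFC", "AMY", "negative"): -0.2732,
    ("MPFC", "LPFC", "negative"): 0.0149,
    ("LPFC", "MPFC", "negative"): -0.2174,
    ("AMY", "MPFC", "negative"): -0.1051,
}

#: driving gain of the all-faces input into the FFA (Hz)
DEFAULT_DRIVING_GAIN = 0.3

#: id of the fully modulated model (all 8 valence switches on)
FULL_BIDIRECTIONAL_MODEL_ID = 255


@dataclass(frozen=True)
class RegionTimeSeries:
    """Per-subject BOLD series of the four network nodes at TR resolution."""

    y: np.ndarray
    tr: float = 2.0
    region_names: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.y.ndim != 2 or self.y.shape[1] != len(self.region_names):
            raise ValueError(f"expected (n_volumes, {len(self.region_names)}) series")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("region time series contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.y.shape[0]

    def column(self, region: str) -> np.ndarray:
        return self.y[:, self.region_names.index(region)]


@dataclass(frozen=True)
class GroundTruth:
    """Group-level generating process of a synthetic dataset."""

    group_mean_params: DCMParameters
    between_subject_sd: dict[str, float]
    generating_model_id: int = FULL_BIDIRECTIONAL_MODEL_ID
    generating_family: str = "bidirectional"

    @property
    def generating_model(self) -> ModelSpec:
        return make_model_spec(self.generating_model_id)


@dataclass(frozen=True)
class BehaviorConfig:
    """Trial-level response model.

    Accuracies and RT moments are the per-condition group means of the task
    (positive/negative/neutral faces and shapes); ``exclusion_rate`` is the
    probability that a trial is unusable — no button press, or a press
    faster than 100 ms — split evenly between the two mechanisms.
    """

    accuracy: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 0.966, "negative": 0.949, "neutral": 0.810, "shapes": 0.935,
        }
    )
    rt_mean: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 2.65, "negative": 2.68, "neutral": 2.74, "shapes": 2.22,
        }
    )
    rt_sd: dict[str, float] = field(
        default_factory=lambda: {
            "positive": 0.18, "negative": 0.21, "neutral": 0.26, "shapes": 0.12,
        }
    )
    exclusion_rate: float = 0.039
    rt_floor: float = 0.1
    rt_ceiling: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the subject-level generator."""

    snr: float = 8.0                 # region signal SD / noise SD (recovery-calibrated)
    voi_radius_mm: float = 6.0       # VOI sphere radius on the 2-mm voxel grid
    voxel_size_mm: float = 2.0
    gain_fwhm_scale_mm: float = 3.0  # radial decay scale of voxel gain
    voxel_noise_scale: float = 1.0   # voxel noise SD relative to region noise SD
    motion_translation_step_mm: float = 0.04
    motion_rotation_step_rad: float = 0.0004
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    params: DCMParameters
    region_ts: RegionTimeSeries
    voxel_ts: dict[str, pd.DataFrame]
    motion: np.ndarray
    behavior: pd.DataFrame
    noise_sd: np.ndarray


def default_ground_truth(
    driving_gain: float = DEFAULT_DRIVING_GAIN,
    between_subject_sd: dict[str, float] | None = None,
) -> GroundTruth:
    """Empirically seeded group truth: bidirectional modulation of all four
    prefrontal-amygdala connections with published mean magnitudes."""
    n = len(REGIONS)
    A = np.zeros((n, n))
    for (src, tgt), value in DEFAULT_A_MEANS.items():
        A[connection_index(src, tgt)] = value
    B = np.zeros((len(INPUT_NAMES), n, n))
    for (src, tgt, mod), value in DEFAULT_B_MEANS.items():
        B[INPUT_NAMES.index(mod)][connection_index(src, tgt)] = value
    C = np.zeros((n, len(INPUT_NAMES)))
    C[REGIONS.index("FFA"), INPUT_NAMES.index("all_faces")] = driving_gain
    params = DCMParameters(A=A, B=B, C=C, input_names=INPUT_NAMES)
    sd = between_subject_sd or {
        "A": 0.03, "B": 0.06, "C": 0.03, "self": 0.05, "tau_log": 0.05,
    }
    return GroundTruth(group_mean_params=params, between_subject_sd=sd)


def draw_subject_params(truth: GroundTruth, seed: int | np.random.Generator) -> DCMParameters:
    """Draw one subject's parameters around the group mean.

    Each structurally present parameter is Normal(group mean, class SD);
    structural zeros (connections absent from the generating model) stay
    exactly zero.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = truth.between_subject_sd
    if any(v < 0 for v in sd.values()):
        raise ValueError("between-subject SDs must be >= 0")
    mean = truth.group_mean_params
    spec = truth.generating_model

    A = np.where(spec.intrinsic_mask, mean.A + rng.normal(0, sd["A"], mean.A.shape), 0.0)
    B = np.where(
        spec.modulation_masks, mean.B + rng.normal(0, sd["B"], mean.B.shape), 0.0
    )
    C = np.where(spec.driving_mask, mean.C + rng.normal(0, sd["C"], mean.C.shape), 0.0)
    self_log = mean.self_log_scale + rng.normal(0, sd["self"], mean.self_log_scale.shape)
    hemo = tuple(
        HemodynamicParams(tau=h.tau * np.exp(rng.normal(0, sd["tau_log"])))
        for h in mean.hemo
    )
    return DCMParameters(
        A=A, B=B, C=C, input_names=mean.input_names, self_log_scale=self_log, hemo=hemo
    )


def voi_voxel_offsets(radius_mm: float = 6.0, voxel_size_mm: float = 2.0) -> np.ndarray:
    """Millimetre offsets of all voxel centres on the grid within the VOI sphere."""
    half = int(np.floor(radius_mm / voxel_size_mm))
    axis = np.arange(-half, half + 1) * voxel_size_mm
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(grid, axis=1) <= radius_mm + 1e-9
    return grid[keep]


def simulate_motion(
    n_volumes: int,
    rng: np.random.Generator,
    translation_step_mm: float = 0.04,
    rotation_step_rad: float = 0.0004,
) -> np.ndarray:
    """Seeded random-walk motion trace: 3 translations (mm), 3 rotations (rad)."""
    steps = np.column_stack(
        [rng.normal(0, translation_step_mm, (n_volumes, 3)),
         rng.normal(0, rotation_step_rad, (n_volumes, 3))]
    )
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def simulate_behavior(
    design: TaskDesign, config: BehaviorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Trial-level responses: correctness, RT, and unusable-trial process."""
    rows = []
    for trial_index, ev in enumerate(design.events):
        excluded = rng.random() < config.exclusion_rate
        if excluded and rng.random() < 0.5:
            responded, rt, correct = False, np.nan, False
        else:
            responded = True
            if excluded:
                rt = rng.uniform(0.0, config.rt_floor)
            else:
                lo, hi = config.rt_floor, config.rt_ceiling
                mu, s = config.rt_mean[ev.condition], config.rt_sd[ev.condition]
                rt = truncnorm.rvs((lo - mu) / s, (hi - mu) / s, mu, s, random_state=rng)
            correct = rng.random() < config.accuracy[ev.condition]
        rows.append(
            {
                "trial_index": trial_index,
                "onset": ev.onset,
                "condition": ev.condition,
                "responded": responded,
                "rt": rt,
                "correct": bool(correct),
            }
        )
    return pd.DataFrame(rows)


def simulate_subject(
    params: DCMParameters,
    design: TaskDesign,
    seed: int | np.random.Generator,
    noise_sd: np.ndarray | float | None = None,
    config: SimulationConfig | None = None,
    subject_id: str = "sub-01",
) -> SyntheticSubject:
    """Generate one subject: region BOLD, VOI voxel tables, motion, behavior.

    ``noise_sd`` may be a per-region vector, a scalar, or None — in which
    case it is derived from the clean signal as SD(signal) / config.snr.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    inputs = events_to_inputs(design)
    clean = integrate_dcm(params, inputs, design).y_hat
    n_regions = clean.shape[1]

    if noise_sd is None:
        signal_sd = clean.std(axis=0, ddof=0)
        noise_sd = signal_sd / config.snr
    noise_sd = np.broadcast_to(np.atleast_1d(np.asarray(noise_sd, float)), (n_regions,)).copy()
    if np.any(noise_sd < 0):
        raise ValueError("noise_sd must be >= 0")

    y = clean + rng.normal(0, 1, clean.shape) * noise_sd
    region_ts = RegionTimeSeries(y=y, tr=design.tr)

    offsets = voi_voxel_offsets(config.voi_radius_mm, config.voxel_size_mm)
    gains = np.exp(-np.sum(offsets**2, axis=1) / (2 * config.gain_fwhm_scale_mm**2))
    voxel_ts: dict[str, pd.DataFrame] = {}
    for i, region in enumerate(REGIONS):
        vox = (
            gains[:, None] * clean[:, i][None, :]
            + rng.normal(0, 1, (offsets.shape[0], clean.shape[0]))
            * noise_sd[i] * config.voxel_noise_scale
        )
        frame = pd.DataFrame(vox, columns=[f"vol_{t:03d}" for t in range(clean.shape[0])])
        frame.insert(0, "dz_mm", offsets[:, 2])
        frame.insert(0, "dy_mm", offsets[:, 1])
        frame.insert(0, "dx_mm", offsets[:, 0])
        voxel_ts[region] = frame

    motion = simulate_motion(
        design.n_volumes, rng, config.motion_translation_step_mm,
        config.motion_rotation_step_rad,
    )
    behavior = simulate_behavior(design, config.behavior, rng)
    return SyntheticSubject(
        subject_id=subject_id,
        params=params,
        region_ts=region_ts,
        voxel_ts=voxel_ts,
        motion=motion,
        behavior=behavior,
        noise_sd=noise_sd,
    )


def simulate_group(
    truth: GroundTruth,
    n_subjects: int = 33,
    master_seed: int = 0,
    config: SimulationConfig | None = None,
    design_config: DesignConfig | None = None,
) -> tuple[list[SyntheticSubject], dict]:
    """Generate a full group plus a manifest of ground truth and seeds.

    Per-subject seeds are spawned deterministically from ``master_seed``,
    so identical calls yield byte-identical datasets.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    config = config or SimulationConfig()
    design_config = design_config or DesignConfig(seed=master_seed)
    design = build_block_schedule(design_config)

    seed_seq = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_subjects)]
    subjects = []
    redraws = 0
    for i, sub_seed in enumerate(child_seeds):
        rng = np.random.default_rng(sub_seed)
        # subjects are drawn from the stable (integrable) region of the
        # parameter distribution: non-physiological draws are rejected
        for _attempt in range(20):
            params = draw_subject_params(truth, rng)
            try:
                subject = simulate_subject(
                    params, design, rng, config=config, subject_id=f"sub-{i + 1:02d}"
                )
                break
            except StabilityError:
                redraws += 1
        else:
            raise StabilityError(
                f"could not draw a stable parameter set for subject {i + 1} "
                "after 20 attempts; reduce between_subject_sd"
            )
        subjects.append(subject)
    manifest = {
        "n_subjects": n_subjects,
        "master_seed": master_seed,
        "subject_seeds": child_seeds,
        "generating_model_id": truth.generating_model_id,
        "generating_family": truth.generating_family,
        "between_subject_sd": truth.between_subject_sd,
        "group_mean_params": params_to_dict(truth.group_mean_params),
        "n_stability_redraws": redraws,
        "snr": config.snr,
        "design": asdict(design_config),
    }
    return subjects, manifest


def write_dataset(
    subjects: list[SyntheticSubject],
    manifest: dict,
    root: str | Path,
    design: TaskDesign,
) -> Path:
    """Write <root>/sub-XX/{events.tsv, regions.tsv, voi_<region>.tsv,
    motion.txt, behavior.tsv} plus manifest.json."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        sub_dir = root / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        write_events_tsv(design, sub_dir / "events.tsv")
        regions = pd.DataFrame(sub.region_ts.y, columns=list(sub.region_ts.region_names))
        regions.to_csv(sub_dir / "regions.tsv", sep="\t", index=False, float_format="%.8f")
        for region, table in sub.voxel_ts.items():
            table.to_csv(
                sub_dir / f"voi_{region}.tsv", sep="\t", index=False, float_format="%.6f"
            )
        write_motion_params(sub.motion, sub_dir / "motion.txt")
        sub.behavior.to_csv(sub_dir / "behavior.tsv", sep="\t", index=False)
        with open(sub_dir / "params.json", "w") as fh:
            json.dump(params_to_dict(sub.params), fh, indent=1)
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return root
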