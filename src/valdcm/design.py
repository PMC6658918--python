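"""Task paradigm construction for the dynamic face-/shape-matching block design.

The paradigm is a 6-min alternating block design: 12 blocks of 20 s (six face
blocks — two each of positive, negative and neutral valence — interleaved with
six shape blocks), each block holding five contiguous 4-s trials.  BOLD data
are acquired at TR = 2 s for 175 volumes (350 s), so the 240 s of task blocks
are embedded in fixation: a configurable initial fixation (default 10 s) plus
equal inter-block gaps that absorb the remaining scan time.

From one :class:`TaskDesign` two derived objects are built:

* :class:`InputMatrix` — microtime boxcar channels (``all_stimuli``,
  ``all_faces``, ``positive``, ``negative``, ``shapes``) that drive the
  neural state equation of the DCM.
* :class:`DesignMatrix` — the first-level GLM regressors: the five task
  channels (``all_faces``, ``positive``, ``negative``, ``neutral``,
  ``shapes``) convolved with the canonical double-gamma HRF and sampled on
  the TR grid, plus six unconvolved head-motion nuisance columns when motion
  parameters are supplied.

Timing convention: 0-based seconds from the first retained volume; every
interval is half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TrialEvent",
    "TaskDesign",
    "InputMatrix",
    "DesignMatrix",
    "DesignConfig",
    "ConfigurationError",
    "build_block_schedule",
    "events_to_inputs",
    "build_design_matrix",
    "canonical_hrf",
    "write_events_tsv",
    "read_events_tsv",
    "read_motion_params",
    "write_motion_params",
]

VALENCES = ("positive", "negative", "neutral")
CONDITIONS = VALENCES + ("shapes",)

#: order of the microtime input channels
INPUT_CHANNELS = ("all_stimuli", "all_faces", "positive", "negative", "shapes")

#: order of the GLM task regressors
TASK_REGRESSORS = ("all_faces", "positive", "negative", "neutral", "shapes")


class ConfigurationError(ValueError):
    """Raised when a design configuration cannot satisfy the paradigm invariants."""


@dataclass(frozen=True)
class TrialEvent:
    """One 4-s matching trial."""

    onset: float
    duration: float
    block_index: int
    condition: str
    is_face: bool

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"trial onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"trial duration must be > 0, got {self.duration}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class TaskDesign:
    """Complete paradigm timeline for one scan run."""

    events: tuple[TrialEvent, ...]
    scan_duration: float
    n_volumes: int
    tr: float

    @property
    def n_blocks(self) -> int:
        return len({e.block_index for e in self.events})

    @property
    def face_events(self) -> tuple[TrialEvent, ...]:
        return tuple(e for e in self.events if e.is_face)

    def events_of(self, condition: str) -> tuple[TrialEvent, ...]:
        return tuple(e for e in self.events if e.condition == condition)


@dataclass(frozen=True)
class InputMatrix:
    """Microtime boxcar channels feeding the neural state equation."""

    dt: float
    channels: dict[str, np.ndarray]
    n_bins: int

    def stack(self, names: Sequence[str]) -> np.ndarray:
        """Return channels as an (n_bins, len(names)) array in the given order."""
        return np.column_stack([self.channels[n] for n in names])


@dataclass(frozen=True)
class DesignMatrix:
    """GLM design matrix on the TR grid."""

    matrix: np.ndarray
    column_names: tuple[str, ...]
    convolution_kernel: str = "double-gamma (peak 6 s, undershoot 16 s, ratio 6, 32 s)"

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the block schedule.

    ``initial_fixation_s`` places the first block; the remaining scan time not
    covered by blocks or initial fixation is split into equal inter-block
    gaps.  The valence order of the six face blocks is a seeded permutation.
    """

    tr: float = 2.0
    n_volumes: int = 175
    block_length_s: float = 20.0
    trial_length_s: float = 4.0
    n_face_blocks: int = 6
    n_shape_blocks: int = 6
    trials_per_block: int = 5
    initial_fixation_s: float = 10.0
    #: stimulus onsets are locked to this presentation frame grid (s); it
    #: equals the default microtime step so boxcars sample identically on
    #: every refinement of that grid
    onset_grid_s: float = 0.125
    seed: int = 0

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.tr

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignConfig":
        with open(path) as fh:
            payload = json.load(fh)
        section = payload.get("design", payload)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in section.items() if k in known})


def build_block_schedule(config: DesignConfig | None = None) -> TaskDesign:
    """Lay out the alternating face/shape block timeline.

    Blocks alternate starting with a face block; face blocks receive their
    valence labels from a seeded permutation of two blocks per valence.
    Trials tile each block contiguously.

    Raises
    ------
    ConfigurationError
        If the block structure cannot host two blocks per valence or the
        schedule overflows the scan.
    """
    config = config or DesignConfig()
    n_blocks = config.n_face_blocks + config.n_shape_blocks
    if config.n_face_blocks % len(VALENCES) != 0 or config.n_face_blocks == 0:
        raise ConfigurationError(
            f"need a positive multiple of {len(VALENCES)} face blocks to balance "
            f"valences, got {config.n_face_blocks}"
        )
    if abs(config.trials_per_block * config.trial_length_s - config.block_length_s) > 1e-9:
        raise ConfigurationError("trials_per_block x trial_length_s must equal block_length_s")

    total_block_time = n_blocks * config.block_length_s
    free_time = config.scan_duration - total_block_time - config.initial_fixation_s
    if free_time < -1e-9:
        raise ConfigurationError(
            f"schedule overflows the scan: {total_block_time + config.initial_fixation_s:.1f} s "
            f"of blocks + initial fixation exceed the {config.scan_duration:.1f} s scan"
        )
    gap = free_time / (n_blocks - 1) if n_blocks > 1 else 0.0

    per_valence = config.n_face_blocks // len(VALENCES)
    rng = np.random.default_rng(config.seed)
    valence_order = list(np.repeat(VALENCES, per_valence))
    rng.shuffle(valence_order)

    events: list[TrialEvent] = []
    face_counter = 0
    for b in range(n_blocks):
        onset = config.initial_fixation_s + b * (config.block_length_s + gap)
        if config.onset_grid_s > 0:
            onset = round(onset / config.onset_grid_s) * config.onset_grid_s
        is_face = b % 2 == 0 if config.n_face_blocks > 0 else False
        if is_face:
            condition = valence_order[face_counter]
            face_counter += 1
        else:
            condition = "shapes"
        for t in range(config.trials_per_block):
            events.append(
                TrialEvent(
                    onset=onset + t * config.trial_length_s,
                    duration=config.trial_length_s,
                    block_index=b,
                    condition=condition,
                    is_face=is_face,
                )
            )

    last_end = max(e.onset + e.duration for e in events)
    if last_end > config.scan_duration + 1e-9:
        raise ConfigurationError(
            f"last event ends at {last_end:.2f} s, beyond the {config.scan_duration:.1f} s scan"
        )
    return TaskDesign(
        events=tuple(events),
        scan_duration=config.scan_duration,
        n_volumes=config.n_volumes,
        tr=config.tr,
    )


def events_to_inputs(design: TaskDesign, dt: float | None = None) -> InputMatrix:
    """Sample boxcar input channels on the microtime grid.

    ``dt`` must divide the TR (default TR/16).  Channels are binary; the
    valence channels are nonzero only during face trials of that valence and
    their union equals ``all_faces``.
    """
    if dt is None:
        dt = design.tr / 16.0
    if dt <= 0 or dt > design.tr:
        raise ValueError(f"dt must lie in (0, tr], got {dt}")
    ratio = design.tr / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"dt must divide tr: tr/dt = {ratio}")

    n_bins = int(round(design.scan_duration / dt))
    channels = {name: np.zeros(n_bins) for name in INPUT_CHANNELS + ("neutral",)}
    grid = np.arange(n_bins) * dt
    for ev in design.events:
        mask = (grid >= ev.onset - 1e-9) & (grid < ev.onset + ev.duration - 1e-9)
        channels["all_stimuli"][mask] = 1.0
        if ev.is_face:
            channels["all_faces"][mask] = 1.0
            channels[ev.condition][mask] = 1.0
        else:
            channels["shapes"][mask] = 1.0
    return InputMatrix(dt=dt, channels=channels, n_bins=n_bins)


def canonical_hrf(dt: float, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  ratio: float = 6.0, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function sampled at ``dt``.

    Difference of two gamma densities (shape = delay, unit scale), the
    undershoot scaled down by ``ratio``; normalised to unit sum so convolving
    a sustained boxcar preserves its plateau amplitude.
    """
    t = np.arange(0.0, length, dt)
    h = _gamma_dist.pdf(t, a=peak_delay) - _gamma_dist.pdf(t, a=undershoot_delay) / ratio
    return h / h.sum()


def build_design_matrix(
    design: TaskDesign,
    motion: np.ndarray | None = None,
    dt: float | None = None,
    intercept: bool = False,
) -> DesignMatrix:
    """Build the first-level GLM design matrix.

    Five task regressors are formed at microtime, convolved with the
    canonical HRF and sampled at volume acquisition times: condition
    regressors ``all_faces`` and ``shapes`` are boxcars, while the three
    valence regressors are parametric-modulation style — the valence
    indicator mean-centered across face trials (value 1 - 1/3 during trials
    of that valence, -1/3 during other face trials).  Centering makes the
    faces-versus-shapes contrast estimable even though the three modulators
    sum to zero by construction.  Six motion parameters, when given, are
    appended unconvolved; an optional intercept column (label ``constant``)
    can be appended for analyses that model the session mean.
    """
    if dt is None:
        dt = design.tr / 16.0
    inputs = events_to_inputs(design, dt)
    hrf = canonical_hrf(dt)
    step = int(round(design.tr / dt))
    sample_idx = np.arange(design.n_volumes) * step

    n_face_conditions = 3
    cols = []
    for name in TASK_REGRESSORS:
        channel = inputs.channels[name]
        if name in VALENCES:
            channel = channel - inputs.channels["all_faces"] / n_face_conditions
        conv = np.convolve(channel, hrf)[: inputs.n_bins]
        cols.append(conv[sample_idx])
    names = list(TASK_REGRESSORS)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.ndim != 2 or motion.shape != (design.n_volumes, 6):
            raise ValueError(
                f"motion must have shape ({design.n_volumes}, 6), got {motion.shape}"
            )
        cols.extend(motion.T)
        names.extend([f"motion_{i}" for i in range(1, 7)])
    if intercept:
        cols.append(np.ones(design.n_volumes))
        names.append("constant")

    X = np.column_stack(cols)
    zero = np.flatnonzero(np.all(X == 0.0, axis=0))
    if zero.size:
        raise ConfigurationError(
            f"design columns {[names[i] for i in zero]} are identically zero"
        )
    return DesignMatrix(matrix=X, column_names=tuple(names))


# ---------------------------------------------------------------------------
# plain-text interchange

def write_events_tsv(design: TaskDesign, path: str | Path) -> None:
    """Write BIDS-style events.tsv (onset, duration, trial_type, block_index)."""
    df = pd.DataFrame(
        {
            "onset": [e.onset for e in design.events],
            "duration": [e.duration for e in design.events],
            "trial_type": [e.condition for e in design.events],
            "block_index": [e.block_index for e in design.events],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path, tr: float = 2.0, n_volumes: int = 175) -> TaskDesign:
    """Read events.tsv back into a :class:`TaskDesign`."""
    df = pd.read_csv(path, sep="\t")
    events = tuple(
        TrialEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            block_index=int(r.block_index),
            condition=str(r.trial_type),
            is_face=str(r.trial_type) != "shapes",
        )
        for r in df.itertuples()
    )
    return TaskDesign(events=events, scan_duration=n_volumes * tr, n_volumes=n_volumes, tr=tr)


def write_motion_params(motion: np.ndarray, path: str | Path) -> None:
    """Write a 6-column motion trace (3 translations mm, 3 rotations rad)."""
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.8f")


def read_motion_params(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got shape {motion.shape}")
    return motion
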