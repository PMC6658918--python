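"""Enumeration of the 256-model space and its four modulation families.

All models share a fixed intrinsic skeleton over (FFA, AMY, LPFC, MPFC):
bidirectional endogenous connections MPFC<->AMY, MPFC<->LPFC and AMY<->LPFC,
feed-forward FFA->AMY and FFA->LPFC with their feedback counterparts
AMY->FFA and LPFC->FFA, and self-connections on every region.  The all-faces
input drives the FFA.  What varies is which of the four prefrontal-amygdala
connections (MPFC->AMY, MPFC->LPFC, AMY->MPFC, LPFC->MPFC) are modulated by
positive and/or negative valence: 4 connections x 2 modulators = 8 binary
switches, hence 2**8 = 256 models, indexed by the bit pattern of their id.

Families group models by the direction of their modulations: ``none`` (no
switch set, 1 model), ``bottom_up`` (all switches on AMY->MPFC or
LPFC->MPFC, 15 models), ``top_down`` (all on MPFC->AMY or MPFC->LPFC,
15 models) and ``bidirectional`` (at least one of each, 225 models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .forward import REGIONS

__all__ = [
    "ModelSpec",
    "FamilyPartition",
    "FAMILIES",
    "MODULATED_CONNECTIONS",
    "INTRINSIC_CONNECTIONS",
    "MODULATORS",
    "INPUT_NAMES",
    "enumerate_model_space",
    "assign_family",
    "family_partition",
    "reduced_space",
]

N_REGIONS = len(REGIONS)
_IDX = {name: i for i, name in enumerate(REGIONS)}

#: DCM input channels: driving input first, then the two valence modulators.
INPUT_NAMES = ("all_faces", "positive", "negative")
MODULATORS = ("positive", "negative")
DRIVING_INPUT = "all_faces"

#: endogenous connections present in every model, as (source, target) pairs
INTRINSIC_CONNECTIONS: tuple[tuple[str, str], ...] = (
    ("MPFC", "AMY"),
    ("MPFC", "LPFC"),
    ("LPFC", "MPFC"),
    ("AMY", "MPFC"),
    ("AMY", "LPFC"),
    ("LPFC", "AMY"),
    ("AMY", "FFA"),
    ("LPFC", "FFA"),
    ("FFA", "AMY"),
    ("FFA", "LPFC"),
)

#: connections eligible for valence modulation, in switch-bit order
MODULATED_CONNECTIONS: tuple[tuple[str, str], ...] = (
    ("MPFC", "AMY"),
    ("MPFC", "LPFC"),
    ("AMY", "MPFC"),
    ("LPFC", "MPFC"),
)
_TOP_DOWN = {("MPFC", "AMY"), ("MPFC", "LPFC")}
_BOTTOM_UP = {("AMY", "MPFC"), ("LPFC", "MPFC")}

FAMILIES = ("none", "bottom_up", "top_down", "bidirectional")

N_MODELS = 2 ** (len(MODULATED_CONNECTIONS) * len(MODULATORS))


def connection_index(source: str, target: str) -> tuple[int, int]:
    """(row, column) of a directed connection: row = target, column = source."""
    return _IDX[target], _IDX[source]


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one model: which couplings exist and which are modulated."""

    model_id: int
    intrinsic_mask: np.ndarray
    modulation_masks: np.ndarray  # (n_inputs, n, n); zero plane for the driving input
    driving_mask: np.ndarray      # (n, n_inputs)
    family: str
    input_names: tuple[str, ...] = INPUT_NAMES
    region_names: tuple[str, ...] = REGIONS

    def modulated_switches(self) -> tuple[tuple[str, str, str], ...]:
        """Active (source, target, modulator) switches of this model."""
        out = []
        for j, mod in enumerate(MODULATORS):
            plane = self.modulation_masks[self.input_names.index(mod)]
            for src, tgt in MODULATED_CONNECTIONS:
                r, c = connection_index(src, tgt)
                if plane[r, c]:
                    out.append((src, tgt, mod))
        return tuple(out)


def _intrinsic_mask() -> np.ndarray:
    mask = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    for src, tgt in INTRINSIC_CONNECTIONS:
        mask[connection_index(src, tgt)] = True
    return mask


def _switches_of(model_id: int) -> list[tuple[tuple[str, str], str]]:
    """Decode the id's bit pattern into (connection, modulator) switches."""
    switches = []
    for c, conn in enumerate(MODULATED_CONNECTIONS):
        for j, mod in enumerate(MODULATORS):
            if model_id >> (c * len(MODULATORS) + j) & 1:
                switches.append((conn, mod))
    return switches


def make_model_spec(model_id: int) -> ModelSpec:
    """Build the full structural spec for one model id in [0, 256)."""
    if not 0 <= model_id < N_MODELS:
        raise ValueError(f"model_id must lie in [0, {N_MODELS}), got {model_id}")
    mod_masks = np.zeros((len(INPUT_NAMES), N_REGIONS, N_REGIONS), dtype=bool)
    for (src, tgt), mod in _switches_of(model_id):
        mod_masks[INPUT_NAMES.index(mod)][connection_index(src, tgt)] = True
    driving = np.zeros((N_REGIONS, len(INPUT_NAMES)), dtype=bool)
    driving[_IDX["FFA"], INPUT_NAMES.index(DRIVING_INPUT)] = True
    return ModelSpec(
        model_id=model_id,
        intrinsic_mask=_intrinsic_mask(),
        modulation_masks=mod_masks,
        driving_mask=driving,
        family=_family_of_id(model_id),
    )


def enumerate_model_space() -> list[ModelSpec]:
    """All 256 models of the space, ordered by model id."""
    return [make_model_spec(i) for i in range(N_MODELS)]


def _family_of_id(model_id: int) -> str:
    conns = {conn for conn, _ in _switches_of(model_id)}
    has_up = bool(conns & _BOTTOM_UP)
    has_down = bool(conns & _TOP_DOWN)
    if not conns:
        return "none"
    if has_up and has_down:
        return "bidirectional"
    return "bottom_up" if has_up else "top_down"


def assign_family(spec: ModelSpec | int) -> str:
    """Classify a model by the direction of its modulated connections."""
    model_id = spec if isinstance(spec, int) else spec.model_id
    return _family_of_id(model_id)


@dataclass(frozen=True)
class FamilyPartition:
    """Family label of every model plus the per-family census."""

    family_of_model: dict[int, str]
    sizes: dict[str, int]

    @classmethod
    def from_models(cls, models: Iterable[ModelSpec]) -> "FamilyPartition":
        fam = {m.model_id: m.family for m in models}
        sizes = {f: sum(1 for v in fam.values() if v == f) for f in FAMILIES}
        return cls(family_of_model=fam, sizes=sizes)

    def members(self, family: str) -> list[int]:
        return sorted(i for i, f in self.family_of_model.items() if f == family)


def family_partition(models: Iterable[ModelSpec] | None = None) -> FamilyPartition:
    return FamilyPartition.from_models(models if models is not None else enumerate_model_space())


def reduced_space(flag: str = "full_256") -> list[ModelSpec]:
    """Deterministic sub-spaces of the 256 models for desk-scale runs.

    ``full_256``
        The complete space.
    ``per_connection_16``
        One model per subset of the four modulable connections, with both
        valences switched together (16 models; family census 1/3/3/9).
    ``families_4_representatives``
        Four models, one per family: no modulation; both valences on both
        bottom-up connections; both valences on both top-down connections;
        both valences everywhere.
    """
    if flag == "full_256":
        return enumerate_model_space()
    if flag == "per_connection_16":
        ids = []
        for subset in range(2 ** len(MODULATED_CONNECTIONS)):
            model_id = 0
            for c in range(len(MODULATED_CONNECTIONS)):
                if subset >> c & 1:
                    model_id |= 0b11 << (c * 2)
            ids.append(model_id)
        return [make_model_spec(i) for i in sorted(ids)]
    if flag == "families_4_representatives":
        both = lambda conns: sum(0b11 << (MODULATED_CONNECTIONS.index(c) * 2) for c in conns)
        ids = [
            0,
            both([("AMY", "MPFC"), ("LPFC", "MPFC")]),
            both([("MPFC", "AMY"), ("MPFC", "LPFC")]),
            both(list(MODULATED_CONNECTIONS)),
        ]
        return [make_model_spec(i) for i in sorted(ids)]
    raise ValueError(f"unknown model-space flag {flag!r}")
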