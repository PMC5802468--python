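"""Concrete cell-model builders and the model registry."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from ..core import CellModel
from .neuron import build_neuron
from .san import build_san


@dataclass(frozen=True)
class ModelRegistryEntry:
    model_id: str
    builder: Callable[[], CellModel]
    provenance: str


REGISTRY: dict[str, ModelRegistryEntry] = {
    "neuron-reduced": ModelRegistryEntry(
        "neuron-reduced", lambda: build_neuron("reduced"),
        "Reduced two-compartment layer-V pyramidal cell, Hay-type channel "
        "repertoire"),
    "san-mouse": ModelRegistryEntry(
        "san-mouse", lambda: build_san("mouse"),
        "Mouse-type single-compartment sinoatrial node cell"),
    "san-rabbit": ModelRegistryEntry(
        "san-rabbit", lambda: build_san("rabbit"),
        "Rabbit-type single-compartment sinoatrial node cell"),
}


def build_model(model_id: str) -> CellModel:
    """Build a registered control model by id (deterministic)."""
    try:
        return REGISTRY[model_id].builder()
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; available: {sorted(REGISTRY)}"
        ) from None


__all__ = ["build_neuron", "build_san", "build_model", "REGISTRY",
           "ModelRegistryEntry"]
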