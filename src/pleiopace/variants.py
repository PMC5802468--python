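"""Representation and scaling algebra of genetic-variant effects.

A variant is a named set of parameter modifications.  Offsets of
half-activation / half-inactivation / reversal potentials are *additive*
(Δ, mV) and scale linearly (Δ → s·Δ); slope factors, time-constant
multipliers, maximal conductances and the SERCA rate are *multiplicative*
(Γ, dimensionless > 0) and scale on the logarithmic scale (Γ → Γ^s).

The effective scale of an application is s = ε·c, where c ∈ [0, 1] is the
behavior-preservation threshold found by calibration and ε is the
user-chosen fraction (typically ±1/4, ±1/2; negative ε reverses the
direction of every parameter change).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import CellModel

ADD = "add"
MULT = "mult"

#: parameter-path suffixes that admit additive (mV) modifications
_ADDITIVE_SUFFIXES = ("v_off", "e_rev")
#: suffixes that admit multiplicative modifications
_MULT_SUFFIXES = ("slope_scale", "tau_scale", "gbar", "p_up")


class VariantError(ValueError):
    """Ill-formed variant effect or inapplicable modification."""


@dataclass(frozen=True)
class ParameterModification:
    """One additive (Δ) or multiplicative (Γ) change to one parameter.

    ``path`` is the canonical parameter path (e.g. ``cal12.act.v_off``,
    ``hcn.gbar``, ``serca.p_up``).  Additive mode is only valid for
    offset/reversal potentials; multiplicative mode only for slope, τ,
    conductance and uptake-rate factors.
    """

    path: str
    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in (ADD, MULT):
            raise VariantError(f"unknown modification mode {self.mode!r}")
        if self.mode == MULT and self.value <= 0:
            raise VariantError(
                f"{self.path}: multiplicative factor must be > 0, "
                f"got {self.value}")
        if self.mode == ADD and not self.path.endswith(_ADDITIVE_SUFFIXES):
            raise VariantError(
                f"{self.path}: additive mode restricted to offset/reversal "
                "potentials")
        if self.mode == MULT and not self.path.endswith(_MULT_SUFFIXES):
            raise VariantError(
                f"{self.path}: multiplicative mode restricted to slope/tau/"
                "gbar/p_up parameters")

    @property
    def neutral(self) -> bool:
        return (self.value == 0.0) if self.mode == ADD else (self.value == 1.0)


def scale_modification(mod: ParameterModification, s: float) -> ParameterModification:
    """Scale a modification by s: Δ → s·Δ (additive), Γ → Γ^s (multiplicative).

    Negative s reverses the direction of the change (Γ^(−s) = 1/Γ^s).
    """
    if not (s == s and abs(s) != float("inf")):
        raise VariantError("scale must be finite")
    if mod.mode == ADD:
        return replace(mod, value=s * mod.value)
    return replace(mod, value=mod.value ** s)


@dataclass(frozen=True)
class VariantEffect:
    """A named variant: gene symbol plus its parameter modifications."""

    variant_id: str
    gene: str
    modifications: tuple[ParameterModification, ...]
    source: str = ""
    model_scope: str = "both"          # neuron | san | both
    partial_allowed: bool = False

    def scaled(self, s: float) -> "VariantEffect":
        return replace(
            self,
            modifications=tuple(scale_modification(m, s)
                                for m in self.modifications),
        )


@dataclass(frozen=True)
class VariantApplication:
    """A variant effect together with its scaling (ε, c)."""

    effect: VariantEffect
    epsilon: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise VariantError(f"calibration threshold c must be in [0,1], got {self.c}")

    @property
    def scale(self) -> float:
        return self.epsilon * self.c


def applicable_paths(effect: VariantEffect, model: CellModel) -> list[str]:
    return [m.path for m in effect.modifications if model.has_param(m.path)]


def is_applicable(effect: VariantEffect, model: CellModel) -> bool:
    """A variant applies if every modification path resolves in the model."""
    if effect.model_scope not in ("both", model.kind):
        return False
    return all(model.has_param(m.path) for m in effect.modifications)


def apply_variant(
    model: CellModel,
    application: VariantApplication | VariantEffect,
    epsilon: float | None = None,
    c: float | None = None,
) -> CellModel:
    """Return a new model with the scaled variant applied; control untouched.

    Raises :class:`VariantError` listing the unresolvable path unless the
    effect is flagged ``partial_allowed`` (in which case unresolvable
    modifications are skipped, mirroring how partially applicable variants
    are either dropped or explicitly marked).
    """
    if isinstance(application, VariantEffect):
        application = VariantApplication(
            application,
            epsilon=1.0 if epsilon is None else epsilon,
            c=1.0 if c is None else c,
        )
    eff = application.effect
    s = application.scale
    updates: dict[str, float] = {}
    for mod in eff.modifications:
        if not model.has_param(mod.path):
            if eff.partial_allowed:
                continue
            raise VariantError(
                f"variant {eff.variant_id!r} not applicable to model "
                f"{model.name!r}: no parameter {mod.path!r}")
        scaled = scale_modification(mod, s)
        base = model.param(mod.path)
        if mod.mode == ADD:
            if mod.path not in model.additive_paths:
                raise VariantError(
                    f"{mod.path}: additive modification not allowed on this "
                    "parameter")
            updates[mod.path] = base + scaled.value
        else:
            updates[mod.path] = base * scaled.value
    if not updates:
        return model.with_params({}, suffix="")
    return model.with_params(
        updates, suffix=f"+{eff.variant_id}@{application.epsilon:g}x{application.c:g}")


# ---------------------------------------------------------------------------
# table I/O — TSV (one modification per line) and JSON mirror
# ---------------------------------------------------------------------------

_COLUMNS = ["variant_id", "gene", "model_scope", "target_path", "mode",
            "value", "units", "source"]


def effects_to_frame(effects: Iterable[VariantEffect]) -> pd.DataFrame:
    rows = []
    for eff in effects:
        for mod in eff.modifications:
            rows.append({
                "variant_id": eff.variant_id,
                "gene": eff.gene,
                "model_scope": eff.model_scope,
                "target_path": mod.path,
                "mode": mod.mode,
                "value": mod.value,
                "units": "mV" if mod.mode == ADD else "x",
                "source": eff.source,
            })
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_effects(df: pd.DataFrame) -> list[VariantEffect]:
    effects = []
    for (vid, gene), grp in df.groupby(["variant_id", "gene"], sort=False):
        scopes = set(grp["model_scope"])
        if len(scopes) != 1:
            raise VariantError(f"variant {vid}: inconsistent model_scope")
        mods = tuple(
            ParameterModification(r.target_path, r.mode, float(r.value))
            for r in grp.itertuples()
        )
        src = str(grp["source"].iloc[0]) if "source" in grp else ""
        effects.append(VariantEffect(
            variant_id=str(vid), gene=str(gene), modifications=mods,
            source=src, model_scope=scopes.pop()))
    return effects


def write_table(effects: Sequence[VariantEffect], path: str | Path,
                header_comment: str = "") -> None:
    """Write a variant table as TSV (or JSON when the suffix is .json)."""
    path = Path(path)
    df = effects_to_frame(effects)
    if path.suffix == ".json":
        payload = {"comment": header_comment,
                   "modifications": df.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> list[VariantEffect]:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["modifications"], columns=_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
    return frame_to_effects(df)
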