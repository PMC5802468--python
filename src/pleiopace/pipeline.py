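"""End-to-end analysis pipeline.

For every variant in a table: calibrate the downscaling threshold c per
model, apply the variant at the requested ε values, run the excitability
protocols (f–I curve + mean rate on neurons, pacemaking rate on SAN
cells), and assemble the variant-outcome table, cross-model correlations
and the analogous/non-analogous classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import classification_summary, classify_table, correlation_matrix, mean_rate
from .calibrate import (
    ConditionSet,
    find_threshold_c,
    neuron_reference,
    san_reference,
)
from .core import CellModel
from .models import build_model
from .protocols import fi_curve, pacemaking_frequency
from .variants import VariantApplication, VariantEffect, apply_variant, is_applicable

log = logging.getLogger("pleiopace.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    neuron_model: str = "neuron-reduced"
    san_model: str = "san-mouse"
    epsilons: tuple[float, ...] = (-0.5, -0.25, 0.25, 0.5)
    fi_amplitudes: tuple[float, ...] = (0.25, 0.35, 0.5, 0.65, 0.8, 0.95,
                                        1.1, 1.25, 1.4)
    mean_rate_range: tuple[float, float] = (0.35, 1.4)
    san_record: float = 6000.0
    san_settle: float = 2000.0
    # calibration search resolution (coarser than the library default to
    # keep many-variant sweeps affordable; precision affects outcome
    # magnitudes marginally, never their signs)
    calib_step: float = 0.2
    calib_resolution: float = 0.02
    conditions: ConditionSet = field(default_factory=ConditionSet)


@dataclass
class PipelineOutput:
    outcomes: pd.DataFrame              # per variant × ε outcome table
    calibrations: pd.DataFrame          # per variant × model c values
    correlations: dict                  # {(epsilon, gene_class|'all'): DataFrame}
    classifications: pd.DataFrame
    summary: dict


def _san_rate(model: CellModel, cfg: PipelineConfig) -> float:
    pm = pacemaking_frequency(model, record=cfg.san_record,
                              settle=cfg.san_settle)
    return pm.frequency


def run_pipeline(effects: list[VariantEffect],
                 config: PipelineConfig | None = None) -> PipelineOutput:
    cfg = config or PipelineConfig()
    neuron = build_model(cfg.neuron_model)
    san = build_model(cfg.san_model)
    cond = cfg.conditions

    n_ref = neuron_reference(neuron, cond)
    s_ref = san_reference(san, cond)
    ctrl_fi = fi_curve(neuron, cfg.fi_amplitudes)
    ctrl_mean = mean_rate(ctrl_fi, cfg.mean_rate_range)
    ctrl_san = s_ref.frequency
    log.info("control: neuron mean rate %.2f Hz (rheobase %.3f nA), "
             "SAN %.3f Hz", ctrl_mean, n_ref.rheobase, ctrl_san)

    rows = []
    calib_rows = []
    for eff in effects:
        cs = {}
        for model, ref, mid in ((neuron, n_ref, cfg.neuron_model),
                                (san, s_ref, cfg.san_model)):
            if not is_applicable(eff, model):
                cs[mid] = math.nan
                continue
            res = find_threshold_c(model, eff, cond,
                                   resolution=cfg.calib_resolution,
                                   coarse_step=cfg.calib_step,
                                   reference=ref)
            cs[mid] = res.c
        calib_rows.append({"variant_id": eff.variant_id, "gene": eff.gene,
                           **cs})
        log.info("variant %s (%s): c_neuron=%s c_san=%s",
                 eff.variant_id, eff.gene, cs.get(cfg.neuron_model),
                 cs.get(cfg.san_model))
        for eps in cfg.epsilons:
            row = {"variant_id": eff.variant_id, "gene": eff.gene,
                   "epsilon": eps}
            c_n = cs[cfg.neuron_model]
            if math.isfinite(c_n) and c_n > 0:
                m = apply_variant(neuron, VariantApplication(eff, eps, c_n))
                fi = fi_curve(m, cfg.fi_amplitudes)
                row["neuron_mean_rate"] = mean_rate(fi, cfg.mean_rate_range)
            else:
                row["neuron_mean_rate"] = math.nan
            c_s = cs[cfg.san_model]
            if math.isfinite(c_s) and c_s > 0:
                m = apply_variant(san, VariantApplication(eff, eps, c_s))
                row["san_rate"] = _san_rate(m, cfg)
            else:
                row["san_rate"] = math.nan
            rows.append(row)

    outcomes = pd.DataFrame(rows)
    from .synth import gene_class

    outcomes["gene_class"] = [gene_class(g) for g in outcomes["gene"]]
    outcomes["neuron_rel"] = outcomes["neuron_mean_rate"] / ctrl_mean - 1.0
    outcomes["san_rel"] = outcomes["san_rate"] / ctrl_san - 1.0

    correlations = {}
    class_frames = []
    for eps in cfg.epsilons:
        sub = outcomes[outcomes["epsilon"] == eps]
        for cls in (None, "ca", "na_hcn"):
            key = (eps, cls or "all")
            try:
                correlations[key] = correlation_matrix(
                    sub, ["neuron_mean_rate", "san_rate"],
                    gene_class_filter=cls)
            except ValueError:
                correlations[key] = None
        classified = classify_table(sub, "neuron_rel", "san_rel")
        class_frames.append(classified)

    classifications = pd.concat(class_frames, ignore_index=True)
    summary = {
        "control": {"neuron_mean_rate": ctrl_mean, "san_rate": ctrl_san,
                    "neuron_rheobase": n_ref.rheobase},
        "correlation": {
            f"eps={eps:+.2f}/{cls}":
                (None if correlations[(eps, cls)] is None else
                 float(correlations[(eps, cls)]
                       .loc["neuron_mean_rate", "san_rate"]))
            for eps in cfg.epsilons for cls in ("all", "ca", "na_hcn")
        },
        "classification_counts": classification_summary(
            classifications).to_json_dict(),
    }
    return PipelineOutput(outcomes, pd.DataFrame(calib_rows), correlations,
                          classifications, summary)
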