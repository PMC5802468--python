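"""Seeded generator of synthetic variant-effect tables.

The experimentally curated table of ion-channel variant effects that this
kind of analysis runs on is a literature product; this module generates
tables with the same *structure* so that every downstream stage
(calibration, protocols, correlation analysis) is testable end to end:

* seven gene classes (SCN1A, HCN1 → Na/HCN class; CACNA1C, CACNA1D,
  CACNB2, CACNA1I, ATP2A2 → Ca/transporter class), default mixture
  80 Ca/transporter : 14 Na/HCN out of 94 variants;
* each gene maps to the channel parameters its product controls
  (SCN1A → Na gates, HCN1 → funny/HCN current, CACNA1C → Cav1.2,
  CACNA1D → Cav1.3, CACNB2 → L-type conductance/inactivation,
  CACNA1I → T-type, ATP2A2 → SERCA uptake rate);
* half-point offsets Δ are drawn uniformly in ±10 mV, multiplicative
  factors Γ log-uniformly in [1/3, 3]; each variant carries 1–4
  parameter modifications.

Output is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variants import ADD, MULT, ParameterModification, VariantEffect

NA_HCN_GENES = ("SCN1A", "HCN1")
CA_GENES = ("CACNA1C", "CACNA1D", "CACNB2", "CACNA1I", "ATP2A2")

#: gene → candidate modification targets (path, mode)
GENE_TARGETS: dict[str, tuple[tuple[str, str], ...]] = {
    "SCN1A": (
        ("na.act.v_off", ADD), ("na.inact.v_off", ADD),
        ("na.act.slope_scale", MULT), ("na.inact.slope_scale", MULT),
        ("na.act.tau_scale", MULT), ("na.inact.tau_scale", MULT),
        ("na.gbar", MULT),
    ),
    "HCN1": (
        ("hcn.act.v_off", ADD), ("hcn.act.slope_scale", MULT),
        ("hcn.act.tau_scale", MULT), ("hcn.gbar", MULT),
    ),
    "CACNA1C": (
        ("cal12.act.v_off", ADD), ("cal12.inact.v_off", ADD),
        ("cal12.act.slope_scale", MULT), ("cal12.inact.slope_scale", MULT),
        ("cal12.act.tau_scale", MULT), ("cal12.inact.tau_scale", MULT),
        ("cal12.gbar", MULT),
    ),
    "CACNA1D": (
        ("cal13.act.v_off", ADD), ("cal13.inact.v_off", ADD),
        ("cal13.act.slope_scale", MULT), ("cal13.inact.slope_scale", MULT),
        ("cal13.gbar", MULT),
    ),
    "CACNB2": (
        ("cal12.gbar", MULT), ("cal12.inact.v_off", ADD),
        ("cal12.inact.tau_scale", MULT),
    ),
    "CACNA1I": (
        ("cat.act.v_off", ADD), ("cat.inact.v_off", ADD),
        ("cat.act.slope_scale", MULT), ("cat.inact.slope_scale", MULT),
        ("cat.act.tau_scale", MULT), ("cat.gbar", MULT),
    ),
    "ATP2A2": (
        ("serca.p_up", MULT),
    ),
}

#: relative gene frequencies within each class, loosely following the
#: published variant counts per gene
_CLASS_WEIGHTS = {
    "ca": {"CACNA1C": 0.38, "CACNA1D": 0.18, "CACNB2": 0.16,
           "CACNA1I": 0.16, "ATP2A2": 0.12},
    "na_hcn": {"SCN1A": 0.4, "HCN1": 0.6},
}


def gene_class(gene: str) -> str:
    """Class of a gene: 'na_hcn' or 'ca' (Ca²⁺ channels and transporters)."""
    if gene in NA_HCN_GENES:
        return "na_hcn"
    if gene in CA_GENES:
        return "ca"
    raise KeyError(f"unknown gene {gene!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    n_variants: int = 94
    seed: int = 0
    n_ca: int | None = None          # default: round(80/94 * n)
    offset_range: float = 10.0       # |Δ| upper bound, mV
    log_factor_range: float = float(np.log(3.0))   # |ln Γ| upper bound
    max_mods: int = 4

    def n_per_class(self) -> tuple[int, int]:
        n_ca = (int(round(self.n_variants * 80.0 / 94.0))
                if self.n_ca is None else self.n_ca)
        if not 0 <= n_ca <= self.n_variants:
            raise ValueError("invalid class mixture")
        return n_ca, self.n_variants - n_ca


def generate_variant_table(config: GeneratorConfig) -> list[VariantEffect]:
    """Draw a synthetic variant table; deterministic under fixed seed."""
    if config.n_variants < 1:
        raise ValueError("need at least one variant")
    rng = np.random.default_rng(config.seed)
    n_ca, n_nahcn = config.n_per_class()
    genes: list[str] = []
    for cls, n in (("ca", n_ca), ("na_hcn", n_nahcn)):
        w = _CLASS_WEIGHTS[cls]
        names = list(w)
        probs = np.array([w[g] for g in names])
        probs = probs / probs.sum()
        genes.extend(rng.choice(names, size=n, p=probs))

    effects = []
    for i, gene in enumerate(genes):
        targets = GENE_TARGETS[gene]
        n_mods = int(rng.integers(1, min(config.max_mods, len(targets)) + 1))
        picks = rng.choice(len(targets), size=n_mods, replace=False)
        mods = []
        for j in sorted(picks):
            path, mode = targets[j]
            if mode == ADD:
                value = float(rng.uniform(-config.offset_range,
                                          config.offset_range))
            else:
                value = float(np.exp(rng.uniform(-config.log_factor_range,
                                                 config.log_factor_range)))
            mods.append(ParameterModification(path, mode, value))
        effects.append(VariantEffect(
            variant_id=f"V{i + 1:03d}",
            gene=str(gene),
            modifications=tuple(mods),
            source=f"synthetic seed={config.seed}",
        ))
    return effects


def provenance_comment(config: GeneratorConfig) -> str:
    n_ca, n_nahcn = config.n_per_class()
    return (
        "synthetic variant-effect table\n"
        f"n_variants={config.n_variants} (ca={n_ca}, na_hcn={n_nahcn}) "
        f"seed={config.seed}\n"
        f"offsets ~ U(-{config.offset_range},{config.offset_range}) mV; "
        f"factors ~ exp(U(-{config.log_factor_range:.4f},"
        f"{config.log_factor_range:.4f}))"
    )
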