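"""Aggregation and cross-model comparison of variant effects.

The core outputs are (i) a variant-outcome table — one row per variant,
one column per model, holding mean firing rate (neurons, averaged over a
stated stimulus-amplitude range) or pacemaking rate (SAN cells) at a
stated ε — (ii) Pearson correlation matrices between model columns,
optionally restricted to a gene class, and (iii) an analogous /
non-analogous / neutral classification of each variant's joint effect on
neuron firing and SAN pacemaking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocols import FICurve
from .synth import gene_class

DEFAULT_DEAD_BAND = 0.01   # 1% relative change


def mean_rate(fi: FICurve, amp_range: tuple[float, float]) -> float:
    """Arithmetic mean firing rate over amplitudes inside a closed interval."""
    lo, hi = amp_range
    mask = (fi.amplitudes >= lo) & (fi.amplitudes <= hi)
    if not np.any(mask):
        raise ValueError(
            f"amplitude range [{lo}, {hi}] does not intersect the curve")
    return float(np.mean(fi.frequencies[mask]))


def outcome_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a variant-outcome table from per-variant dicts.

    Each dict needs 'variant_id', 'gene' and one entry per model column;
    the gene class is derived from the gene symbol.
    """
    df = pd.DataFrame(rows)
    df["gene_class"] = [gene_class(g) for g in df["gene"]]
    cols = ["variant_id", "gene", "gene_class"]
    other = [c for c in df.columns if c not in cols]
    return df[cols + other]


def correlation_matrix(
    table: pd.DataFrame,
    model_columns: list[str],
    gene_class_filter: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation between per-model outcome columns.

    Rows with any missing model value are dropped (inapplicable variants
    are omitted, not partially used).  A column with zero variance yields
    NaN entries — flagged as undefined rather than raising.
    """
    df = table
    if gene_class_filter is not None:
        df = df[df["gene_class"] == gene_class_filter]
    df = df.dropna(subset=model_columns)
    if len(df) < 3:
        raise ValueError(
            "need at least 3 complete variant rows for a correlation")
    sub = df[model_columns].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.corrcoef(sub.to_numpy().T)
    out = pd.DataFrame(mat, index=model_columns, columns=model_columns)
    np.fill_diagonal(out.values, 1.0)
    return out


def classify_pleiotropy(
    neuron_change: float,
    san_change: float,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> str:
    """Classify a variant's joint effect signature.

    Same sign outside the dead band → 'analogous'; opposite signs →
    'non-analogous'; either change inside the dead band → 'neutral'.
    """
    if abs(neuron_change) <= dead_band or abs(san_change) <= dead_band:
        return "neutral"
    return ("analogous" if math.copysign(1, neuron_change)
            == math.copysign(1, san_change) else "non-analogous")


@dataclass(frozen=True)
class ClassificationSummary:
    counts: dict

    def to_json_dict(self) -> dict:
        return {cls: dict(v) for cls, v in self.counts.items()}


def classify_table(
    table: pd.DataFrame,
    neuron_column: str,
    san_column: str,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> pd.DataFrame:
    """Per-variant classification from relative-change columns."""
    out = table.copy()
    out["classification"] = [
        classify_pleiotropy(n, s, dead_band) if not (pd.isna(n) or pd.isna(s))
        else "inapplicable"
        for n, s in zip(out[neuron_column], out[san_column])
    ]
    return out


def classification_summary(classified: pd.DataFrame) -> ClassificationSummary:
    counts: dict = {}
    for cls, grp in classified.groupby("gene_class"):
        counts[cls] = grp["classification"].value_counts().to_dict()
    return ClassificationSummary(counts)
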