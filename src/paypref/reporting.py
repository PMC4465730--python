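"""Relative attribute importance and golden-standard utility standardization.

Two reporting scales are produced from a fitted choice model:

* *Relative importance* — per attribute, ``-log(p)`` of its likelihood-ratio
  test, rescaled so the most significant attribute scores exactly 100.  The
  scaled score ``100 * log(p_attr) / log(p_min)`` is invariant to the
  logarithm base.
* *Standardized marginal utilities* — every level utility divided by the
  absolute value of a reference coefficient (the pooled main-effect utility
  of a deterioration in the reference attribute), so the reference reads
  exactly -1 and all other values are expressed on its scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import AttributeSchema, LEVELS

#: numeric floor for p-values; values at/below it are clamped and flagged
P_FLOOR = 1e-300


class ReportingError(ValueError):
    pass


def importance_table(lr_table: pd.DataFrame) -> pd.DataFrame:
    """Attribute importance from an LR-test table.

    Input columns: ``attribute``, ``p_value`` (``statistic``/``df`` carried
    through when present).  Output adds ``raw_importance`` (``-log10 p``),
    ``scaled_importance`` in [0, 100] (minimum-p attribute exactly 100) and a
    ``p_clamped`` flag; rows are sorted by descending importance.
    """
    df = lr_table.copy()
    p = df["p_value"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ReportingError("p-values must lie in [0, 1]")
    clamped = p <= P_FLOOR
    p = np.clip(p, P_FLOOR, 1.0)
    logp = np.log(p)
    log_pmin = logp.min()
    if log_pmin == 0.0:  # all p == 1: degenerate, everything equally (un)important
        scaled = np.full_like(logp, 100.0)
    else:
        # ratio first, so the minimum-p attribute scores exactly 100
        scaled = 100.0 * (logp / log_pmin)
    df["p_clamped"] = clamped
    df["raw_importance"] = -np.log10(p)
    df["scaled_importance"] = scaled
    return df.sort_values("scaled_importance", ascending=False, kind="stable").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class StandardizedUtilities:
    """Per-(attribute, level) standardized marginal utilities for one context."""

    table: pd.DataFrame  # columns: attribute, level, utility
    reference_attribute_id: str
    reference_level: str
    denominator: float  # |pooled raw reference utility|
    context: dict

    def value(self, attribute_id: str, level: str) -> float:
        m = self.table[
            (self.table["attribute"] == attribute_id) & (self.table["level"] == level)
        ]
        if m.empty:
            raise ReportingError(f"no utility for ({attribute_id!r}, {level!r})")
        return float(m["utility"].iloc[0])

    def triple(self, attribute_id: str) -> tuple[float, float, float]:
        return tuple(self.value(attribute_id, lvl) for lvl in LEVELS)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def standardize(
    results, schema: AttributeSchema, context: Mapping[str, float] | None = None
) -> StandardizedUtilities:
    """Standardize all level utilities to the golden-standard reference.

    The denominator is always the *pooled* main-effect reference utility
    (in absolute value), also when a subgroup ``context`` is supplied — this
    keeps subgroup utilities comparable across contexts.  In the pooled
    context the reference level maps to exactly -1.
    """
    ref_pooled = results.level_utilities(schema.reference_attribute_id, context=None)
    ref_raw = ref_pooled[LEVELS.index(schema.reference_level)]
    denom = abs(ref_raw)
    if denom < 1e-8:
        raise ReportingError(
            "reference utility is numerically zero; standardization undefined"
        )
    rows = []
    for a in schema:
        triple = results.level_utilities(a.id, context=context)
        for lvl, u in zip(LEVELS, triple):
            rows.append({"attribute": a.id, "level": lvl, "utility": u / denom})
    return StandardizedUtilities(
        table=pd.DataFrame(rows),
        reference_attribute_id=schema.reference_attribute_id,
        reference_level=schema.reference_level,
        denominator=denom,
        context=dict(context or {}),
    )


def ratio_excess(a: float, b: float) -> float:
    """Proportional excess ``a / b - 1`` between two (standardized) utilities."""
    if b == 0:
        raise ReportingError("ratio_excess undefined for b = 0")
    return a / b - 1.0


# ---------------------------------------------------------------------------
# Plots (optional; mirror the importance-bar and level-utility-bar layouts)
# ---------------------------------------------------------------------------

def plot_importance(table: pd.DataFrame, ax=None):
    """Horizontal bar chart of scaled attribute importance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t = table.sort_values("scaled_importance")
    ax.barh(t["attribute"], t["scaled_importance"], color="#33658a")
    ax.set_xlabel("relative importance (most important = 100)")
    ax.set_xlim(0, 105)
    return ax


def plot_level_utilities(utils: StandardizedUtilities, ax=None):
    """Grouped bars of standardized positive / no-change / negative utilities."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    attrs = utils.table["attribute"].unique()
    x = np.arange(len(attrs))
    width = 0.27
    colors = {"positive": "#4c9f70", "no_change": "#b8b8b8", "negative": "#c44536"}
    for k, lvl in enumerate(LEVELS):
        vals = [utils.value(a, lvl) for a in attrs]
        ax.bar(x + (k - 1) * width, vals, width, label=lvl, color=colors[lvl])
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(x, attrs, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("standardized marginal utility")
    ax.legend()
    return ax
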