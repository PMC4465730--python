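"""Scenario total-utility comparison between payment systems.

A *scenario* assigns one outcome level to every performance domain; its total
utility for a stakeholder subgroup is the sum of the subgroup's standardized
marginal utilities at those levels.  The status-quo baseline sets every
domain to ``no_change``.  Reports compare the two totals per
(area, stakeholder-role) cell via the relative difference
``(U_after - U_before) / U_before`` and summarize cross-stakeholder alignment
as the change in the absolute utility gap between role pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .reporting import StandardizedUtilities, standardize
from .schema import AttributeSchema, SchemaError, normalize_level

#: (area, role) grid of the study report, in display order
REPORT_AREAS = ("canada", "oceania", "eastern_europe", "western_europe", "us")
REPORT_ROLES = ("physician", "policy_maker", "executive", "researcher")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class Scenario:
    """A named outcome-level assignment, complete over the schema."""

    name: str
    outcomes: dict  # attribute id -> level label

    def validate(self, schema: AttributeSchema) -> "Scenario":
        missing = set(schema.ids) - set(self.outcomes)
        if missing:
            raise ScenarioError(f"scenario {self.name!r} missing attributes: {sorted(missing)}")
        extra = set(self.outcomes) - set(schema.ids)
        if extra:
            raise ScenarioError(f"scenario {self.name!r} has unknown attributes: {sorted(extra)}")
        norm = {a: normalize_level(l) for a, l in self.outcomes.items()}
        return Scenario(self.name, norm)

    @classmethod
    def from_yaml(cls, path, schema: AttributeSchema) -> "Scenario":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(name=str(doc["name"]), outcomes=dict(doc["outcomes"])).validate(schema)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"name": self.name, "outcomes": dict(self.outcomes)}, fh)


def status_quo_scenario(schema: AttributeSchema) -> Scenario:
    """Every domain at no change — the current payment system baseline."""
    return Scenario("status_quo", {a: "no_change" for a in schema.ids})


#: The proposed payment reform: five domains improve, five deteriorate as
#: unintended consequences, care equity stays at the status quo.
_REFORM_IMPROVED = (
    "effectiveness_safety",
    "long_term_cost",
    "best_practice",
    "coordination",
    "innovation",
)
_REFORM_DETERIORATED = (
    "provider_wellness",
    "patient_centeredness",
    "timeliness",
    "gaming",
    "short_term_cost",
)


def reform_scenario_default(schema: AttributeSchema) -> Scenario:
    """The default reform scenario on the study schema."""
    outcomes = {}
    for aid in schema.ids:
        if aid in _REFORM_IMPROVED:
            outcomes[aid] = "positive"
        elif aid in _REFORM_DETERIORATED:
            outcomes[aid] = "negative"
        else:
            outcomes[aid] = "no_change"
    return Scenario("payment_reform", outcomes).validate(schema)


def total_utility(utilities: StandardizedUtilities, scenario: Scenario) -> float:
    """Sum of the context's standardized marginal utilities at the scenario's
    outcome levels; additive over any partition of the attributes."""
    return float(
        sum(utilities.value(aid, lvl) for aid, lvl in scenario.outcomes.items())
    )


def relative_difference(u_before: float, u_after: float) -> float:
    """``(u_after - u_before) / u_before``; undefined at a zero baseline.

    For negative baselines the sign of the result flips relative to the
    intuitive "gain" reading; report rows carry a ``baseline_negative`` flag
    so such cells can be interpreted (or excluded) explicitly.
    """
    if u_before == 0:
        raise ScenarioError("relative difference undefined for a zero baseline")
    return (u_after - u_before) / u_before


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def subgroup_context(area: str | None = None, role: str | None = None) -> dict:
    """Covariate context of an (area, role) cell: role indicator plus area
    indicator, main effects otherwise (no area-by-role terms)."""
    ctx: dict[str, float] = {}
    if role is not None:
        ctx[role] = 1.0
    if area is not None:
        ctx[f"area_{area}"] = 1.0
    return ctx


def utility_report(
    results,
    schema: AttributeSchema,
    scenario: Scenario,
    areas: Sequence[str] = REPORT_AREAS,
    roles: Sequence[str] = REPORT_ROLES,
) -> pd.DataFrame:
    """Total utilities before/after reform per (area, role) cell.

    Columns: ``area, role, u_status_quo, u_scenario, relative_difference,
    baseline_negative``; the relative difference is reported rounded to two
    decimals (half-up), recomputable from the row's unrounded utilities.
    """
    scenario = scenario.validate(schema)
    sq = status_quo_scenario(schema)
    rows = []
    for area in areas:
        for role in roles:
            utils = standardize(results, schema, subgroup_context(area, role))
            u0 = total_utility(utils, sq)
            u1 = total_utility(utils, scenario)
            rows.append(
                {
                    "area": area,
                    "role": role,
                    "u_status_quo": u0,
                    "u_scenario": u1,
                    "relative_difference": round_half_up(relative_difference(u0, u1))
                    if u0 != 0
                    else float("nan"),
                    "baseline_negative": u0 < 0,
                }
            )
    return pd.DataFrame(rows)


def alignment_change(report: pd.DataFrame, role_a: str, role_b: str) -> pd.DataFrame:
    """Per-area absolute utility gaps between two roles, before and after.

    ``narrowed`` is true where the scenario gap is strictly smaller than the
    status-quo gap — the stakeholder-alignment reading of the comparison.
    """
    for role in (role_a, role_b):
        if not (report["role"] == role).any():
            raise ScenarioError(f"role {role!r} missing from report")
    rows = []
    for area, grp in report.groupby("area", sort=False):
        a = grp[grp["role"] == role_a]
        b = grp[grp["role"] == role_b]
        if a.empty or b.empty:
            raise ScenarioError(f"area {area!r} lacks rows for both roles")
        gap0 = abs(float(a["u_status_quo"].iloc[0]) - float(b["u_status_quo"].iloc[0]))
        gap1 = abs(float(a["u_scenario"].iloc[0]) - float(b["u_scenario"].iloc[0]))
        rows.append(
            {
                "area": area,
                "gap_status_quo": gap0,
                "gap_scenario": gap1,
                "narrowed": gap1 < gap0,
            }
        )
    return pd.DataFrame(rows)
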