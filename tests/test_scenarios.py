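"""Scenario total utilities, relative differences and alignment."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import paypref as pp
from paypref.reporting import StandardizedUtilities
from paypref.scenarios import (
    Scenario,
    ScenarioError,
    alignment_change,
    relative_difference,
    round_half_up,
    status_quo_scenario,
    total_utility,
    utility_report,
)

from conftest import make_schema


def _utils(schema, values):
    rows = [
        {"attribute": a, "level": lvl, "utility": values[(a, lvl)]}
        for a in schema.ids
        for lvl in ("positive", "no_change", "negative")
    ]
    return StandardizedUtilities(
        table=pd.DataFrame(rows),
        reference_attribute_id=schema.reference_attribute_id,
        reference_level=schema.reference_level,
        denominator=1.0,
        context={},
    )


class TestReformScenarioDefault:
    def test_care_equity_stays_at_status_quo(self, study_schema):
        sc = pp.reform_scenario_default(study_schema)
        assert sc.outcomes["care_equity"] == "no_change"

    def test_exactly_five_improvements(self, study_schema):
        sc = pp.reform_scenario_default(study_schema)
        assert sum(lvl == "positive" for lvl in sc.outcomes.values()) == 5

    def test_gaming_deteriorates(self, study_schema):
        sc = pp.reform_scenario_default(study_schema)
        assert sc.outcomes["gaming"] == "negative"

    def test_incomplete_scenario_rejected(self, study_schema):
        with pytest.raises(ScenarioError):
            Scenario("partial", {"gaming": "negative"}).validate(study_schema)


class TestTotalUtility:
    def test_zero_no_change_utilities(self):
        schema = make_schema(2)
        vals = {(a, l): 0.0 for a in schema.ids for l in ("positive", "no_change", "negative")}
        assert total_utility(_utils(schema, vals), status_quo_scenario(schema)) == 0.0

    def test_two_attribute_addition(self):
        schema = make_schema(2)
        vals = {(a, l): 0.0 for a in schema.ids for l in ("positive", "no_change", "negative")}
        vals[("a1", "positive")] = 0.5
        vals[("a2", "negative")] = -0.3
        sc = Scenario("mix", {"a1": "positive", "a2": "negative"}).validate(schema)
        assert total_utility(_utils(schema, vals), sc) == pytest.approx(0.2)

    @given(st.lists(st.floats(-2, 2), min_size=8, max_size=8))
    def test_additive_over_attribute_partition(self, raw):
        """Splitting the attributes into two sub-scenarios and summing the
        sub-totals equals the full total, exactly."""
        schema = make_schema(4)
        it = iter(raw)
        vals = {}
        levels = {}
        for i, a in enumerate(schema.ids):
            for l in ("positive", "no_change", "negative"):
                vals[(a, l)] = 0.0
            lvl = ("positive", "negative")[i % 2]
            vals[(a, lvl)] = next(it, 0.0)
            levels[a] = lvl
        utils = _utils(schema, vals)
        full = Scenario("full", levels).validate(schema)
        total = total_utility(utils, full)
        part = sum(vals[(a, levels[a])] for a in schema.ids)
        assert total == pytest.approx(part, abs=1e-12)


# the 17 positive-baseline rows of the published before/after utility table
POSITIVE_BASELINE_ROWS = [
    ("canada", "physician", 0.61, 0.48, -0.21),
    ("canada", "executive", 0.37, 0.48, 0.30),
    ("canada", "researcher", 0.42, 1.18, 1.81),
    ("oceania", "physician", 1.57, 1.18, -0.25),
    ("oceania", "policy_maker", 0.92, 1.52, 0.65),
    ("oceania", "executive", 1.33, 1.18, -0.11),
    ("oceania", "researcher", 1.38, 1.88, 0.36),
    ("eastern_europe", "physician", 0.22, 1.40, 5.36),
    ("eastern_europe", "researcher", 0.03, 2.10, 69.00),
    ("western_europe", "physician", 0.96, 0.80, -0.17),
    ("western_europe", "policy_maker", 0.31, 1.14, 2.68),
    ("western_europe", "executive", 0.72, 0.80, 0.11),
    ("western_europe", "researcher", 0.77, 1.50, 0.95),
    ("us", "physician", 1.00, 1.23, 0.23),
    ("us", "policy_maker", 0.35, 1.57, 3.49),
    ("us", "executive", 0.76, 1.23, 0.62),
    ("us", "researcher", 0.81, 1.93, 1.38),
]


class TestRelativeDifference:
    @pytest.mark.parametrize("area,role,before,after,printed", POSITIVE_BASELINE_ROWS)
    def test_published_rows_reproduce(self, area, role, before, after, printed):
        assert round_half_up(relative_difference(before, after)) == pytest.approx(printed)

    def test_identity_at_equal_utilities(self):
        assert relative_difference(0.7, 0.7) == 0.0

    @given(st.floats(0.05, 5.0), st.floats(-0.9, 3.0))
    def test_algebraic_identity(self, u, r):
        assert relative_difference(u, u * (1 + r)) == pytest.approx(r, abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ScenarioError):
            relative_difference(0.0, 1.0)


class TestAlignment:
    def _report(self, rows):
        return pd.DataFrame(
            rows,
            columns=["area", "role", "u_status_quo", "u_scenario"],
        )

    def test_published_canada_pair_narrows(self):
        report = self._report(
            [
                ("canada", "physician", 0.61, 0.48),
                ("canada", "policy_maker", -0.04, 0.82),
            ]
        )
        out = alignment_change(report, "physician", "policy_maker")
        row = out.iloc[0]
        assert row["gap_status_quo"] == pytest.approx(0.65)
        assert row["gap_scenario"] == pytest.approx(0.34)
        assert bool(row["narrowed"])

    def test_identical_utilities_not_narrowed(self):
        report = self._report(
            [("us", "physician", 0.4, 0.9), ("us", "executive", 0.4, 0.9)]
        )
        out = alignment_change(report, "physician", "executive")
        assert out.iloc[0]["gap_status_quo"] == 0.0
        assert not bool(out.iloc[0]["narrowed"])

    def test_matches_pairing_oracle_on_shuffled_report(self):
        rng = np.random.default_rng(8)
        rows = []
        for area in ("canada", "us", "oceania"):
            for role in ("physician", "policy_maker"):
                rows.append((area, role, rng.normal(), rng.normal()))
        report = self._report(rows).sample(frac=1.0, random_state=3).reset_index(drop=True)
        out = alignment_change(report, "physician", "policy_maker").set_index("area")
        # brute-force pairing oracle
        for area in ("canada", "us", "oceania"):
            sub = {r[1]: (r[2], r[3]) for r in rows if r[0] == area}
            gap0 = abs(sub["physician"][0] - sub["policy_maker"][0])
            gap1 = abs(sub["physician"][1] - sub["policy_maker"][1])
            assert out.loc[area, "gap_status_quo"] == pytest.approx(gap0)
            assert out.loc[area, "gap_scenario"] == pytest.approx(gap1)

    def test_missing_role_rejected(self):
        report = self._report([("us", "physician", 0.4, 0.9)])
        with pytest.raises(ScenarioError):
            alignment_change(report, "physician", "researcher")


class TestUtilityReport:
    def test_table_structure_and_recomputability(self, full_fit, study_schema):
        sc = pp.reform_scenario_default(study_schema)
        report = utility_report(full_fit, study_schema, sc)
        assert list(report.columns) == [
            "area",
            "role",
            "u_status_quo",
            "u_scenario",
            "relative_difference",
            "baseline_negative",
        ]
        assert len(report) == 5 * 4
        for _, row in report.iterrows():
            if row["u_status_quo"] != 0:
                rd = round_half_up(
                    relative_difference(row["u_status_quo"], row["u_scenario"])
                )
                assert row["relative_difference"] == pytest.approx(rd)
            assert row["baseline_negative"] == (row["u_status_quo"] < 0)
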