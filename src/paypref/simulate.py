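"""Synthetic respondent population and choice-behavior simulator.

The generator emulates the structure of the payment-reform preference survey:
547 respondents carrying one or more stakeholder roles (physician, policy
maker, healthcare executive, researcher), one of five geographical areas,
demographics (age, seniority, sex) and the payment forms currently in use to
pay physicians.  Respondents are dealt round-robin across the survey blocks,
answer each of their block's choice sets independently with a fixed
completion probability (study rate 87%), and choose between the two profiles
of an answered set with multinomial-logit probabilities under a configurable
"truth" coefficient vector with subgroup interaction offsets.

Characteristics are sampled independently of one another: the study reports
only marginal frequencies, not a joint distribution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .design import ChoiceDesign, DesignError, _difference_matrix
from .schema import AttributeSchema, SHORT_LABELS, TO_SHORT, triples_to_beta

ROLES = ("physician", "policy_maker", "executive", "researcher")
AREAS = ("canada", "eastern_europe", "western_europe", "oceania", "us")
PAYMENT_SYSTEMS = (
    "pay_salary",
    "pay_fee_for_service",
    "pay_episode_based",
    "pay_capitation",
    "pay_quality_bonus",
    "pay_case_rate",
    "pay_warranty",
)

#: Study sample size and survey length.
N_RESPONDENTS = 547
SETS_PER_RESPONDENT = 18
COMPLETION_RATE = 0.87

#: Marginal frequencies of the study population (respondent characteristics
#: table); roles and payment systems are non-exclusive.
STUDY_MARGINS: dict = {
    "roles": {
        "physician": 0.67,
        "policy_maker": 0.22,
        "executive": 0.34,
        "researcher": 0.30,
    },
    "areas": {
        "canada": 0.10,
        "eastern_europe": 0.09,
        "western_europe": 0.25,
        "oceania": 0.18,
        "us": 0.37,
    },
    "female": 0.31,
    "age": {"mean": 50.0, "sd": 11.0, "lo": 25.0, "hi": 85.0},
    "seniority": {"mean": 23.0, "sd": 11.0, "lo": 0.0, "hi": 60.0},
    "payment_systems": {
        "pay_salary": 0.67,
        "pay_fee_for_service": 0.60,
        "pay_episode_based": 0.06,
        "pay_capitation": 0.16,
        "pay_quality_bonus": 0.16,
        "pay_case_rate": 0.02,
        "pay_warranty": 0.01,
    },
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class RespondentProfile:
    """One synthetic survey respondent."""

    id: str
    roles: frozenset[str]
    area: str
    age: float
    seniority: float
    female: bool
    payment_systems: frozenset[str]
    block: int

    def __post_init__(self) -> None:
        if not self.roles:
            raise SimulationError(f"respondent {self.id}: at least one role required")
        if self.area not in AREAS:
            raise SimulationError(f"respondent {self.id}: unknown area {self.area!r}")
        if not (self.age >= self.seniority >= 0):
            raise SimulationError(
                f"respondent {self.id}: need age >= seniority >= 0 "
                f"(got {self.age}, {self.seniority})"
            )


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_population(
    n: int,
    margins: Mapping | None = None,
    seed: int = 0,
    n_blocks: int = 3,
) -> list[RespondentProfile]:
    """Sample *n* respondents with the given marginal frequencies.

    Roles are independent Bernoulli draws (redrawn if a respondent ends up
    with none); areas are a single categorical draw; ages and seniorities are
    truncated normals, with seniority capped at age.  Survey blocks are dealt
    round-robin so each survey is filled out a near-equal number of times.
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    m = dict(STUDY_MARGINS if margins is None else margins)
    for key in ("roles", "areas", "payment_systems"):
        for v in m[key].values():
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"margin for {key} outside [0, 1]: {v}")
    if not (0.0 <= m["female"] <= 1.0):
        raise SimulationError("female margin outside [0, 1]")
    rng = np.random.default_rng(seed)

    role_names = list(m["roles"])
    target = np.array([m["roles"][r] for r in role_names])
    # Redrawing role-less respondents conditions on "at least one role", which
    # inflates every marginal; solve q = target * (1 - prod(1 - q)) by fixed
    # point so the *conditional* margins hit the targets.
    role_p = target.copy()
    if np.all(target < 1.0) and target.sum() > 0:
        for _ in range(100):
            p_empty = np.prod(1.0 - np.clip(role_p, 0.0, 1.0))
            new = target * (1.0 - p_empty)
            if np.max(np.abs(new - role_p)) < 1e-12:
                break
            role_p = new
    roles = rng.random((n, len(role_names))) < role_p
    empty = ~roles.any(axis=1)
    while empty.any():  # respondents must carry at least one role
        roles[empty] = rng.random((int(empty.sum()), len(role_names))) < role_p
        empty = ~roles.any(axis=1)

    area_names = list(m["areas"])
    area_p = np.array([m["areas"][a] for a in area_names], dtype=float)
    area_p = area_p / area_p.sum()
    areas = rng.choice(len(area_names), size=n, p=area_p)

    age = _truncated_normal(rng, n, **m["age"])
    seniority = np.minimum(_truncated_normal(rng, n, **m["seniority"]), age)
    female = rng.random(n) < m["female"]

    pay_names = list(m["payment_systems"])
    pay_p = np.array([m["payment_systems"][p] for p in pay_names])
    pays = rng.random((n, len(pay_names))) < pay_p

    out = []
    for i in range(n):
        out.append(
            RespondentProfile(
                id=f"r{i + 1:04d}",
                roles=frozenset(r for j, r in enumerate(role_names) if roles[i, j]),
                area=area_names[areas[i]],
                age=float(age[i]),
                seniority=float(seniority[i]),
                female=bool(female[i]),
                payment_systems=frozenset(
                    p for j, p in enumerate(pay_names) if pays[i, j]
                ),
                block=i % n_blocks,
            )
        )
    return out


def respondents_frame(population: Sequence[RespondentProfile]) -> pd.DataFrame:
    """Flatten respondents into a covariate table (roles and payment systems as
    0/1 indicator columns)."""
    rows = []
    for r in population:
        row = {
            "respondent_id": r.id,
            "area": r.area,
            "age": r.age,
            "seniority": r.seniority,
            "female": int(r.female),
            "block": r.block,
        }
        for role in ROLES:
            row[role] = int(role in r.roles)
        for p in PAYMENT_SYSTEMS:
            row[p] = int(p in r.payment_systems)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthSpec:
    """Data-generating coefficients for the simulator.

    ``base`` holds the effects-coded main effects; ``interactions`` maps
    ``(covariate, attribute)`` to a 2-vector of coded coefficient offsets that
    apply in proportion to the respondent's covariate value.
    """

    base: np.ndarray
    interactions: dict = field(default_factory=dict)
    completion: float = COMPLETION_RATE

    def __post_init__(self) -> None:
        base = np.asarray(self.base, dtype=float)
        object.__setattr__(self, "base", base)
        if not (0.0 < self.completion <= 1.0):
            raise SimulationError("completion probability must lie in (0, 1]")
        for key, off in self.interactions.items():
            off = np.asarray(off, dtype=float)
            if off.shape != (2,):
                raise SimulationError(
                    f"interaction offset {key} must be a 2-vector of coded "
                    f"coefficients, got shape {off.shape}"
                )
            self.interactions[key] = off

    @classmethod
    def from_level_utilities(
        cls,
        schema: AttributeSchema,
        main: Mapping[str, Sequence[float]],
        interactions: Mapping[tuple, Sequence[float]] | None = None,
        completion: float = COMPLETION_RATE,
    ) -> "TruthSpec":
        """Build a truth from per-attribute (positive, no_change, negative)
        utility triples; triples are centered into effects-coding space."""
        from .schema import triple_to_coded

        base = triples_to_beta(schema, main)
        inter = {}
        if interactions:
            for (cov, aid), triple in interactions.items():
                inter[(cov, aid)] = triple_to_coded(triple)
        return cls(base=base, interactions=inter, completion=completion)


#: Default truth level-utility triples (positive, no_change, negative), on the
#: standardized scale where a deterioration in effectiveness/safety is -1.
#: Avoidance outweighs improvement everywhere except long-term cost
#: containment and gaming, whose status-quo utilities are slightly negative.
STUDY_TRUTH_MAIN: dict[str, tuple[float, float, float]] = {
    "effectiveness_safety": (0.90, 0.10, -1.00),
    "long_term_cost": (0.56, -0.05, -0.51),
    "best_practice": (0.50, 0.04, -0.54),
    "coordination": (0.47, 0.04, -0.51),
    "provider_wellness": (0.44, 0.04, -0.48),
    "innovation": (0.38, 0.03, -0.41),
    "patient_centeredness": (0.35, 0.03, -0.38),
    "timeliness": (0.32, 0.02, -0.34),
    "care_equity": (0.31, 0.02, -0.33),
    "gaming": (0.33, -0.03, -0.30),
    "short_term_cost": (0.30, 0.02, -0.32),
}

#: Subgroup interaction offsets, with the signs of the reported heterogeneity:
#: physicians weight effectiveness avoidance, coordination, provider wellness
#: and timeliness up and short-term cost containment down; policy makers shift
#: gaming toward improvement; executives weight provider wellness up;
#: researchers weight effectiveness and long-term cost containment up; Oceania
#: (Canada) weights effectiveness most (least).
STUDY_TRUTH_INTERACTIONS: dict[tuple, tuple[float, float, float]] = {
    ("physician", "effectiveness_safety"): (0.05, 0.03, -0.08),
    ("physician", "coordination"): (0.04, 0.01, -0.05),
    ("physician", "provider_wellness"): (0.08, 0.02, -0.10),
    ("physician", "timeliness"): (0.05, 0.01, -0.06),
    ("physician", "short_term_cost"): (-0.04, 0.00, 0.04),
    ("policy_maker", "gaming"): (0.04, -0.07, 0.03),
    ("executive", "provider_wellness"): (0.06, 0.02, -0.08),
    ("researcher", "effectiveness_safety"): (0.05, 0.02, -0.07),
    ("researcher", "long_term_cost"): (0.07, 0.02, -0.09),
    ("area_oceania", "effectiveness_safety"): (0.08, 0.02, -0.10),
    ("area_canada", "effectiveness_safety"): (-0.06, -0.02, 0.08),
}


def study_truth_default(schema: AttributeSchema) -> TruthSpec:
    """The documented default truth for study-scale simulations."""
    missing = set(schema.ids) - set(STUDY_TRUTH_MAIN)
    if missing:
        raise SimulationError(
            f"default truth is defined for the study schema; missing {sorted(missing)}"
        )
    return TruthSpec.from_level_utilities(
        schema, STUDY_TRUTH_MAIN, STUDY_TRUTH_INTERACTIONS, completion=COMPLETION_RATE
    )


def default_truth(schema: AttributeSchema, completion: float = COMPLETION_RATE) -> TruthSpec:
    """Study truth when the schema matches the study configuration, otherwise a
    generic ordered, loss-averse truth decaying across importance ranks."""
    if set(schema.ids) <= set(STUDY_TRUTH_MAIN):
        truth = study_truth_default(schema)
        if completion != truth.completion:
            truth = TruthSpec(
                base=truth.base, interactions=truth.interactions, completion=completion
            )
        return truth
    triples = {}
    for a in schema:
        g = 0.5 * 0.9 ** (a.rank - 1)
        triples[a.id] = (g, 0.0, -1.2 * g)
    return TruthSpec.from_level_utilities(schema, triples, completion=completion)


# ---------------------------------------------------------------------------
# Choice dataset
# ---------------------------------------------------------------------------

@dataclass
class ChoiceDataset:
    """Long-format observed choices plus the respondent covariate table.

    ``choices`` has two rows per answered choice set (one per alternative)
    with exactly one ``chosen == 1``; unanswered sets are absent entirely.
    """

    schema: AttributeSchema
    respondents: pd.DataFrame
    choices: pd.DataFrame

    @property
    def n_answered(self) -> int:
        return len(self.choices) // 2

    def save(self, directory) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rpath = directory / "respondents.csv"
        cpath = directory / "choices.csv"
        self.respondents.to_csv(rpath, index=False)
        out = self.choices.copy()
        for a in self.schema.ids:
            out[a] = out[a].map(TO_SHORT)
        out.to_csv(cpath, index=False)
        return rpath, cpath

    @classmethod
    def load(cls, schema: AttributeSchema, respondents_path, choices_path) -> "ChoiceDataset":
        respondents = pd.read_csv(respondents_path)
        choices = pd.read_csv(choices_path)
        for a in schema.ids:
            choices[a] = choices[a].map(lambda s: SHORT_LABELS[str(s).strip()])
        return cls(schema=schema, respondents=respondents, choices=choices)


def _subgroup_offsets_matrix(
    schema: AttributeSchema,
    truth: TruthSpec,
    respondents: pd.DataFrame,
) -> np.ndarray:
    """Per-respondent coefficient vectors: base + covariate * interaction offsets."""
    n = len(respondents)
    beta = np.tile(truth.base, (n, 1))
    for (cov, aid), off in truth.interactions.items():
        if cov.startswith("area_"):
            vals = (respondents["area"] == cov.removeprefix("area_")).to_numpy(float)
        elif cov in respondents.columns:
            vals = respondents[cov].to_numpy(float)
        else:
            raise SimulationError(f"truth interaction covariate {cov!r} not found")
        j0, j1 = schema.columns_of(aid)
        beta[:, j0] += vals * off[0]
        beta[:, j1] += vals * off[1]
    return beta


def simulate_choices(
    design: ChoiceDesign,
    population: Sequence[RespondentProfile] | pd.DataFrame,
    truth: TruthSpec,
    seed: int = 0,
) -> ChoiceDataset:
    """Simulate the survey: each respondent sees their block's choice sets,
    answers each independently with probability ``truth.completion``, and
    chooses alternative 1 with MNL probability ``expit(u1 - u2)``."""
    schema = design.schema
    if isinstance(population, pd.DataFrame):
        resp = population.copy()
    else:
        resp = respondents_frame(population)
    if resp["block"].max() >= design.n_blocks:
        raise DesignError(
            f"respondent block {int(resp['block'].max())} outside design with "
            f"{design.n_blocks} blocks"
        )
    rng = np.random.default_rng(seed)
    D = _difference_matrix(design)  # (S, p)
    beta = _subgroup_offsets_matrix(schema, truth, resp)  # (n, p)
    set_ids = [cs.id for cs in design.choice_sets]
    block_of_set = np.array([design.blocks[sid] for sid in set_ids])

    rows = []
    for i, (_, r) in enumerate(resp.iterrows()):
        idx = np.flatnonzero(block_of_set == r["block"])
        answered = rng.random(len(idx)) < truth.completion
        idx = idx[answered]
        if len(idx) == 0:
            continue
        u_diff = D[idx] @ beta[i]
        pick1 = rng.random(len(idx)) < expit(u_diff)
        for j, s in enumerate(idx):
            cs = design.choice_sets[s]
            for alt, prof in enumerate(cs.profiles, start=1):
                row = {
                    "respondent_id": r["respondent_id"],
                    "set_id": cs.id,
                    "alt": alt,
                    "chosen": int((alt == 1) == bool(pick1[j])),
                }
                for a in schema.ids:
                    row[a] = prof[a]
                rows.append(row)
    cols = ["respondent_id", "set_id", "alt"] + list(schema.ids) + ["chosen"]
    choices = pd.DataFrame(rows, columns=cols)
    return ChoiceDataset(schema=schema, respondents=resp, choices=choices)
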