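"""Attribute schema, effects coding, profiles and choice sets.

A discrete choice experiment (DCE) in this package presents respondents with
*paired* partial profiles: two hypothetical outcome configurations over a set
of performance attributes, each attribute taking one of three ordered outcome
levels — ``positive``, ``no_change`` or ``negative``.  This module defines the
shared vocabulary used by every other module: the attribute schema, the
effects coding that maps a profile onto model-matrix columns, and the choice
set container with its constant-attribute bookkeeping.

Effects coding uses two columns per attribute::

    positive  -> ( 1,  0)
    no_change -> ( 0,  1)
    negative  -> (-1, -1)

so that the three level utilities of every attribute sum to zero and each
level's marginal utility is a first-class, reportable quantity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

#: Canonical outcome levels, in display order.
LEVELS: tuple[str, str, str] = ("positive", "no_change", "negative")

#: Short labels used in design / choice CSV files.
SHORT_LABELS: dict[str, str] = {"pos": "positive", "nc": "no_change", "neg": "negative"}
TO_SHORT: dict[str, str] = {v: k for k, v in SHORT_LABELS.items()}

#: Effects-coding rows, indexed by level position in :data:`LEVELS`.
_LEVEL_CODES = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])


class SchemaError(ValueError):
    """Raised when an attribute schema or profile fails validation."""


def normalize_level(label: str) -> str:
    """Map a (possibly short or untidy) level label to its canonical form."""
    s = str(label).strip().lower()
    if s in SHORT_LABELS:
        return SHORT_LABELS[s]
    if s in LEVELS:
        return s
    raise SchemaError(f"unknown outcome level label: {label!r}")


@dataclass(frozen=True)
class Attribute:
    """One performance domain with its three ordered outcome levels."""

    id: str
    name: str
    rank: int
    levels: tuple[str, str, str] = LEVELS

    def __post_init__(self) -> None:
        if len(set(self.levels)) != 3:
            raise SchemaError(f"attribute {self.id!r}: levels must be 3 distinct labels")
        if self.rank < 1:
            raise SchemaError(f"attribute {self.id!r}: rank must be a positive integer")


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes plus the standardization reference pair.

    The reference pair (attribute, level) names the coefficient used as the
    "golden standard" when utilities are standardized downstream; for the
    study configuration it is a deterioration in clinical effectiveness and
    patient safety.
    """

    attributes: tuple[Attribute, ...]
    reference_attribute_id: str
    reference_level: str

    def __post_init__(self) -> None:
        ids = [a.id for a in self.attributes]
        if len(self.attributes) < 2:
            raise SchemaError("schema needs at least 2 attributes")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate attribute ids: {dupes}")
        ranks = [a.rank for a in self.attributes]
        if len(set(ranks)) != len(ranks):
            raise SchemaError("attribute ranks must be unique within the schema")
        if self.reference_attribute_id not in ids:
            raise SchemaError(
                f"reference attribute {self.reference_attribute_id!r} not in schema"
            )
        ref = self[self.reference_attribute_id]
        if self.reference_level not in ref.levels:
            raise SchemaError(
                f"reference level {self.reference_level!r} not a level of "
                f"{self.reference_attribute_id!r}"
            )

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.attributes)

    def __iter__(self):
        return iter(self.attributes)

    def __getitem__(self, attribute_id: str) -> Attribute:
        for a in self.attributes:
            if a.id == attribute_id:
                return a
        raise KeyError(attribute_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.attributes)

    def index(self, attribute_id: str) -> int:
        try:
            return self.ids.index(attribute_id)
        except ValueError:
            raise KeyError(attribute_id) from None

    # -- coding map --------------------------------------------------------
    @property
    def n_columns(self) -> int:
        """Dimension of the effects-coded model matrix (2 per attribute)."""
        return 2 * len(self)

    @property
    def column_labels(self) -> tuple[str, ...]:
        """Stable coefficient-column labels: ``<attr>:pos`` and ``<attr>:nc``."""
        out: list[str] = []
        for a in self.attributes:
            out.extend((f"{a.id}:pos", f"{a.id}:nc"))
        return tuple(out)

    def columns_of(self, attribute_id: str) -> tuple[int, int]:
        i = self.index(attribute_id)
        return 2 * i, 2 * i + 1


# ---------------------------------------------------------------------------
# Profiles and choice sets
# ---------------------------------------------------------------------------

Profile = Mapping[str, str]  # attribute id -> outcome-level label


def validate_profile(schema: AttributeSchema, profile: Profile) -> dict[str, str]:
    """Return a normalized copy of *profile*, complete w.r.t. *schema*."""
    out: dict[str, str] = {}
    for a in schema:
        if a.id not in profile:
            raise SchemaError(f"profile missing attribute {a.id!r}")
        out[a.id] = normalize_level(profile[a.id])
    extra = set(profile) - set(schema.ids)
    if extra:
        raise SchemaError(f"profile has unknown attributes: {sorted(extra)}")
    return out


@dataclass(frozen=True)
class ChoiceSet:
    """A forced pair of profiles with constant-attribute bookkeeping.

    ``balanced_constant_ids`` are the planned constants ('*' attributes fixed
    by the attribute-balance plan); ``incidental_constant_ids`` ('§') are
    attributes that were free to vary but ended up equal in both profiles
    during design optimization.
    """

    id: str
    profiles: tuple[dict[str, str], dict[str, str]]
    balanced_constant_ids: frozenset[str] = frozenset()
    incidental_constant_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.profiles) != 2:
            raise SchemaError(f"choice set {self.id!r}: exactly 2 profiles required")
        overlap = self.balanced_constant_ids & self.incidental_constant_ids
        if overlap:
            raise SchemaError(
                f"choice set {self.id!r}: attributes {sorted(overlap)} marked both "
                "'*' and '§'"
            )
        a, b = self.profiles
        for aid in self.balanced_constant_ids | self.incidental_constant_ids:
            if a.get(aid) != b.get(aid):
                raise SchemaError(
                    f"choice set {self.id!r}: constant attribute {aid!r} differs "
                    "between profiles"
                )

    @property
    def constant_ids(self) -> frozenset[str]:
        return self.balanced_constant_ids | self.incidental_constant_ids

    def varying_ids(self, schema: AttributeSchema) -> tuple[str, ...]:
        """Attributes whose levels actually differ between the two profiles."""
        a, b = self.profiles
        return tuple(aid for aid in schema.ids if a[aid] != b[aid])

    def n_differing(self, schema: AttributeSchema) -> int:
        return len(self.varying_ids(schema))

    def swapped(self) -> "ChoiceSet":
        """The same choice set with alternative order reversed."""
        return ChoiceSet(
            id=self.id,
            profiles=(self.profiles[1], self.profiles[0]),
            balanced_constant_ids=self.balanced_constant_ids,
            incidental_constant_ids=self.incidental_constant_ids,
        )


# ---------------------------------------------------------------------------
# Coding operations
# ---------------------------------------------------------------------------

def encode_level(level: str) -> np.ndarray:
    """Two-column effects code of a single outcome level."""
    return _LEVEL_CODES[LEVELS.index(normalize_level(level))].copy()


def effects_code(schema: AttributeSchema, profile: Profile) -> np.ndarray:
    """Effects-coded row vector (length ``2 * K``) of a complete profile."""
    prof = validate_profile(schema, profile)
    out = np.empty(schema.n_columns)
    for i, a in enumerate(schema.attributes):
        out[2 * i : 2 * i + 2] = _LEVEL_CODES[LEVELS.index(prof[a.id])]
    return out


def level_utilities(
    schema: AttributeSchema, beta: np.ndarray, attribute_id: str
) -> tuple[float, float, float]:
    """Marginal utilities ``(positive, no_change, negative)`` of one attribute.

    Under effects coding the two coefficient columns ``(a, b)`` of an
    attribute imply level utilities ``(a, b, -a-b)``, which sum to zero.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (schema.n_columns,):
        raise SchemaError(
            f"beta has shape {beta.shape}, expected ({schema.n_columns},)"
        )
    j0, j1 = schema.columns_of(attribute_id)
    a, b = float(beta[j0]), float(beta[j1])
    return (a, b, -a - b)


def level_utility_triples(schema: AttributeSchema, beta: np.ndarray) -> dict[str, tuple[float, float, float]]:
    """``level_utilities`` for every attribute, keyed by attribute id."""
    return {a.id: level_utilities(schema, beta, a.id) for a in schema}


def triple_to_coded(triple: Sequence[float]) -> np.ndarray:
    """Least-squares map of a ``(positive, no_change, negative)`` utility triple
    onto the two effects-coded coefficients.

    Effects coding spans only zero-sum triples; a triple with nonzero sum is
    first centered (the constant shift cancels in any choice between two
    profiles, so nothing interpretable is lost).
    """
    t = np.asarray(triple, dtype=float)
    if t.shape != (3,):
        raise SchemaError("utility triple must have exactly 3 entries")
    tc = t - t.mean()
    return tc[:2].copy()


def triples_to_beta(schema: AttributeSchema, triples: Mapping[str, Sequence[float]]) -> np.ndarray:
    """Assemble a full coefficient vector from per-attribute utility triples."""
    beta = np.zeros(schema.n_columns)
    for aid, triple in triples.items():
        j0, j1 = schema.columns_of(aid)
        beta[[j0, j1]] = triple_to_coded(triple)
    return beta


# ---------------------------------------------------------------------------
# Schema construction
# ---------------------------------------------------------------------------

def build_schema(config: Mapping) -> AttributeSchema:
    """Build and validate an :class:`AttributeSchema` from a config mapping.

    The config document (YAML/JSON-compatible) has the form::

        attributes:
          - {id: effectiveness_safety, name: "...", rank: 1}
          - ...
        reference: {attribute: effectiveness_safety, level: negative}

    Each attribute may list explicit ``levels``; they default to the canonical
    positive / no_change / negative triple.
    """
    try:
        raw_attrs = config["attributes"]
    except (KeyError, TypeError):
        raise SchemaError("config must contain an 'attributes' list") from None
    if not isinstance(raw_attrs, Iterable):
        raise SchemaError("'attributes' must be a list")
    attrs = []
    for entry in raw_attrs:
        if "id" not in entry:
            raise SchemaError(f"attribute entry missing 'id': {entry!r}")
        levels = tuple(normalize_level(l) for l in entry.get("levels", LEVELS))
        if len(levels) != 3:
            raise SchemaError(
                f"attribute {entry['id']!r} lists {len(levels)} levels; exactly 3 required"
            )
        attrs.append(
            Attribute(
                id=str(entry["id"]),
                name=str(entry.get("name", entry["id"])),
                rank=int(entry["rank"]),
                levels=levels,
            )
        )
    ref = config.get("reference")
    if not ref or "attribute" not in ref or "level" not in ref:
        raise SchemaError("config must name a reference pair: {attribute, level}")
    return AttributeSchema(
        attributes=tuple(attrs),
        reference_attribute_id=str(ref["attribute"]),
        reference_level=normalize_level(ref["level"]),
    )


def load_schema(path) -> AttributeSchema:
    """Load a schema from a YAML (or JSON) document on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return build_schema(yaml.safe_load(fh))


#: The 11 healthcare-system performance domains of the study, in their
#: published order; the a-priori importance rank follows that order.
STUDY_ATTRIBUTES: tuple[tuple[str, str], ...] = (
    ("effectiveness_safety", "Clinical effectiveness and patient safety"),
    ("best_practice", "Best practice service use"),
    ("care_equity", "Care equity"),
    ("coordination", "Care coordination, teamwork and continuity"),
    ("patient_centeredness", "Patient centeredness"),
    ("timeliness", "Timeliness"),
    ("short_term_cost", "Short term cost containment and budget safety"),
    ("long_term_cost", "Long term cost containment and budget safety"),
    ("provider_wellness", "Provider wellness"),
    ("innovation", "Innovation"),
    ("gaming", "Gaming the system"),
)


def study_schema() -> AttributeSchema:
    """The default study configuration: 11 domains, reference = a deterioration
    in clinical effectiveness and patient safety."""
    return build_schema(
        {
            "attributes": [
                {"id": aid, "name": name, "rank": i + 1}
                for i, (aid, name) in enumerate(STUDY_ATTRIBUTES)
            ],
            "reference": {"attribute": "effectiveness_safety", "level": "negative"},
        }
    )
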