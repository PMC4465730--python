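"""End-to-end pipeline: design -> simulate -> fit -> report -> scenario.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence``; the per-stage seeds are recorded in the run
manifest so every intermediate artifact is reproducible in isolation.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ChoiceDesign, design_report, optimize_design
from .model import ConditionalLogit, ModelSpec
from .priors import build_ordered_prior, sample_prior
from .reporting import importance_table, standardize
from .scenarios import (
    Scenario,
    alignment_change,
    reform_scenario_default,
    utility_report,
)
from .schema import SHORT_LABELS, AttributeSchema, load_schema, study_schema
from .simulate import (
    COMPLETION_RATE,
    ChoiceDataset,
    default_truth,
    generate_population,
    respondents_frame,
    simulate_choices,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    schema_path: str | None = None  # None -> built-in study schema
    prior: dict = field(default_factory=dict)  # build_ordered_prior kwargs
    design: dict = field(
        default_factory=lambda: {
            "n_sets": 54,
            "n_varying_max": 5,
            "n_blocks": 3,
            "restarts": 4,
        }
    )
    simulation: dict = field(
        default_factory=lambda: {"n_respondents": 547, "completion": COMPLETION_RATE}
    )
    model: dict = field(default_factory=dict)  # {interactions: [[cov, attr]...], adjustments: [...]}
    scenario_path: str | None = None  # None -> default reform scenario

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(out_dir=doc["out_dir"])
        for key in ("seed", "schema_path", "prior", "design", "simulation", "model", "scenario_path"):
            if key in doc:
                setattr(cfg, key, doc[key])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("schema_path", "scenario_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{key} does not exist: {p}")


def _stage_seeds(root_seed: int, n: int = 4) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(root_seed).generate_state(n) % (2**31)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Stage failures halt the run with the stage name attached.  Identical
    configs produce byte-identical numeric outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "root_seed": config.seed,
        "stage_seeds": {
            "prior_draws": seeds[0],
            "design": seeds[1],
            "population": seeds[2],
            "choices": seeds[3],
        },
        "files": [],
        "timings_s": {},
    }

    def _record(path: Path) -> None:
        manifest["files"].append(str(path.name))

    stage = "schema"
    try:
        t0 = time.perf_counter()
        schema = load_schema(config.schema_path) if config.schema_path else study_schema()
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "prior"
        t0 = time.perf_counter()
        prior = build_ordered_prior(schema, seed=seeds[0], **config.prior)
        prior_path = out / "prior.json"
        prior.save(prior_path)
        _record(prior_path)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "design"
        t0 = time.perf_counter()
        design = optimize_design(schema, prior, seed=seeds[1], **config.design)
        design_path = out / "design.csv"
        design.to_csv(design_path)
        _record(design_path)
        report_path = out / "design_report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(design_report(design), fh, indent=1)
        _record(report_path)
        manifest["criterion_value"] = design.criterion_value
        manifest["design_converged"] = design.converged
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "simulate"
        t0 = time.perf_counter()
        sim = dict(config.simulation)
        n = int(sim.pop("n_respondents", 547))
        completion = float(sim.pop("completion", COMPLETION_RATE))
        population = generate_population(
            n, margins=sim.pop("margins", None), seed=seeds[2], n_blocks=design.n_blocks
        )
        truth = default_truth(schema, completion=completion)
        dataset = simulate_choices(design, population, truth, seed=seeds[3])
        rpath, cpath = dataset.save(out)
        _record(rpath)
        _record(cpath)
        manifest["n_answered_sets"] = dataset.n_answered
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "fit"
        t0 = time.perf_counter()
        spec = ModelSpec(
            interactions=tuple(
                (c, a) for c, a in config.model.get(
                    "interactions", [list(k) for k in truth.interactions]
                )
            ),
            adjustments=tuple(config.model.get("adjustments", ())),
        )
        results = ConditionalLogit(dataset, spec).fit()
        fit_path = out / "fit.json"
        results.save(fit_path)
        _record(fit_path)
        manifest["log_likelihood"] = results.llf
        manifest["fit_converged"] = results.converged
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "report"
        t0 = time.perf_counter()
        # attribute importance is a pooled statement: LR tests from the
        # main-effects model, not conditional on subgroup interactions
        pooled = (
            results
            if not spec.interactions and not spec.adjustments
            else ConditionalLogit(dataset, ModelSpec()).fit()
        )
        imp = importance_table(pooled.lr_table())
        imp_path = out / "importance.csv"
        imp.to_csv(imp_path, index=False)
        _record(imp_path)
        std = standardize(pooled, schema)
        std_path = out / "standardized_utilities.csv"
        std.to_csv(std_path)
        _record(std_path)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)

        stage = "scenario"
        t0 = time.perf_counter()
        scenario = (
            Scenario.from_yaml(config.scenario_path, schema)
            if config.scenario_path
            else reform_scenario_default(schema)
        )
        table = utility_report(results, schema, scenario)
        table_path = out / "scenario_utilities.csv"
        table.to_csv(table_path, index=False)
        _record(table_path)
        align = alignment_change(table, "physician", "policy_maker")
        align_path = out / "alignment.csv"
        align.to_csv(align_path, index=False)
        _record(align_path)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------

def validate_dataset(
    choices: pd.DataFrame,
    respondents: pd.DataFrame,
    design: ChoiceDesign,
) -> dict:
    """Check choice-dataset invariants; returns ``{violations, warnings, n_sets}``.

    Checks: legal level labels (untidy labels are normalized with a warning),
    both alternatives present per answered set, exactly one chosen, set ids
    present in the design, and respondent blocks consistent with the block of
    every set they answered.
    """
    schema = design.schema
    violations: list[str] = []
    warnings_: list[str] = []
    ch = choices.copy()

    legal = set(SHORT_LABELS) | set(SHORT_LABELS.values())
    for aid in schema.ids:
        raw = ch[aid].astype(str)
        tidy = raw.str.strip().str.lower()
        changed = raw != tidy
        if changed.any():
            rows = list(ch.index[changed][:5])
            warnings_.append(
                f"column {aid!r}: {int(changed.sum())} untidy level labels normalized "
                f"(rows {rows})"
            )
        bad = ~tidy.isin(legal)
        if bad.any():
            violations.append(
                f"column {aid!r}: illegal level labels at rows {list(ch.index[bad][:5])}"
            )
        ch[aid] = tidy.map(lambda s: SHORT_LABELS.get(s, s))

    design_ids = {cs.id for cs in design.choice_sets}
    unknown = set(ch["set_id"].astype(str)) - design_ids
    if unknown:
        violations.append(f"unknown set ids: {sorted(unknown)[:5]}")

    block_of = {cs.id: design.blocks[cs.id] for cs in design.choice_sets}
    resp_block = dict(zip(respondents["respondent_id"], respondents["block"]))
    n_sets = 0
    for (rid, sid), grp in ch.groupby(["respondent_id", "set_id"], sort=False):
        n_sets += 1
        alts = sorted(grp["alt"].tolist())
        if alts != [1, 2]:
            violations.append(f"({rid}, {sid}): alternatives {alts}, expected [1, 2]")
        n_chosen = int(grp["chosen"].sum())
        if n_chosen != 1:
            violations.append(f"({rid}, {sid}): {n_chosen} alternatives chosen")
        if str(sid) in block_of and rid in resp_block:
            if block_of[str(sid)] != resp_block[rid]:
                violations.append(
                    f"({rid}, {sid}): set belongs to block {block_of[str(sid)]}, "
                    f"respondent assigned block {resp_block[rid]}"
                )
    return {"violations": violations, "warnings": warnings_, "n_sets": n_sets}
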