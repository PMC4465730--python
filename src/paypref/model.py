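"""Maximum-likelihood estimation of the multinomial logit choice model.

With forced pairs and unlabeled alternatives, the MNL model reduces exactly
to a binary logit on the difference of the two alternatives' effects-coded
model-matrix rows: respondent-level main effects cancel, so respondent
covariates enter only through interactions with attribute codes.  The model
object (:class:`ConditionalLogit`) is built from a :class:`ChoiceDataset` and
a :class:`ModelSpec`; :meth:`ConditionalLogit.fit` returns a
:class:`ConditionalLogitResults` carrying estimates, their covariance
(inverse observed information), the log-likelihood, likelihood-ratio
attribute tests and a summary table.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .schema import AttributeSchema, LEVELS, _LEVEL_CODES
from .simulate import ChoiceDataset

_GRAD_TOL = 1e-6
_MAX_ITER = 100
_SEPARATION_BOUND = 50.0


class EstimationError(ValueError):
    pass


class IdentifiabilityError(EstimationError):
    """Raised when a coefficient column never varies within any choice set."""

    def __init__(self, columns: Sequence[str]):
        self.columns = tuple(columns)
        super().__init__(
            "non-identifiable coefficient columns (no within-set variation): "
            + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class ModelSpec:
    """Model terms: all main effects, plus subgroup interactions and
    covariate adjustments.

    ``interactions`` lists ``(covariate, attribute_id)`` pairs, each adding the
    covariate times the attribute's two coded columns.  ``adjustments`` lists
    respondent covariates interacted with *all* attribute codes (continuous
    covariates are standardized first); a conditional logit on forced pairs
    has no room for respondent-level intercepts, so adjustment can only enter
    through such interactions.
    """

    interactions: tuple = ()
    adjustments: tuple = ()

    def __post_init__(self) -> None:
        inter = tuple(dict.fromkeys((str(c), str(a)) for c, a in self.interactions))
        adj = tuple(dict.fromkeys(str(c) for c in self.adjustments))
        object.__setattr__(self, "interactions", inter)
        object.__setattr__(self, "adjustments", adj)

    def column_labels(self, schema: AttributeSchema) -> tuple[str, ...]:
        labels = list(schema.column_labels)
        for cov, aid in self.interactions:
            labels.extend((f"{cov}*{aid}:pos", f"{cov}*{aid}:nc"))
        for cov in self.adjustments:
            labels.extend(f"{cov}*{c}" for c in schema.column_labels)
        return tuple(labels)


def resolve_covariate(respondents: pd.DataFrame, name: str, standardize: bool = False) -> pd.Series:
    """Resolve a covariate name against the respondent table.

    ``area_<x>`` names resolve to 0/1 indicators of the categorical ``area``
    column; anything else must be an existing numeric column.  With
    ``standardize=True``, covariates with more than two distinct values are
    scaled to mean 0, SD 1.
    """
    if name.startswith("area_") and name not in respondents.columns:
        key = name.removeprefix("area_")
        s = (respondents["area"] == key).astype(float)
    elif name in respondents.columns:
        s = respondents[name].astype(float)
    else:
        raise EstimationError(f"covariate {name!r} not found in respondent table")
    if standardize and s.nunique() > 2:
        sd = s.std(ddof=0)
        if sd > 0:
            s = (s - s.mean()) / sd
    return s


def _paired_differences(dataset: ChoiceDataset) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per answered set: coded profile difference d, outcome y (alt1 chosen),
    and the respondent row aligned to each set."""
    schema = dataset.schema
    ch = dataset.choices.sort_values(["respondent_id", "set_id", "alt"], kind="stable")
    if len(ch) % 2:
        raise EstimationError("choices table must hold two rows per answered set")
    a1 = ch.iloc[0::2]
    a2 = ch.iloc[1::2]
    if not (
        (a1["respondent_id"].to_numpy() == a2["respondent_id"].to_numpy()).all()
        and (a1["set_id"].to_numpy() == a2["set_id"].to_numpy()).all()
    ):
        raise EstimationError("choices table rows do not pair up by (respondent, set)")
    chosen = a1["chosen"].to_numpy() + a2["chosen"].to_numpy()
    if not np.all(chosen == 1):
        raise EstimationError("each answered set must have exactly one chosen alternative")
    level_idx = {lvl: i for i, lvl in enumerate(LEVELS)}

    def _code(frame: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(frame), schema.n_columns))
        for i, aid in enumerate(schema.ids):
            idx = frame[aid].map(level_idx).to_numpy()
            out[:, 2 * i : 2 * i + 2] = _LEVEL_CODES[idx]
        return out

    d = _code(a1) - _code(a2)
    y = a1["chosen"].to_numpy(dtype=float)
    resp = dataset.respondents.set_index("respondent_id")
    aligned = resp.loc[a1["respondent_id"].to_numpy()].reset_index()
    return d, y, aligned


def build_design_matrix(
    dataset: ChoiceDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Differenced model matrix Z, outcome y, and column labels."""
    schema = dataset.schema
    d, y, aligned = _paired_differences(dataset)
    rid = aligned["respondent_id"].to_numpy()

    def _per_set(cov: str, standardize: bool) -> np.ndarray:
        s = resolve_covariate(dataset.respondents, cov, standardize=standardize)
        s = pd.Series(s.to_numpy(), index=dataset.respondents["respondent_id"].to_numpy())
        return s.loc[rid].to_numpy()

    blocks = [d]
    for cov, aid in spec.interactions:
        v = _per_set(cov, standardize=False)
        j0, j1 = schema.columns_of(aid)
        blocks.append(d[:, [j0, j1]] * v[:, None])
    for cov in spec.adjustments:
        v = _per_set(cov, standardize=True)
        blocks.append(d * v[:, None])
    Z = np.hstack(blocks)
    return Z, y, spec.column_labels(schema)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _loglike(Z: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Binary-logit log-likelihood on differenced utilities, overflow-safe."""
    eta = Z @ beta
    # log P(chosen) = -log(1 + exp(-s*eta)) with s = +1 if alt1 chosen else -1
    s = 2.0 * y - 1.0
    return float(-np.logaddexp(0.0, -s * eta).sum())


class ConditionalLogit:
    """MNL choice model on forced pairs, built from a choice dataset."""

    def __init__(self, dataset: ChoiceDataset, spec: ModelSpec | None = None):
        self.dataset = dataset
        self.schema = dataset.schema
        self.spec = spec if spec is not None else ModelSpec()
        self.exog, self.endog, self.exog_names = build_design_matrix(dataset, self.spec)
        dead = [
            name
            for j, name in enumerate(self.exog_names)
            if not np.any(self.exog[:, j])
        ]
        if dead:
            raise IdentifiabilityError(dead)

    @classmethod
    def from_frames(
        cls,
        choices: pd.DataFrame,
        respondents: pd.DataFrame,
        schema: AttributeSchema,
        spec: ModelSpec | None = None,
    ) -> "ConditionalLogit":
        return cls(ChoiceDataset(schema, respondents, choices), spec)

    @property
    def n_choice_sets(self) -> int:
        return len(self.endog)

    @property
    def k_params(self) -> int:
        return self.exog.shape[1]

    def loglike(self, beta: np.ndarray) -> float:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.k_params,):
            raise EstimationError(
                f"beta has shape {beta.shape}, expected ({self.k_params},)"
            )
        return _loglike(self.exog, self.endog, beta)

    def score(self, beta: np.ndarray) -> np.ndarray:
        p = expit(self.exog @ beta)
        return self.exog.T @ (self.endog - p)

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        """Hessian of the log-likelihood (negative definite)."""
        p = expit(self.exog @ beta)
        w = p * (1.0 - p)
        return -(self.exog.T * w) @ self.exog

    def fit(self, tol: float = _GRAD_TOL, maxiter: int = _MAX_ITER) -> "ConditionalLogitResults":
        """Newton's method with step halving from beta = 0; converged when the
        gradient max-norm drops below *tol*.  Deterministic given the data."""
        beta = np.zeros(self.k_params)
        ll = self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            g = self.score(beta)
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            H = self.hessian(beta)
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-H, g, rcond=None)[0]
            scale = 1.0
            for _half in range(30):
                cand = beta + scale * step
                ll_cand = self.loglike(cand)
                if ll_cand >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, ll = cand, ll_cand
        flagged = tuple(
            name
            for j, name in enumerate(self.exog_names)
            if abs(beta[j]) > _SEPARATION_BOUND
        )
        if flagged:
            converged = False
            warnings.warn(
                "possible separation; runaway coefficients: " + ", ".join(flagged),
                RuntimeWarning,
            )
        H = self.hessian(beta)
        info = -H
        pseudo = False
        try:
            cov = np.linalg.inv(info)
            if not np.all(np.isfinite(cov)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular observed information; using pseudo-inverse covariance",
                RuntimeWarning,
            )
            cov = np.linalg.pinv(info)
            pseudo = True
        return ConditionalLogitResults(
            model=self,
            params=beta,
            cov=cov,
            llf=ll,
            converged=converged,
            flagged_params=flagged,
            cov_is_pseudo_inverse=pseudo,
        )


class ConditionalLogitResults:
    """Fit results: estimates, uncertainty, diagnostics and LR attribute tests."""

    def __init__(
        self,
        model: ConditionalLogit | None,
        params: np.ndarray,
        cov: np.ndarray,
        llf: float,
        converged: bool,
        flagged_params: tuple = (),
        cov_is_pseudo_inverse: bool = False,
        exog_names: tuple[str, ...] | None = None,
        schema: AttributeSchema | None = None,
        n_choice_sets: int | None = None,
        lr_table_df: pd.DataFrame | None = None,
    ):
        self.model = model
        self.schema = schema if schema is not None else model.schema
        self.exog_names = exog_names if exog_names is not None else model.exog_names
        self.params = np.asarray(params, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.flagged_params = flagged_params
        self.cov_is_pseudo_inverse = cov_is_pseudo_inverse
        self._n_choice_sets = (
            n_choice_sets if n_choice_sets is not None else model.n_choice_sets
        )
        self._lr_table = lr_table_df

    # -- basic accessors ---------------------------------------------------
    @property
    def n_choice_sets(self) -> int:
        return self._n_choice_sets

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def llnull(self) -> float:
        """Log-likelihood at beta = 0: every pair a coin flip."""
        return self._n_choice_sets * float(np.log(0.5))

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.exog_names, columns=self.exog_names)

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.exog_names, name="coef")

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    # -- LR tests ----------------------------------------------------------
    def lr_test(self, attribute_id: str) -> tuple[float, int, float]:
        """LR test of an attribute's overall significance: refit without its
        two main-effect columns (interactions retained), statistic
        ``2 * (LL_full - LL_reduced)`` against chi-square(2)."""
        if self.model is None:
            raise EstimationError("lr_test requires the fitted model (not a loaded report)")
        j0, j1 = self.schema.columns_of(attribute_id)
        keep = [j for j in range(len(self.exog_names)) if j not in (j0, j1)]
        Z = self.model.exog[:, keep]
        y = self.model.endog
        ll_red = _newton_loglike(Z, y)
        stat = max(0.0, 2.0 * (self.llf - ll_red))
        df = 2
        return stat, df, float(chi2.sf(stat, df))

    def lr_table(self) -> pd.DataFrame:
        """Per-attribute LR statistics, one row per schema attribute."""
        if self._lr_table is None:
            rows = []
            for a in self.schema:
                stat, df, p = self.lr_test(a.id)
                rows.append({"attribute": a.id, "statistic": stat, "df": df, "p_value": p})
            self._lr_table = pd.DataFrame(rows)
        return self._lr_table.copy()

    # -- utilities ---------------------------------------------------------
    def level_utilities(
        self, attribute_id: str, context: Mapping[str, float] | None = None
    ) -> tuple[float, float, float]:
        """Raw (positive, no_change, negative) utilities of an attribute, for
        the pooled main-effects context or a subgroup context of covariate
        values applied to the spec's interaction terms."""
        j0, j1 = self.schema.columns_of(attribute_id)
        a, b = self.params[j0], self.params[j1]
        if context:
            for name, value in context.items():
                la, lb = f"{name}*{attribute_id}:pos", f"{name}*{attribute_id}:nc"
                if la in self.exog_names:
                    a += value * self.params[self.exog_names.index(la)]
                    b += value * self.params[self.exog_names.index(lb)]
        return (float(a), float(b), float(-a - b))

    def standardized_utilities(self, context: Mapping[str, float] | None = None):
        from .reporting import standardize

        return standardize(self, self.schema, context)

    def importance_table(self) -> pd.DataFrame:
        from .reporting import importance_table

        return importance_table(self.lr_table())

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Conditional logit (MNL on forced pairs)",
            "=" * 72,
            f"N choice sets: {self.n_choice_sets:>8d}    Log-likelihood: {self.llf:.3f}",
            f"LL (null):     {self.llnull:>8.3f}    Converged: {self.converged}",
            "-" * 72,
            f"{'coef':>32s} {'estimate':>10s} {'std err':>10s} {'z':>8s}",
        ]
        se = self.bse
        for j, name in enumerate(self.exog_names):
            z = self.params[j] / se[j] if se[j] > 0 else np.nan
            lines.append(f"{name:>32s} {self.params[j]:>10.4f} {se[j]:>10.4f} {z:>8.2f}")
        lines.append("=" * 72)
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "exog_names": list(self.exog_names),
                "params": self.params.tolist(),
                "cov": self.cov.tolist(),
                "llf": self.llf,
                "n_choice_sets": self.n_choice_sets,
                "converged": self.converged,
                "flagged_params": list(self.flagged_params),
                "cov_is_pseudo_inverse": self.cov_is_pseudo_inverse,
                "lr_table": self.lr_table().to_dict(orient="records"),
            },
            indent=1,
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, doc: str, schema: AttributeSchema) -> "ConditionalLogitResults":
        d = json.loads(doc)
        return cls(
            model=None,
            params=np.asarray(d["params"]),
            cov=np.asarray(d["cov"]),
            llf=d["llf"],
            converged=d["converged"],
            flagged_params=tuple(d.get("flagged_params", ())),
            cov_is_pseudo_inverse=d.get("cov_is_pseudo_inverse", False),
            exog_names=tuple(d["exog_names"]),
            schema=schema,
            n_choice_sets=d["n_choice_sets"],
            lr_table_df=pd.DataFrame(d["lr_table"]),
        )

    @classmethod
    def load(cls, path, schema: AttributeSchema) -> "ConditionalLogitResults":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read(), schema)


def _newton_loglike(Z: np.ndarray, y: np.ndarray) -> float:
    """Maximized log-likelihood of a binary logit on (Z, y); helper for LR tests."""
    beta = np.zeros(Z.shape[1])
    ll = _loglike(Z, y, beta)
    for _ in range(_MAX_ITER):
        p = expit(Z @ beta)
        g = Z.T @ (y - p)
        if np.max(np.abs(g)) < _GRAD_TOL:
            return ll
        w = p * (1.0 - p)
        H = (Z.T * w) @ Z
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_cand = _loglike(Z, y, cand)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll = cand, ll_cand
    raise EstimationError("reduced model did not converge")


# ---------------------------------------------------------------------------
# Spec-surface wrappers
# ---------------------------------------------------------------------------

def log_likelihood(dataset: ChoiceDataset, spec: ModelSpec, beta: np.ndarray) -> float:
    """MNL log-likelihood of *beta* on the dataset under the model spec."""
    return ConditionalLogit(dataset, spec).loglike(beta)


def fit(dataset: ChoiceDataset, spec: ModelSpec | None = None, **options) -> ConditionalLogitResults:
    """Fit the conditional logit; see :meth:`ConditionalLogit.fit`."""
    return ConditionalLogit(dataset, spec).fit(**options)


def lr_test_attribute(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    results: ConditionalLogitResults,
    attribute_id: str,
) -> tuple[float, int, float]:
    if results.model is None:
        return ConditionalLogit(dataset, spec).fit().lr_test(attribute_id)
    return results.lr_test(attribute_id)
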