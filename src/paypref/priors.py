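"""Multivariate normal priors over choice-model coefficients.

The design stage averages the D-criterion over a prior belief about the
utility coefficients.  The prior encodes three a-priori assumptions about
respondents: (i) within every attribute, a positive outcome is preferred to
no change, which is preferred to a negative outcome; (ii) loss aversion —
avoiding a negative outcome weighs more than achieving a positive one; and
(iii) attributes ranked as more important a priori carry larger utility gaps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .schema import AttributeSchema, triples_to_beta

_PSD_TOL = 1e-10


class PriorError(ValueError):
    """Raised for dimension mismatches or invalid covariance matrices."""


@dataclass(frozen=True)
class PriorSpec:
    """A multivariate normal belief over the coded coefficient vector."""

    mean: np.ndarray
    covariance: np.ndarray
    draws: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.ndim != 1:
            raise PriorError("prior mean must be a vector")
        d = mean.shape[0]
        if cov.shape != (d, d):
            raise PriorError(
                f"covariance shape {cov.shape} does not match mean dimension {d}"
            )
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise PriorError("covariance must be symmetric")
        w = np.linalg.eigvalsh(cov)
        if w.min(initial=0.0) < -_PSD_TOL * max(1.0, w.max(initial=1.0)):
            raise PriorError("covariance is not positive semi-definite")
        if self.draws < 1:
            raise PriorError("draws must be >= 1")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "covariance": self.covariance.tolist(),
                "draws": self.draws,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "PriorSpec":
        d = json.loads(doc)
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            draws=int(d["draws"]),
            seed=int(d["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PriorSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def build_ordered_prior(
    schema: AttributeSchema,
    base_gap: float = 1.0,
    loss_aversion: float = 1.5,
    rank_decay: float = 0.9,
    sd: float = 0.5,
    draws: int = 512,
    seed: int = 0,
    covariance: np.ndarray | None = None,
) -> PriorSpec:
    """Construct the ordered, loss-averse prior.

    For an attribute with a-priori importance rank ``r`` the target prior-mean
    level utilities are ``(+g_r, 0, -loss_aversion * g_r)`` with
    ``g_r = base_gap * rank_decay**(r - 1)``.  Because effects coding spans
    only zero-sum utility triples, the target is projected onto coding space
    by least squares (centering); the projection preserves the level ordering
    and, for ``loss_aversion > 1``, the dominance of the negative level.

    Parameters
    ----------
    base_gap : positive utility gap of the top-ranked attribute.
    loss_aversion : multiplier (>= 1) on the negative level's utility magnitude.
    rank_decay : geometric decay in (0, 1] of the gap across importance ranks.
    sd : prior standard deviation; default covariance is ``sd**2 * I``.
    covariance : optional full covariance matrix overriding the diagonal default.
    """
    if base_gap <= 0:
        raise PriorError("base_gap must be > 0")
    if sd <= 0:
        raise PriorError("sd must be > 0")
    if loss_aversion < 1:
        raise PriorError("loss_aversion must be >= 1")
    if not (0 < rank_decay <= 1):
        raise PriorError("rank_decay must lie in (0, 1]")
    triples = {}
    for a in schema:
        g = base_gap * rank_decay ** (a.rank - 1)
        triples[a.id] = (g, 0.0, -loss_aversion * g)
    mean = triples_to_beta(schema, triples)
    if covariance is None:
        covariance = sd**2 * np.eye(schema.n_columns)
    return PriorSpec(mean=mean, covariance=np.asarray(covariance, dtype=float), draws=draws, seed=seed)


def sample_prior(prior: PriorSpec) -> np.ndarray:
    """Draw ``prior.draws`` coefficient vectors; reproducible given the seed.

    Degenerate (rank-deficient, including zero) covariances are supported via
    an eigen-decomposition square root, so a point-mass prior simply repeats
    the mean.
    """
    rng = np.random.default_rng(prior.seed)
    w, v = np.linalg.eigh(prior.covariance)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((prior.draws, prior.dim))
    return prior.mean + z @ root.T
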