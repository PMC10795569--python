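"""Simulation of two-group Likert response data under three generating families.

The study conditions emulated here: two groups of persons with bivariate
normal traits (substantive theta1, extreme-response theta2, independent at
generation); the reference group is N(0, I); the focal group shifts only its
ERS mean (by -1, 0 or +1).  Items are four-category, share slopes of 1.5 on
both dimensions, and have base thresholds [-1, 0, 1] (symmetric) or
[0, 1, 2] (asymmetric) shifted per item by constants equally spaced in
[-0.5, 0.5] so that item locations vary as they would in a real test.

Generating families:

* ``mnrm``   — draws from the MNRM category distribution,
* ``irtree`` — sequential Bernoulli draws through the three tree nodes,
* ``gpcm``   — the no-response-style control: the MNRM with every person's
  ERS contribution nulled (equivalently, ERS slope zero).

"True" tree item parameters are not free inputs: they are derived by fitting
the constrained tree model to very large MNRM-generated samples, so that the
two ERS-aware families describe populations that are as comparable as
possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .response_models import (
    MISSING,
    MnrmItem,
    ModelStructureError,
    ScoringMatrix,
    TreeItem,
    irtree_node_probs,
    mnrm_category_probs,
)

__all__ = [
    "GroupSpec",
    "ConditionSpec",
    "PersonSample",
    "ResponseData",
    "make_item_set",
    "sample_persons",
    "simulate",
    "derive_irtree_truth",
]

DEFAULT_SLOPE = 1.5
BASE_THRESHOLDS = ((-1.0, 0.0, 1.0), (0.0, 1.0, 2.0))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GroupSpec:
    """Latent-trait mean vector and covariance for one group."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        c = np.asarray(self.cov, dtype=float)
        if m.shape != (2,) or c.shape != (2, 2):
            raise ModelStructureError("mean must be length 2 and cov 2 x 2")
        if not np.allclose(c, c.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("covariance must be positive-definite")
        m.setflags(write=False)
        cc = np.ascontiguousarray(c)
        cc.setflags(write=False)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", cc)

    @classmethod
    def standard(cls, ers_mean: float = 0.0) -> "GroupSpec":
        """Unit-variance independent traits; optional ERS mean shift."""
        return cls(np.array([0.0, ers_mean]), np.eye(2))


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design grid."""

    generator: str
    n_items: int
    base_thresholds: tuple
    delta_ers: float
    n_per_group: int = 1000
    n_reps: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.generator not in ("mnrm", "irtree", "gpcm"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.n_items < 2:
            raise ValueError("need at least two items")
        if self.n_reps < 1:
            raise ValueError("need at least one replication")
        if self.n_per_group < 1:
            raise ValueError("need at least one person per group")
        object.__setattr__(
            self, "base_thresholds", tuple(float(t) for t in self.base_thresholds)
        )

    @property
    def group_specs(self) -> tuple:
        return (GroupSpec.standard(0.0), GroupSpec.standard(self.delta_ers))


@dataclass(frozen=True)
class PersonSample:
    """Sampled latent traits with 1-based group labels."""

    traits: np.ndarray  # (n, 2)
    group: np.ndarray  # (n,) in {1, 2}

    @property
    def n_persons(self) -> int:
        return self.traits.shape[0]


@dataclass
class ResponseData:
    """Persons x items categorical table (1..K) with group labels.

    ``MISSING`` (-1) marks absent responses; they are marginalized during
    estimation, never imputed.  ``true_traits`` is retained for
    individual-level checks on simulated data and is None for real data.
    """

    responses: np.ndarray  # (n, J) int
    group: np.ndarray  # (n,) int in {1, 2}
    true_traits: Optional[np.ndarray] = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        r = np.asarray(self.responses, dtype=int)
        g = np.asarray(self.group, dtype=int)
        if r.ndim != 2:
            raise ModelStructureError("responses must be persons x items")
        if g.shape != (r.shape[0],):
            raise ModelStructureError("one group label per person is required")
        ok = (r == MISSING) | ((r >= 1) & (r <= self.n_categories))
        if not ok.all():
            rows = np.unique(np.argwhere(~ok)[:, 0])[:5]
            raise ValueError(
                f"responses outside 1..{self.n_categories} in rows {rows.tolist()}"
            )
        self.responses = r
        self.group = g

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]


def make_item_set(
    base_thresholds: Sequence[float],
    slope: float = DEFAULT_SLOPE,
    n_items: int = 10,
) -> list:
    """Item set with per-item location shifts equally spaced in [-0.5, 0.5].

    Item ``j`` has thresholds ``base + m_j`` and slopes ``(slope, slope)``
    on the substantive and ERS dimensions.
    """
    if n_items < 2:
        raise ValueError("need at least two items for the shift grid")
    base = np.asarray(base_thresholds, dtype=float)
    shifts = np.linspace(-0.5, 0.5, n_items)
    return [
        MnrmItem.from_thresholds(base + m, (slope, slope)) for m in shifts
    ]


def sample_persons(
    group_specs: Sequence[GroupSpec], n_per_group: int, seed=None
) -> PersonSample:
    """Draw latent traits for each group from its bivariate normal."""
    if n_per_group < 1:
        raise ValueError("need at least one person per group")
    rng = as_rng(seed)
    traits, labels = [], []
    for g, spec in enumerate(group_specs, start=1):
        chol = np.linalg.cholesky(spec.cov)
        z = rng.standard_normal((n_per_group, 2))
        traits.append(spec.mean + z @ chol.T)
        labels.append(np.full(n_per_group, g))
    return PersonSample(np.vstack(traits), np.concatenate(labels))


def _sample_categorical(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of one category (1-based) per row of probabilities."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)


def simulate(
    family: str,
    items: Sequence,
    persons: PersonSample,
    seed=None,
    *,
    scoring: Optional[ScoringMatrix] = None,
    irtree_sampling: str = "nodes",
) -> ResponseData:
    """Simulate a response matrix under the given family.

    ``gpcm`` uses MNRM items but nulls every person's ERS trait (the
    control condition with no response style).  ``irtree`` draws the three
    node Bernoullis sequentially by default; ``irtree_sampling="categories"``
    draws directly from the implied four-category distribution (identical in
    distribution, used for cross-checks).
    """
    rng = as_rng(seed)
    theta = persons.traits
    n, J = theta.shape[0], len(items)
    out = np.empty((n, J), dtype=int)

    if family in ("mnrm", "gpcm"):
        for it in items:
            if not isinstance(it, MnrmItem):
                raise ModelStructureError(f"{family} generator requires MnrmItems")
        if scoring is None:
            scoring = ScoringMatrix.ers(items[0].n_categories)
        th = theta.copy()
        if family == "gpcm":
            th[:, 1] = 0.0  # every person contributes zero ERS
        for j, it in enumerate(items):
            p = mnrm_category_probs(th, it, scoring)
            out[:, j] = _sample_categorical(p, rng)
    elif family == "irtree":
        for it in items:
            if not isinstance(it, TreeItem):
                raise ModelStructureError("irtree generator requires TreeItems")
        for j, it in enumerate(items):
            pnode = irtree_node_probs(theta, it)
            if irtree_sampling == "nodes":
                y1 = rng.random(n) < pnode[:, 0]
                y2 = rng.random(n) < pnode[:, 1]
                y3 = rng.random(n) < pnode[:, 2]
                out[:, j] = np.where(y1, 3 + y3, 1 + y2)
            elif irtree_sampling == "categories":
                p1, p2, p3 = pnode[:, 0], pnode[:, 1], pnode[:, 2]
                probs = np.column_stack(
                    [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p3), p1 * p3]
                )
                out[:, j] = _sample_categorical(probs, rng)
            else:
                raise ValueError(f"unknown irtree_sampling {irtree_sampling!r}")
    else:
        raise ModelStructureError(f"unknown generating family {family!r}")

    return ResponseData(out, persons.group.copy(), true_traits=theta.copy())


def derive_irtree_truth(
    mnrm_items: Sequence[MnrmItem],
    group_specs: Optional[Sequence[GroupSpec]] = None,
    n_per_group: int = 500_000,
    seed=None,
    *,
    scoring: Optional[ScoringMatrix] = None,
    quad_points: Optional[int] = None,
    return_fit: bool = False,
):
    """Derive "true" tree item parameters from an MNRM generating setup.

    A large MNRM sample is simulated with both groups at the reference
    distribution N(0, I) (tree item parameters are population quantities and
    must not depend on any focal-group ERS shift), and the constrained tree
    model is fit by marginal ML with the latent distribution fixed at the
    exact generating N(0, I).  The fitted item parameters serve as the true
    values of the tree-generating conditions.

    The fit is warm-started from a per-item least-squares match of the tree
    category-probability curves to the generating MNRM curves on a trait
    grid; the marginal-ML fit then runs to convergence.

    Raises ``EstimationError`` with diagnostics if the fit does not converge.
    """
    from . import estimation  # deferred: estimation imports this module's types

    if group_specs is None:
        group_specs = (GroupSpec.standard(0.0), GroupSpec.standard(0.0))
    if isinstance(seed, np.random.Generator):
        rng_persons = rng_resp = seed  # one stream, consumed sequentially
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        c1, c2 = ss.spawn(2)
        rng_persons, rng_resp = np.random.default_rng(c1), np.random.default_rng(c2)
    persons = sample_persons(group_specs, n_per_group, rng_persons)
    data = simulate("mnrm", mnrm_items, persons, rng_resp, scoring=scoring)
    start = [
        estimation.tree_start_from_mnrm(it, scoring or ScoringMatrix.ers(it.n_categories))
        for it in mnrm_items
    ]
    fit = estimation.fit(
        data,
        estimation.ModelSpec(family="irtree"),
        quad_points=quad_points,
        free_focal=False,
        start_items=start,
    )
    if not fit.converged:
        raise estimation.EstimationError(
            f"tree-truth calibration did not converge: {fit.message} "
            f"(n_evals={fit.n_evals}, loglik={fit.loglik:.2f})"
        )
    return (fit.items, fit) if return_fit else fit.items
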