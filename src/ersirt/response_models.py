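"""Probability kernels for response-style-aware item response models.

Three model families for four-category Likert items are implemented:

* **MNRM** — the multidimensional nominal response model in scoring-matrix
  form.  Category probabilities are a softmax over linear predictors
  ``eta_k = sum_v a_v * s_kv * theta_v + c_k``, where the fixed integer
  scoring matrix ``s`` assigns each category a score on each latent
  dimension (column 1: ordinal substantive scores 0..K-1; column 2: an
  extreme-response flag that is 1 on the two endpoint categories).
* **IRTree** — a three-node sequential tree.  Node 1 (agree vs. disagree)
  loads only on the substantive trait; nodes 2 and 3 (extremity of the
  disagreement / agreement) load on both traits, with the substantive slope
  shared across nodes 2 and 3 and the ERS slope mirrored (node 2 slope is
  the negative of the node 3 slope).  Observed categories map onto binary
  pseudo-items with structural missingness on the branch not taken.
* **GPCM** — the generalized partial credit model: the MNRM without an ERS
  dimension, i.e. the "ignore response style" control.

All kernels accept a single trait vector or an ``(n, d)`` array of trait
vectors and return a probability vector or an ``(n, K)`` array accordingly.
Category labels are 1-based at the API surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy.special import expit, log_softmax

__all__ = [
    "MISSING",
    "ModelFamily",
    "ModelStructureError",
    "ScoringMatrix",
    "MnrmItem",
    "TreeItem",
    "PersonTraits",
    "PseudoResponse",
    "mnrm_category_probs",
    "gpcm_category_probs",
    "irtree_node_probs",
    "irtree_category_probs",
    "category_probs",
    "pseudo_items",
    "expand_pseudo_items",
    "agreement_prob",
    "conditional_extreme_agreement",
    "intercepts_from_thresholds",
    "thresholds_from_intercepts",
]

#: Sentinel for a structurally missing value (pseudo-item on the branch not
#: taken, or an absent questionnaire response).  Distinct from any category.
MISSING: int = -1

ModelFamily = Literal["mnrm", "irtree", "gpcm"]


class ModelStructureError(ValueError):
    """Items, scoring matrices, traits or families that do not fit together."""


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class ScoringMatrix:
    """K x D integer score assignment linking categories to latent dimensions.

    Row ``k`` is the score vector of category ``k+1``.  Column 0 carries the
    ordinal substantive scores ``0..K-1``; any further columns are binary
    response-style indicators (for ERS: 1 on the extreme categories).
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=int)
        if s.ndim != 2:
            raise ModelStructureError("scoring matrix must be 2-D (K x D)")
        K, D = s.shape
        if K < 2 or D < 1:
            raise ModelStructureError(f"need K >= 2 and D >= 1, got {K} x {D}")
        if not np.array_equal(s[:, 0], np.arange(K)):
            raise ModelStructureError(
                "substantive column of the scoring matrix must be 0..K-1"
            )
        if D > 1 and not np.isin(s[:, 1:], (0, 1)).all():
            raise ModelStructureError("style columns must contain only 0/1 entries")
        object.__setattr__(self, "scores", _readonly(s))

    @property
    def n_categories(self) -> int:
        return self.scores.shape[0]

    @property
    def n_dims(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def gpcm(cls, n_categories: int = 4) -> "ScoringMatrix":
        """Single-column ordinal scoring (no response style)."""
        return cls(np.arange(n_categories)[:, None])

    @classmethod
    def ers(cls, n_categories: int = 4) -> "ScoringMatrix":
        """Ordinal scoring plus an extreme-response column (1 on endpoints)."""
        ers_col = np.zeros(n_categories, dtype=int)
        ers_col[[0, -1]] = 1
        return cls(np.column_stack([np.arange(n_categories), ers_col]))


@dataclass(frozen=True)
class MnrmItem:
    """MNRM item: one positive slope per latent dimension, K category intercepts.

    The first intercept is fixed at 0 by convention; category probabilities
    are invariant to adding a constant to all intercepts, so this is a pure
    location choice that makes the threshold conversion round-trip exact.
    """

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        c = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        if a.ndim != 1 or c.ndim != 1:
            raise ModelStructureError("slopes and intercepts must be 1-D")
        if c.size < 2:
            raise ModelStructureError("need at least two categories")
        if not (np.isfinite(a).all() and np.isfinite(c).all()):
            raise ValueError("item parameters must be finite")
        object.__setattr__(self, "slopes", _readonly(a))
        object.__setattr__(self, "intercepts", _readonly(c))

    @property
    def n_dims(self) -> int:
        return self.slopes.size

    @property
    def n_categories(self) -> int:
        return self.intercepts.size

    @classmethod
    def from_thresholds(cls, thresholds, slopes) -> "MnrmItem":
        """Build an item from K-1 thresholds; intercepts follow the
        substantive slope via the cumulative conversion (first intercept 0)."""
        slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
        return cls(slopes, intercepts_from_thresholds(thresholds, slopes[0]))

    def thresholds(self) -> np.ndarray:
        return thresholds_from_intercepts(self)


@dataclass(frozen=True)
class TreeItem:
    """Constrained three-node tree item for a four-category response.

    Stored parameters (five free values plus one structural zero):

    * ``node1_slope`` — substantive slope of the agreement node (ERS slope
      on node 1 is structurally zero).
    * ``node1_intercept`` — agreement-node intercept.
    * ``agree_slope`` — substantive slope shared by the two extremity nodes.
    * ``ers_slope`` — ERS slope of node 3; node 2 carries its negative.
      Convention at generation: positive.
    * ``node2_intercept``, ``node3_intercept`` — extremity-node intercepts.
    """

    node1_slope: float
    node1_intercept: float
    agree_slope: float
    ers_slope: float
    node2_intercept: float
    node3_intercept: float

    def __post_init__(self) -> None:
        vals = [
            self.node1_slope,
            self.node1_intercept,
            self.agree_slope,
            self.ers_slope,
            self.node2_intercept,
            self.node3_intercept,
        ]
        if not np.isfinite(vals).all():
            raise ValueError("tree item parameters must be finite")

    def node_slopes(self) -> np.ndarray:
        """Reconstruct the 3 x 2 slope matrix [[a11, 0], [a21, -e], [a31, +e]]."""
        return np.array(
            [
                [self.node1_slope, 0.0],
                [self.agree_slope, -self.ers_slope],
                [self.agree_slope, self.ers_slope],
            ]
        )

    def node_intercepts(self) -> np.ndarray:
        return np.array(
            [self.node1_intercept, self.node2_intercept, self.node3_intercept]
        )


@dataclass(frozen=True)
class PersonTraits:
    """Latent trait vector: (substantive theta1, extreme-response theta2)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if t.ndim != 1 or t.size != 2:
            raise ModelStructureError("traits must be a length-2 vector")
        if not np.isfinite(t).all():
            raise ValueError("traits must be finite")
        object.__setattr__(self, "theta", _readonly(t))


@dataclass(frozen=True)
class PseudoResponse:
    """Binary node outcomes (Y1, Y2, Y3) with structural missingness."""

    node_values: tuple

    def __post_init__(self) -> None:
        v = tuple(int(x) for x in self.node_values)
        if len(v) != 3:
            raise ModelStructureError("need exactly three node values")
        if v[0] not in (0, 1):
            raise ValueError("node 1 is never missing and must be binary")
        if v[0] == 0 and not (v[1] in (0, 1) and v[2] == MISSING):
            raise ValueError("disagreement requires node 2 observed, node 3 missing")
        if v[0] == 1 and not (v[2] in (0, 1) and v[1] == MISSING):
            raise ValueError("agreement requires node 3 observed, node 2 missing")
        object.__setattr__(self, "node_values", v)


ThetaLike = Union[PersonTraits, np.ndarray, list, tuple, float]


def _as_theta(theta: ThetaLike, n_dims: int):
    """Coerce to an (n, n_dims) float array; return (array, was_single)."""
    if isinstance(theta, PersonTraits):
        theta = theta.theta
    t = np.asarray(theta, dtype=float)
    if t.ndim == 0:
        t = t.reshape(1, 1)
    single = t.ndim == 1
    t = np.atleast_2d(t)
    if t.shape[-1] != n_dims:
        raise ModelStructureError(
            f"trait vectors have {t.shape[-1]} dimensions, model expects {n_dims}"
        )
    if not np.isfinite(t).all():
        raise ValueError("trait values must be finite")
    return t, single


# ---------------------------------------------------------------------------
# MNRM / GPCM kernels
# ---------------------------------------------------------------------------

def mnrm_log_probs(theta: ThetaLike, item: MnrmItem, scoring: ScoringMatrix):
    """Log category probabilities under the MNRM (softmax in log space)."""
    if scoring.n_dims != item.n_dims:
        raise ModelStructureError(
            f"scoring matrix has {scoring.n_dims} dimensions, item has {item.n_dims}"
        )
    if scoring.n_categories != item.n_categories:
        raise ModelStructureError(
            f"scoring matrix has {scoring.n_categories} categories, "
            f"item has {item.n_categories}"
        )
    t, single = _as_theta(theta, item.n_dims)
    eta = t @ (scoring.scores * item.slopes).T + item.intercepts  # (n, K)
    logp = log_softmax(eta, axis=-1)
    return logp[0] if single else logp


def mnrm_category_probs(
    theta: ThetaLike, item: MnrmItem, scoring: ScoringMatrix
) -> np.ndarray:
    """Category probabilities of the MNRM at the given trait vector(s).

    Entry ``k`` is proportional to ``exp(sum_v a_v s_kv theta_v + c_k)``.
    """
    return np.exp(mnrm_log_probs(theta, item, scoring))


def gpcm_category_probs(theta1, item: MnrmItem) -> np.ndarray:
    """GPCM category probabilities: the MNRM restricted to its substantive
    dimension (single-column ordinal scoring), evaluated at ``theta1``.

    ``item`` may carry extra style dimensions; only the substantive slope and
    the intercepts are used, so this equals ``mnrm_category_probs`` with the
    ERS slope set to zero.
    """
    t1 = np.asarray(theta1, dtype=float)
    single = t1.ndim == 0
    uni = MnrmItem(item.slopes[:1], item.intercepts)
    p = mnrm_category_probs(
        np.atleast_1d(t1)[:, None], uni, ScoringMatrix.gpcm(item.n_categories)
    )
    return p[0] if single else p


def intercepts_from_thresholds(tau, slope: float) -> np.ndarray:
    """Convert K-1 thresholds to K category intercepts (first fixed at 0).

    A threshold is the substantive-trait point where adjacent categories are
    equally likely at zero ERS: ``tau_g = (c_g - c_{g+1}) / a``, hence
    ``c_{g+1} = c_g - a * tau_g``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if not np.isfinite(tau).all():
        raise ValueError("thresholds must be finite")
    return np.concatenate([[0.0], -slope * np.cumsum(tau)])


def thresholds_from_intercepts(item: MnrmItem) -> np.ndarray:
    """Inverse conversion: ``tau_g = (c_g - c_{g+1}) / a`` using the
    substantive slope.  Round-trips with :func:`intercepts_from_thresholds`
    to machine precision."""
    a = float(item.slopes[0])
    if a <= 0:
        raise ValueError(f"substantive slope must be positive, got {a}")
    c = item.intercepts
    return -np.diff(c) / a


# ---------------------------------------------------------------------------
# IRTree kernels
# ---------------------------------------------------------------------------

def irtree_node_probs(theta: ThetaLike, item: TreeItem) -> np.ndarray:
    """P(node outcome = 1) for the three nodes at the given trait vector(s).

    Node 1 uses only the substantive trait; nodes 2 and 3 use the shared
    substantive slope and mirrored ERS slopes (-e on node 2, +e on node 3).
    """
    t, single = _as_theta(theta, 2)
    eta = t @ item.node_slopes().T + item.node_intercepts()  # (n, 3)
    p = expit(eta)
    return p[0] if single else p


def irtree_category_probs(theta: ThetaLike, item: TreeItem) -> np.ndarray:
    """Four-category probabilities implied by the tree:
    P(1)=(1-P1)(1-P2), P(2)=(1-P1)P2, P(3)=P1(1-P3), P(4)=P1*P3."""
    t, single = _as_theta(theta, 2)
    eta = t @ item.node_slopes().T + item.node_intercepts()
    p1, p2, p3 = expit(eta).T
    out = np.column_stack(
        [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p3), p1 * p3]
    )
    return out[0] if single else out


_PSEUDO_TABLE = {
    1: (0, 0, MISSING),
    2: (0, 1, MISSING),
    3: (1, MISSING, 0),
    4: (1, MISSING, 1),
}


def pseudo_items(response: int) -> PseudoResponse:
    """Map an observed category 1..4 to its binary pseudo-item triplet."""
    r = int(response)
    if r not in _PSEUDO_TABLE:
        raise ValueError(f"response must be in 1..4, got {response}")
    return PseudoResponse(_PSEUDO_TABLE[r])


def expand_pseudo_items(responses) -> np.ndarray:
    """Vectorized pseudo-item expansion: (...,) categories -> (..., 3) codes.

    ``MISSING`` responses expand to all-missing triplets.
    """
    r = np.asarray(responses, dtype=int)
    bad = (r != MISSING) & ((r < 1) | (r > 4))
    if bad.any():
        raise ValueError(f"responses outside 1..4 at positions {np.argwhere(bad)[:5]}")
    table = np.full((6, 3), MISSING, dtype=int)
    for k, v in _PSEUDO_TABLE.items():
        table[k + 1] = v  # shift so that MISSING (-1) lands on row 0
    return table[r + 1]


# ---------------------------------------------------------------------------
# Family dispatch and derived quantities
# ---------------------------------------------------------------------------

def category_probs(
    family: ModelFamily,
    theta: ThetaLike,
    item,
    scoring: ScoringMatrix | None = None,
) -> np.ndarray:
    """Category probabilities under any of the three families.

    ``theta`` is always the full (theta1, theta2) trait vector; the GPCM
    ignores the ERS component.
    """
    if family == "mnrm":
        if not isinstance(item, MnrmItem):
            raise ModelStructureError("mnrm family requires an MnrmItem")
        if scoring is None:
            scoring = ScoringMatrix.ers(item.n_categories)
        return mnrm_category_probs(theta, item, scoring)
    if family == "irtree":
        if not isinstance(item, TreeItem):
            raise ModelStructureError("irtree family requires a TreeItem")
        return irtree_category_probs(theta, item)
    if family == "gpcm":
        if not isinstance(item, MnrmItem):
            raise ModelStructureError("gpcm family requires an MnrmItem")
        if isinstance(theta, PersonTraits):
            return gpcm_category_probs(theta.theta[0], item)
        t = np.asarray(theta, dtype=float)
        if t.ndim >= 1 and t.shape[-1] == 2:
            # full trait vectors: the GPCM ignores the ERS component
            theta1 = t[..., 0] if t.ndim > 1 else t[0]
        else:
            theta1 = t
        return gpcm_category_probs(theta1, item)
    raise ModelStructureError(f"unknown model family {family!r}")


def agreement_prob(
    family: ModelFamily,
    theta: ThetaLike,
    item,
    scoring: ScoringMatrix | None = None,
) -> np.ndarray:
    """Probability of agreeing with the item, i.e. responding 3 or 4."""
    p = category_probs(family, theta, item, scoring)
    return p[..., 2] + p[..., 3]


def conditional_extreme_agreement(
    family: ModelFamily,
    theta: ThetaLike,
    item,
    scoring: ScoringMatrix | None = None,
) -> np.ndarray:
    """P(response = 4 | response extreme), i.e. P(4) / (P(1) + P(4))."""
    p = category_probs(family, theta, item, scoring)
    return p[..., 3] / (p[..., 0] + p[..., 3])
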