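"""Graded-response-model machinery for T-score Maps.

Samejima's graded response model (GRM) describes the probability of each
ordered response category of a questionnaire item as a function of a latent
trait ``theta`` (standard-normal metric in the reference population).  Patient-
reported outcome systems such as PROMIS report scores on the T metric,
``T = 50 + 10*theta``.  This module holds the item/bank containers, the GRM
probability curves, the modal-category rule that T-score Maps are built from,
and a deterministic inverse fit that recovers item parameters from printed
probability snapshots (probability vectors at known T-scores).

Model
-----
For an item with slope ``a > 0`` and strictly increasing thresholds
``b_1 < ... < b_{K-1}`` on the theta metric, the boundary (cumulative)
response curves are logistic,

    P*_k(theta) = 1 / (1 + exp(-D * a * (theta - b_k))),   k = 1..K-1,

with ``D`` an optional scaling constant (default 1.0: pure logistic metric,
the convention of PROMIS operational calibrations).  Category probabilities
are adjacent differences, ``P_k = P*_{k-1} - P*_k`` with ``P*_0 = 1`` and
``P*_K = 0``.  Categories are coded 1..K, higher index = more of the named
trait; items presented in reversed display order record that mapping in
``direction_note`` and are never re-ordered by the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Metric",
    "ItemParameters",
    "ItemBank",
    "ProbabilitySnapshot",
    "FitError",
    "theta_from_t",
    "t_from_theta",
    "boundary_probabilities",
    "category_probabilities",
    "modal_category",
    "fit_item_from_snapshots",
    "snapshot_residuals",
]

# Probability clamps: printed snapshots are rounded (p = 0.002 etc.), so
# cumulative probabilities are clamped before taking logits.
_CLAMP_FIT = 1e-6
_CLAMP_LOGIT = 1e-12


class FitError(RuntimeError):
    """Snapshot inversion failed (infeasible ordering or underdetermined)."""


@dataclass(frozen=True)
class Metric:
    """Affine map between the latent theta metric and the reporting metric.

    The T metric uses center 50 and scale 10: ``T = center + scale * theta``.
    """

    center: float = 50.0
    scale: float = 10.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.center) and math.isfinite(self.scale)):
            raise ValueError("metric center/scale must be finite")
        if self.scale <= 0:
            raise ValueError(f"metric scale must be > 0, got {self.scale}")


@dataclass
class ItemParameters:
    """One GRM-calibrated item: slope, ordered thresholds, category labels."""

    item_id: str
    stem: str
    labels: list[str]
    slope: float
    thresholds: list[float]
    direction_note: str = ""

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.thresholds = [float(b) for b in self.thresholds]
        self.slope = float(self.slope)
        if len(self.labels) < 2:
            raise ValueError(f"item {self.item_id!r}: need >= 2 categories")
        if self.slope <= 0 or not math.isfinite(self.slope):
            raise ValueError(f"item {self.item_id!r}: slope must be > 0")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError(
                f"item {self.item_id!r}: {len(self.labels)} labels require "
                f"{len(self.labels) - 1} thresholds, got {len(self.thresholds)}"
            )
        diffs = np.diff(self.thresholds)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.labels)


@dataclass
class ItemBank:
    """Ordered collection of items sharing one latent metric."""

    bank_id: str
    items: list[ItemParameters]
    metric: Metric = field(default_factory=Metric)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("bank must contain at least one item")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate item_ids in bank {self.bank_id!r}")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


@dataclass
class ProbabilitySnapshot:
    """Printed category-probability vector at one T-score.

    Probabilities are normalized on construction (printed values are rounded
    and need not sum exactly to 1).
    """

    t_score: float
    probabilities: list[float]

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("snapshot needs >= 2 category probabilities")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("snapshot probabilities must lie in [0, 1]")
        total = p.sum()
        if not (0.9 < total < 1.1):
            raise ValueError(f"snapshot probabilities sum to {total:.3f}, not ~1")
        self.probabilities = list(p / total)
        self.t_score = float(self.t_score)


def theta_from_t(t: float, metric: Metric = Metric()) -> float:
    """Convert a reporting-metric score to theta: ``theta = (t - center)/scale``."""
    t = float(t)
    if not math.isfinite(t):
        raise ValueError(f"non-finite score: {t}")
    return (t - metric.center) / metric.scale


def t_from_theta(theta: float, metric: Metric = Metric()) -> float:
    """Convert theta to the reporting metric: ``t = center + scale*theta``."""
    theta = float(theta)
    if not math.isfinite(theta):
        raise ValueError(f"non-finite theta: {theta}")
    return metric.center + metric.scale * theta


def boundary_probabilities(
    item: ItemParameters, theta, scaling_constant: float = 1.0
) -> np.ndarray:
    """Cumulative response curves P*_k(theta) = P(response >= k+1), k=1..K-1.

    ``theta`` may be a scalar or an array; the category axis is appended last.
    Values are strictly decreasing in k for any theta.
    """
    th = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds)
    z = scaling_constant * item.slope * (th[..., None] - b)
    return 1.0 / (1.0 + np.exp(-z))


def category_probabilities(
    item: ItemParameters, theta, scaling_constant: float = 1.0
) -> np.ndarray:
    """Category probabilities P_k = P*_{k-1} - P*_k, k = 1..K (sum to 1)."""
    star = boundary_probabilities(item, theta, scaling_constant)
    pad_shape = star.shape[:-1] + (1,)
    full = np.concatenate(
        [np.ones(pad_shape), star, np.zeros(pad_shape)], axis=-1
    )
    return full[..., :-1] - full[..., 1:]


def modal_category(
    item: ItemParameters, theta, scaling_constant: float = 1.0
) -> int | np.ndarray:
    """Most probable response category (1..K) at theta.

    Ties break toward the lower index (argmax-first), a deterministic rule
    that is conservative toward less severity; ties occur on a measure-zero
    set of theta.
    """
    p = category_probabilities(item, theta, scaling_constant)
    idx = np.argmax(p, axis=-1) + 1
    return int(idx) if np.ndim(theta) == 0 else idx


def _snapshot_cumulative(snapshot: ProbabilitySnapshot) -> np.ndarray:
    """Observed boundary probabilities from a snapshot, clamped and checked."""
    p = np.asarray(snapshot.probabilities)
    star = 1.0 - np.cumsum(p)[:-1]
    star = np.clip(star, _CLAMP_FIT, 1.0 - _CLAMP_FIT)
    if np.any(np.diff(star) >= 0):
        raise FitError(
            f"snapshot at T={snapshot.t_score}: cumulative probabilities "
            f"{np.round(star, 6).tolist()} are not strictly decreasing after "
            f"clamping; GRM ordering is infeasible"
        )
    return star


def fit_item_from_snapshots(
    snapshots: list[ProbabilitySnapshot],
    K: int,
    metric: Metric = Metric(),
    *,
    item_id: str = "fitted_item",
    stem: str = "",
    labels: list[str] | None = None,
    scaling_constant: float = 1.0,
) -> ItemParameters:
    """Invert printed probability snapshots into GRM item parameters.

    Deterministic bounded least squares on category probabilities.  Each
    snapshot is converted to cumulative (boundary) probabilities, clamped to
    [1e-6, 1-1e-6]; initial values come from a cumulative-logit linear
    regression (logit P*_sk = a*theta_s - a*b_k is linear in a and a*b_k);
    the refinement minimizes the summed squared error between model and
    observed *category* probabilities over (slope, thresholds), with the
    threshold ordering enforced by a log-gap parametrization.  No randomness
    is involved, so results are machine-reproducible.

    Raises
    ------
    FitError
        If fewer than 2 snapshots at distinct T are given, the constraint
        count is below K (underdetermined), or the cumulative probabilities
        are non-monotone after clamping.
    """
    if K < 2:
        raise FitError(f"K must be >= 2, got {K}")
    snaps = list(snapshots)
    if len({s.t_score for s in snaps}) < 2:
        raise FitError(
            f"need >= 2 snapshots at distinct T to identify one slope and "
            f"{K - 1} thresholds; got {len(snaps)} snapshot(s)"
        )
    for s in snaps:
        if len(s.probabilities) != K:
            raise FitError(
                f"snapshot at T={s.t_score} has {len(s.probabilities)} "
                f"categories, expected K={K}"
            )
    # (K-1) independent values per snapshot; need at least K constraints.
    if len(snaps) * (K - 1) < K:
        raise FitError("underdetermined: fewer constraints than parameters")

    thetas = np.array([theta_from_t(s.t_score, metric) for s in snaps])
    obs_cat = np.array([s.probabilities for s in snaps])  # (S, K)
    obs_star = np.array([_snapshot_cumulative(s) for s in snaps])  # (S, K-1)

    # --- analytic initialization: cumulative-logit linear regression -------
    # logit(P*_sk) = D*a*theta_s - D*a*b_k; unknowns x = (D*a, D*a*b_1..b_{K-1})
    logits = np.log(obs_star) - np.log1p(-np.clip(obs_star, _CLAMP_LOGIT, 1 - _CLAMP_LOGIT))
    S = len(snaps)
    rows, y = [], []
    for s in range(S):
        for k in range(K - 1):
            row = np.zeros(K)
            row[0] = thetas[s]
            row[1 + k] = -1.0
            rows.append(row)
            y.append(logits[s, k])
    coef, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(y), rcond=None)
    a0 = max(coef[0] / scaling_constant, 0.05)
    b0 = coef[1:] / (a0 * scaling_constant)
    b0 = np.maximum.accumulate(b0)  # enforce ordering for the start point
    gaps0 = np.maximum(np.diff(b0, prepend=b0[0]), 1e-3)[1:] if K > 2 else np.array([])

    # --- refinement: least squares on category probabilities ---------------
    # x = [log a, b_1, log(gap_2), ..., log(gap_{K-1})] keeps a > 0 and the
    # thresholds strictly increasing without explicit bounds.
    x0 = np.concatenate([[np.log(a0), b0[0]], np.log(gaps0)])

    def unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
        a = float(np.exp(x[0]))
        b = np.concatenate([[x[1]], x[1] + np.cumsum(np.exp(x[2:]))])
        return a, b

    def residuals(x: np.ndarray) -> np.ndarray:
        a, b = unpack(x)
        z = scaling_constant * a * (thetas[:, None] - b)
        star = 1.0 / (1.0 + np.exp(-z))
        full = np.concatenate(
            [np.ones((S, 1)), star, np.zeros((S, 1))], axis=1
        )
        model = full[:, :-1] - full[:, 1:]
        return (model - obs_cat).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a_hat, b_hat = unpack(sol.x)
    if labels is None:
        labels = [f"category_{k}" for k in range(1, K + 1)]
    return ItemParameters(
        item_id=item_id,
        stem=stem,
        labels=list(labels),
        slope=a_hat,
        thresholds=list(b_hat),
    )


def snapshot_residuals(
    item: ItemParameters,
    snapshots: list[ProbabilitySnapshot],
    metric: Metric = Metric(),
    scaling_constant: float = 1.0,
) -> np.ndarray:
    """Model-minus-observed category probabilities, shape (n_snapshots, K)."""
    out = []
    for s in snapshots:
        p = category_probabilities(item, theta_from_t(s.t_score, metric), scaling_constant)
        out.append(p - np.asarray(s.probabilities))
    return np.asarray(out)
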