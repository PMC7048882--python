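"""Synthetic item banks, GRM response simulation, and the enumeration oracle.

Real PROMIS calibrations are licensed artifacts that are not bundled here;
these generators produce structurally equivalent fixtures so every pipeline
stage is testable end to end.  The *clinical-like* preset emulates a chronic-
condition sample — n = 1594 respondents with T ~ N(52, 9.5) on the scored
domain, the midpoint of the four scale means/SDs of the study population the
method was validated on.  It is an emulation of the score distribution only:
no diagnosis mix, demographics, cross-domain correlation, or IRT misfit
(e.g. local dependence) is modelled, so passing tests demonstrate internal
consistency of the method, not agreement with any particular clinical
dataset.

``expected_match_rates`` is the analytic twin of the observed match rates:
it enumerates every response pattern (exactly, for small forms), scores each
pattern, reads the predicted responses off the map at the scored T, and
accumulates model-probability-weighted match indicators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grm_core import (
    ItemBank,
    ItemParameters,
    Metric,
    category_probabilities,
    modal_category,
)
from .map_builder import TScoreMap
from .scoring import QuadratureGrid, eap_theta_pattern, make_grid, summed_score_to_t
from .validation_pipeline import predict_responses

__all__ = [
    "SimulationConfig",
    "ExpectedMatchRates",
    "make_fixture_bank",
    "simulate_respondents",
    "clinical_like_config",
    "expected_match_rates",
]

#: Symptom-style category labels used for 5-category fixture items.
SYMPTOM_LABELS = ["never", "rarely", "sometimes", "often", "always"]

#: Parameters of the engineered item whose second category is never modal:
#: the first two thresholds are close together and the slope is low, so the
#: adjacent categories' curves dominate category 2 everywhere.
NEVER_MODAL_ITEM = {"slope": 0.8, "thresholds": [-0.1, 0.1, 1.5, 1.7]}

#: Full pattern enumeration is exact up to this many patterns; larger forms
#: fall back to seeded Monte Carlo.
MAX_ENUMERATION_PATTERNS = 20_000


@dataclass(frozen=True)
class SimulationConfig:
    """Respondent-simulation settings; theta parameters are on the T metric."""

    bank_id: str
    n_respondents: int
    theta_mean_t: float = 50.0
    theta_sd_t: float = 10.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.theta_sd_t <= 0:
            raise ValueError("theta_sd_t must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def clinical_like_config(bank_id: str, seed: int = 7) -> SimulationConfig:
    """Chronic-condition-sample emulation: n=1594, T ~ N(52, 9.5)."""
    return SimulationConfig(
        bank_id=bank_id,
        n_respondents=1594,
        theta_mean_t=52.0,
        theta_sd_t=9.5,
        missing_rate=0.0,
        seed=seed,
    )


def make_short_form_bank(seed: int = 0, n_items: int = 4) -> "ItemBank":
    """Four-item short form emulating an operational symptom scale.

    Unlike the default fixture, no engineered never-modal item is included:
    operational short forms are composed of well-functioning items, and the
    clinical-like concordance analysis targets that regime.  Slope and
    threshold defaults follow :func:`make_fixture_bank`.
    """
    return make_fixture_bank(
        n_items=n_items,
        seed=seed,
        include_never_modal=False,
        bank_id=f"short_form_{n_items}item_seed{seed}",
    )


def make_fixture_bank(
    n_items: int = 8,
    K: int = 5,
    slope_range: tuple[float, float] = (2.5, 4.2),
    threshold_span: tuple[float, float] = (0.0, 2.6),
    seed: int = 0,
    bank_id: str | None = None,
    include_never_modal: bool = True,
) -> ItemBank:
    """Reproducible synthetic GRM bank.

    Slopes are drawn uniformly in ``slope_range``.  Each item's K−1
    thresholds are evenly spread positions across ``threshold_span`` with
    uniform jitter of up to ±30% of the inter-threshold spacing — the
    well-separated threshold structure typical of operational symptom
    calibrations, under which every category is usually modal somewhere.
    When ``include_never_modal`` is set (and K ≥ 3), the last item is
    replaced by a fixed engineered item whose second category is never the
    modal response — the map edge case of an omitted band.
    """
    if n_items < 1 or K < 2:
        raise ValueError("need n_items >= 1 and K >= 2")
    a_lo, a_hi = slope_range
    b_lo, b_hi = threshold_span
    if not (0 < a_lo <= a_hi) or not b_lo < b_hi:
        raise ValueError("degenerate slope_range or threshold_span")
    rng = np.random.default_rng(seed)
    labels = SYMPTOM_LABELS if K == 5 else [f"level_{k}" for k in range(1, K + 1)]
    items = []
    for i in range(n_items):
        slope = float(rng.uniform(a_lo, a_hi))
        base = np.linspace(b_lo, b_hi, K - 1)
        spacing = (b_hi - b_lo) / max(K - 2, 1)
        b = np.sort(base + rng.uniform(-0.3 * spacing, 0.3 * spacing, size=K - 1))
        # enforce a minimum threshold gap so categories are identifiable
        for j in range(1, K - 1):
            b[j] = max(b[j], b[j - 1] + 0.1)
        items.append(
            ItemParameters(
                item_id=f"item_{i + 1:02d}",
                stem=f"Synthetic symptom statement {i + 1}",
                labels=labels,
                slope=slope,
                thresholds=list(b),
            )
        )
    if include_never_modal and K >= 3 and n_items >= 1:
        nm_b = list(NEVER_MODAL_ITEM["thresholds"])[: K - 1]
        if len(nm_b) < K - 1:  # extend deterministically for large K
            last = nm_b[-1]
            nm_b += [last + 0.5 * (j + 1) for j in range(K - 1 - len(nm_b))]
        items[-1] = ItemParameters(
            item_id=items[-1].item_id,
            stem="Synthetic item with a never-modal middle category",
            labels=labels,
            slope=NEVER_MODAL_ITEM["slope"],
            thresholds=nm_b,
        )
    if bank_id is None:
        bank_id = f"fixture_{n_items}item_seed{seed}"
    return ItemBank(bank_id=bank_id, items=items, metric=Metric())


def simulate_respondents(
    bank: ItemBank, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw GRM responses for simulated respondents.

    theta_i ~ Normal((theta_mean_t − 50)/10, theta_sd_t/10); each response
    is drawn by inverse CDF over the item's category probabilities; missing
    entries are injected completely at random at ``missing_rate``.  Returns
    ``(responses, truth)``: a respondents × items frame of nullable-integer
    categories, and a sidecar with the true theta (and T) per respondent so
    recovery tests never need to touch the response file.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = bank.metric
    mean = (config.theta_mean_t - m.center) / m.scale
    sd = config.theta_sd_t / m.scale
    thetas = rng.normal(mean, sd, size=config.n_respondents)

    data: dict[str, np.ndarray] = {}
    for item in bank.items:
        p = category_probabilities(item, thetas)  # (n, K)
        u = rng.uniform(size=config.n_respondents)
        cats = 1 + (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
        data[item.item_id] = cats
    responses = pd.DataFrame(data, dtype="Int64")
    responses.index = pd.Index(
        [f"r{i + 1:05d}" for i in range(config.n_respondents)],
        name="respondent_id",
    )
    if config.missing_rate > 0:
        mask = rng.uniform(size=responses.shape) < config.missing_rate
        responses = responses.mask(mask)
    truth = pd.DataFrame(
        {
            "theta": thetas,
            "t": m.center + m.scale * thetas,
            "seed": config.seed,
        },
        index=responses.index,
    )
    return responses, truth


@dataclass
class ExpectedMatchRates:
    """Model-expected concordance under a given population of theta."""

    per_item: dict[str, float]  # P(observed == predicted) per item
    perfect: float  # P(exact match on every item)
    method: str  # "enumeration" or "monte_carlo"
    n_patterns: int


def expected_match_rates(
    bank: ItemBank,
    tmap: TScoreMap,
    population_grid: QuadratureGrid,
    scoring_grid: QuadratureGrid | None = None,
    scoring_method: str = "summed",
    n_mc: int = 200_000,
    seed: int = 0,
) -> ExpectedMatchRates:
    """Expected per-item and perfect match probabilities.

    For each complete response pattern x: weight = Σ_q w_q Π_i P_i(x_i|θ_q)
    under the *population* grid; the pattern is scored (summed-score table
    or pattern EAP, both under the standard scoring prior unless
    ``scoring_grid`` is given), predictions are read off the map at the
    scored T, and match indicators are accumulated.  Exact enumeration is
    used when the pattern count is tractable (all banks of ≤ 5 five-category
    items qualify); larger forms use seeded Monte Carlo over the same
    population grid.
    """
    if scoring_grid is None:
        scoring_grid = make_grid()
    if scoring_method not in ("summed", "pattern"):
        raise ValueError(f"unknown scoring method {scoring_method!r}")
    item_ids = bank.item_ids
    Ks = [it.n_categories for it in bank.items]
    n_patterns = int(np.prod(Ks))
    probs = [
        category_probabilities(it, population_grid.nodes) for it in bank.items
    ]  # list of (n_nodes, K_i)
    table = (
        summed_score_to_t(bank, scoring_grid) if scoring_method == "summed" else None
    )

    def t_of_pattern(x: tuple[int, ...]) -> float:
        if scoring_method == "summed":
            return float(table.lookup(sum(x))["t"])
        return eap_theta_pattern(dict(zip(item_ids, x)), bank, scoring_grid)["t"]

    if n_patterns <= MAX_ENUMERATION_PATTERNS:
        match_item = dict.fromkeys(item_ids, 0.0)
        match_all = 0.0
        for x in itertools.product(*(range(1, K + 1) for K in Ks)):
            lik = population_grid.weights.copy()
            for i, xi in enumerate(x):
                lik *= probs[i][:, xi - 1]
            w = float(lik.sum())
            if w == 0.0:
                continue
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                pred = predict_responses(t_of_pattern(x), tmap)
            hits = [pred[item_ids[i]] == xi for i, xi in enumerate(x)]
            for i, h in enumerate(hits):
                if h:
                    match_item[item_ids[i]] += w
            if all(hits):
                match_all += w
        return ExpectedMatchRates(match_item, match_all, "enumeration", n_patterns)

    # Monte Carlo over the population grid (theta drawn from the discrete
    # prior so results converge to the enumeration value).
    rng = np.random.default_rng(seed)
    nodes_idx = rng.choice(
        len(population_grid.nodes), size=n_mc, p=population_grid.weights
    )
    draws = np.empty((n_mc, len(bank.items)), dtype=int)
    for i, it in enumerate(bank.items):
        p = probs[i][nodes_idx]  # (n_mc, K_i)
        u = rng.uniform(size=n_mc)
        draws[:, i] = 1 + (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
    # score each unique pattern once
    uniq, inv = np.unique(draws, axis=0, return_inverse=True)
    import warnings as _warnings

    preds = np.empty_like(uniq)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for j, x in enumerate(uniq):
            pred = predict_responses(t_of_pattern(tuple(int(v) for v in x)), tmap)
            preds[j] = [pred[i] for i in item_ids]
    hit = uniq == preds  # per unique pattern, per item
    hits_per_draw = hit[inv]
    per_item = {
        item_ids[i]: float(hits_per_draw[:, i].mean()) for i in range(len(item_ids))
    }
    perfect = float(hits_per_draw.all(axis=1).mean())
    return ExpectedMatchRates(per_item, perfect, "monte_carlo", n_mc)
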