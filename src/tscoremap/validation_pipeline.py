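"""Predicted-vs-observed concordance analysis for T-score Maps.

Each respondent is scored on the short form, the resulting T is located on
the map, and the map's modal response for every item becomes that
respondent's *predicted* response.  Concordance is summarized by difference
scores (observed − predicted; positive = more severe than predicted),
per-item exact/adjacent match rates, per-item Spearman correlations between
predicted and observed categories, and the scale-level perfect-match rate
(every item exactly matched).

Missing data: respondents contribute to each item's table wherever the
observed response is present, but are excluded from the perfect-match
denominator if any item is missing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grm_core import ItemBank
from .map_builder import TScoreMap
from .scoring import QuadratureGrid, UnscorableError, score_responses

__all__ = [
    "PredictionRecord",
    "ItemConcordance",
    "ValidationReport",
    "UndefinedCorrelationError",
    "predict_responses",
    "difference_table",
    "spearman_predicted_observed",
    "perfect_match_rate",
    "validation_report",
]


class UndefinedCorrelationError(ValueError):
    """Spearman correlation undefined (constant vector or too few pairs)."""


@dataclass
class PredictionRecord:
    """One respondent: T-score, per-item predicted/observed categories."""

    respondent_id: str
    t: float
    predicted: dict[str, int]
    observed: dict[str, int | None]

    @property
    def differences(self) -> dict[str, int | None]:
        """Observed − predicted per item (None where unobserved)."""
        return {
            i: (None if self.observed.get(i) is None else self.observed[i] - p)
            for i, p in self.predicted.items()
        }


def predict_responses(t: float, tmap: TScoreMap) -> dict[str, int]:
    """Map-predicted category for every item at score t.

    A score exactly on a band boundary belongs to the lower-category band
    (half-open intervals).  Scores outside the map range are clamped to the
    nearest edge with a warning.
    """
    t = float(t)
    if t < tmap.t_min or t > tmap.t_max:
        clamped = min(max(t, tmap.t_min), tmap.t_max)
        warnings.warn(
            f"T={t:.2f} outside map range [{tmap.t_min}, {tmap.t_max}]; "
            f"clamped to {clamped}",
            stacklevel=2,
        )
        t = clamped
    return {i: tmap.band_at(i, t).category for i in tmap.item_ids}


def difference_table(
    records: list[PredictionRecord], item_id: str, n_categories: int = 5
) -> pd.DataFrame:
    """Difference-score distribution for one item.

    Rows cover every difference −(K−1)..+(K−1); records with a missing
    observation for the item are excluded from N.  Raises on zero scorable
    records.
    """
    diffs = [
        r.differences[item_id]
        for r in records
        if r.differences.get(item_id) is not None
    ]
    if not diffs:
        raise ValueError(f"no scorable records for item {item_id!r}")
    span = np.arange(-(n_categories - 1), n_categories)
    counts = pd.Series(diffs).value_counts().reindex(span, fill_value=0)
    n = int(counts.sum())
    return pd.DataFrame(
        {
            "difference": span,
            "n": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / n,
        }
    )


def spearman_predicted_observed(
    records: list[PredictionRecord], item_id: str
) -> float:
    """Spearman rank correlation between predicted and observed categories.

    Ties get average (mid) ranks — Pearson correlation on midranks.  The
    correlation is undefined for constant vectors or fewer than 3 pairs and
    raises :class:`UndefinedCorrelationError` rather than returning 0.
    """
    pairs = [
        (r.predicted[item_id], r.observed[item_id])
        for r in records
        if r.observed.get(item_id) is not None
    ]
    if len(pairs) < 3:
        raise UndefinedCorrelationError(
            f"item {item_id!r}: need >= 3 scorable pairs, got {len(pairs)}"
        )
    pred, obs = map(np.asarray, zip(*pairs))
    if len(set(pred)) < 2 or len(set(obs)) < 2:
        raise UndefinedCorrelationError(
            f"item {item_id!r}: constant predicted or observed vector; "
            f"Spearman correlation undefined"
        )
    return float(stats.spearmanr(pred, obs).statistic)


def perfect_match_rate(records: list[PredictionRecord]) -> float:
    """Percent of respondents with difference 0 on *every* item.

    Respondents with any missing item are excluded from the denominator.
    """
    complete = [
        r for r in records if all(d is not None for d in r.differences.values())
    ]
    if not complete:
        return float("nan")
    hits = sum(
        all(d == 0 for d in r.differences.values()) for r in complete
    )
    return 100.0 * hits / len(complete)


@dataclass
class ItemConcordance:
    """Concordance summary for one item (one Table block)."""

    item_id: str
    table: pd.DataFrame  # difference, n, percent
    total_n: int
    exact_match_pct: float
    adjacent_more_severe_pct: float  # difference +1
    adjacent_less_severe_pct: float  # difference −1
    spearman_r: float | None


@dataclass
class ValidationReport:
    """Full predicted-vs-observed report for one scale."""

    bank_id: str
    n_respondents: int
    items: dict[str, ItemConcordance]
    perfect_match_pct: float
    t_mean: float
    t_sd: float
    scoring_method: str
    records: list[PredictionRecord] = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bank_id": self.bank_id,
            "n_respondents": self.n_respondents,
            "scoring_method": self.scoring_method,
            "t_mean": self.t_mean,
            "t_sd": self.t_sd,
            "perfect_match_pct": self.perfect_match_pct,
            "items": {
                i: {
                    "total_n": c.total_n,
                    "exact_match_pct": c.exact_match_pct,
                    "adjacent_more_severe_pct": c.adjacent_more_severe_pct,
                    "adjacent_less_severe_pct": c.adjacent_less_severe_pct,
                    "spearman_r": c.spearman_r,
                    "differences": {
                        str(int(row["difference"])): {
                            "n": int(row["n"]),
                            "percent": round(float(row["percent"]), 1),
                        }
                        for _, row in c.table.iterrows()
                    },
                }
                for i, c in self.items.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per item × difference value.

        Percentages rounded to one decimal for publication-style output;
        ``r`` and ``total_n`` repeat on each of the item's rows.
        """
        rows = []
        for item_id, c in self.items.items():
            for _, row in c.table.iterrows():
                rows.append(
                    {
                        "bank_id": self.bank_id,
                        "item_id": item_id,
                        "difference": int(row["difference"]),
                        "n": int(row["n"]),
                        "percent": round(float(row["percent"]), 1),
                        "spearman_r": c.spearman_r,
                        "total_n": c.total_n,
                    }
                )
        return pd.DataFrame(rows)


def validation_report(
    responses: pd.DataFrame,
    bank: ItemBank,
    tmap: TScoreMap,
    grid: QuadratureGrid | None = None,
    method: str = "summed",
    integer_t: bool = False,
) -> ValidationReport:
    """Score every respondent, predict from the map, and tabulate concordance.

    ``responses``: respondents × items frame of categories 1..K (NaN/NA =
    missing), indexed or keyed by respondent id.  ``integer_t=True`` rounds
    each T to the nearest integer before map lookup (compatibility mode for
    maps published at integer resolution); the default places the unrounded
    T on the map.  Respondents with every item missing are dropped with a
    warning.
    """
    if responses.empty:
        raise ValueError("empty response matrix")
    unknown = [
        c for c in responses.columns
        if c not in bank.item_ids and c != "respondent_id"
    ]
    if unknown:
        raise ValueError(f"unknown item columns in responses: {unknown}")
    if "respondent_id" in responses.columns:
        responses = responses.set_index("respondent_id")

    scorable_mask = responses[bank.item_ids].notna().any(axis=1)
    n_dropped = int((~scorable_mask).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} all-missing respondent(s)", stacklevel=2)
        responses = responses[scorable_mask]
    if responses.empty:
        raise UnscorableError("no scorable respondents")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fallback warnings aggregated here
        scored = score_responses(responses, bank, grid, method)

    records: list[PredictionRecord] = []
    for rid, srow in scored.iterrows():
        t_place = round(float(srow["t"])) if integer_t else float(srow["t"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # out-of-range clamping
            pred = predict_responses(t_place, tmap)
        obs_row = responses.loc[rid, bank.item_ids]
        obs = {
            i: (None if pd.isna(v) else int(v)) for i, v in obs_row.items()
        }
        records.append(PredictionRecord(str(rid), float(srow["t"]), pred, obs))

    items: dict[str, ItemConcordance] = {}
    for item in bank.items:
        K = item.n_categories
        table = difference_table(records, item.item_id, K)
        by_diff = table.set_index("difference")
        try:
            r = spearman_predicted_observed(records, item.item_id)
        except UndefinedCorrelationError:
            r = None
        items[item.item_id] = ItemConcordance(
            item_id=item.item_id,
            table=table,
            total_n=int(table["n"].sum()),
            exact_match_pct=float(by_diff.loc[0, "percent"]),
            adjacent_more_severe_pct=float(by_diff.loc[1, "percent"]),
            adjacent_less_severe_pct=float(by_diff.loc[-1, "percent"]),
            spearman_r=r,
        )

    return ValidationReport(
        bank_id=bank.bank_id,
        n_respondents=len(records),
        items=items,
        perfect_match_pct=perfect_match_rate(records),
        t_mean=float(scored["t"].mean()),
        t_sd=float(scored["t"].std(ddof=1)),
        scoring_method=method,
        records=records,
    )
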