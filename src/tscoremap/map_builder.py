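"""Build T-score Maps: modal-response bands over the T continuum.

A T-score Map shows, for each item of a short form, which response option is
the most probable one at every score on the T metric.  Each item's map is a
partition of the score range into contiguous half-open bands ``[t_low,
t_high)``, one per response category that is modal somewhere in the range
(categories that are never modal are omitted, not drawn as zero-width bands).
Band boundaries are located exactly by bisection on the difference between
the two competing category curves.

Conventions: the default range is [20, 80] (±3 SD around the reference mean),
intervals are half-open so a score exactly at a crossing belongs to the
lower-category band (matching the lower-index modal tie rule), JSON output
keeps full precision while the CSV adds display columns rounded to 0.1 T.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm_core import (
    ItemBank,
    ItemParameters,
    Metric,
    category_probabilities,
    modal_category,
    theta_from_t,
)

__all__ = [
    "Band",
    "TScoreMap",
    "crossing_point",
    "build_map",
    "export_map",
    "map_to_dict",
    "map_from_dict",
    "map_to_frame",
    "map_from_frame",
    "render_figure",
]

#: Grid step (T units) used to scan for modal-category changes.
DEFAULT_GRID_STEP = 0.01
#: Bisection stops when the bracket is narrower than this (T units).
CROSSING_TOL = 1e-6


@dataclass(frozen=True)
class Band:
    """One contiguous interval [t_low, t_high) where `category` is modal."""

    item_id: str
    category: int
    label: str
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(
                f"band {self.item_id}/{self.category}: t_low {self.t_low} "
                f"must be < t_high {self.t_high}"
            )

    def contains(self, t: float) -> bool:
        return self.t_low <= t < self.t_high


@dataclass
class TScoreMap:
    """Per-item modal-response bands tiling a T-score range."""

    bank_id: str
    t_min: float
    t_max: float
    bands: dict[str, list[Band]]
    omitted_labels: dict[str, list[str]] = field(default_factory=dict)
    grid_step: float = DEFAULT_GRID_STEP

    @property
    def item_ids(self) -> list[str]:
        return list(self.bands)

    def band_at(self, item_id: str, t: float) -> Band:
        """Band containing score t for one item (t must lie in the range)."""
        for band in self.bands[item_id]:
            if band.contains(t):
                return band
        # t == t_max falls outside every half-open band; assign the top band.
        if t == self.t_max:
            return self.bands[item_id][-1]
        raise ValueError(
            f"t={t} outside map range [{self.t_min}, {self.t_max}]"
        )


def crossing_point(
    item: ItemParameters,
    cat_a: int,
    cat_b: int,
    bracket: tuple[float, float],
    metric: Metric = Metric(),
    scaling_constant: float = 1.0,
) -> float:
    """Exact T where P(cat_b) overtakes P(cat_a), by bisection.

    Requires P(cat_a) > P(cat_b) at ``bracket[0]`` and the reverse at
    ``bracket[1]``.  Bisects f(T) = P(cat_b) - P(cat_a) until the bracket is
    narrower than 1e-6 T units.
    """
    t1, t2 = float(bracket[0]), float(bracket[1])

    def f(t: float) -> float:
        p = category_probabilities(item, theta_from_t(t, metric), scaling_constant)
        return p[cat_b - 1] - p[cat_a - 1]

    f1, f2 = f(t1), f(t2)
    if not (f1 < 0 <= f2 or f1 <= 0 < f2):
        raise ValueError(
            f"bracket [{t1}, {t2}] does not straddle a {cat_a}->{cat_b} "
            f"crossing (f={f1:.4g}, {f2:.4g})"
        )
    lo, hi = t1, t2
    while hi - lo > CROSSING_TOL:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_map(
    bank: ItemBank,
    t_min: float = 20.0,
    t_max: float = 80.0,
    grid_step: float = DEFAULT_GRID_STEP,
    scaling_constant: float = 1.0,
) -> TScoreMap:
    """Scan each item's modal category on a fine T grid and emit bands.

    Change points found on the grid are refined by :func:`crossing_point`;
    per item the resulting half-open bands tile [t_min, t_max) with strictly
    increasing category codes.  A degenerate item (one category modal
    everywhere in range) yields a single full-range band.
    """
    if not t_min < t_max:
        raise ValueError(f"t_min {t_min} must be < t_max {t_max}")
    n = int(round((t_max - t_min) / grid_step)) + 1
    grid = np.linspace(t_min, t_max, n)
    thetas = (grid - bank.metric.center) / bank.metric.scale

    bands: dict[str, list[Band]] = {}
    omitted: dict[str, list[str]] = {}
    for item in bank.items:
        modal = modal_category(item, thetas, scaling_constant)
        # Modal category is non-decreasing in theta for a GRM item; collapse
        # the grid to its change points.
        change = np.nonzero(np.diff(modal))[0]
        edges: list[float] = []
        cats: list[int] = [int(modal[0])]
        for i in change:
            cat_a, cat_b = int(modal[i]), int(modal[i + 1])
            t_cross = crossing_point(
                item, cat_a, cat_b, (grid[i], grid[i + 1]), bank.metric,
                scaling_constant,
            )
            edges.append(t_cross)
            cats.append(cat_b)
        cuts = [t_min, *edges, t_max]
        item_bands = [
            Band(item.item_id, cat, item.labels[cat - 1], lo, hi)
            for cat, lo, hi in zip(cats, cuts[:-1], cuts[1:])
        ]
        bands[item.item_id] = item_bands
        present = {b.category for b in item_bands}
        omitted[item.item_id] = [
            item.labels[k - 1]
            for k in range(1, item.n_categories + 1)
            if k not in present
        ]
    return TScoreMap(
        bank_id=bank.bank_id,
        t_min=float(t_min),
        t_max=float(t_max),
        bands=bands,
        omitted_labels=omitted,
        grid_step=float(grid_step),
    )


# ---------------------------------------------------------------------------
# serialization


def map_to_dict(tmap: TScoreMap) -> dict:
    return {
        "bank_id": tmap.bank_id,
        "t_range": [tmap.t_min, tmap.t_max],
        "resolution": {"grid_step": tmap.grid_step, "crossing_tol": CROSSING_TOL},
        "items": [
            {
                "item_id": item_id,
                "bands": [
                    {
                        "category": b.category,
                        "label": b.label,
                        "t_low": b.t_low,
                        "t_high": b.t_high,
                    }
                    for b in item_bands
                ],
                "omitted_labels": tmap.omitted_labels.get(item_id, []),
            }
            for item_id, item_bands in tmap.bands.items()
        ],
    }


def map_from_dict(d: dict) -> TScoreMap:
    t_min, t_max = d["t_range"]
    bands = {
        rec["item_id"]: [
            Band(rec["item_id"], b["category"], b["label"], b["t_low"], b["t_high"])
            for b in rec["bands"]
        ]
        for rec in d["items"]
    }
    omitted = {rec["item_id"]: list(rec.get("omitted_labels", [])) for rec in d["items"]}
    return TScoreMap(
        bank_id=d["bank_id"],
        t_min=float(t_min),
        t_max=float(t_max),
        bands=bands,
        omitted_labels=omitted,
        grid_step=float(d.get("resolution", {}).get("grid_step", DEFAULT_GRID_STEP)),
    )


def map_to_frame(tmap: TScoreMap) -> pd.DataFrame:
    """Tidy one-row-per-band table.

    ``t_low``/``t_high`` keep full precision (so CSV round trips are exact);
    ``t_low_display``/``t_high_display`` are rounded to 0.1 T for publication-
    style reporting.
    """
    rows = [
        {
            "bank_id": tmap.bank_id,
            "item_id": item_id,
            "category": b.category,
            "label": b.label,
            "t_low": b.t_low,
            "t_high": b.t_high,
            "t_low_display": round(b.t_low, 1),
            "t_high_display": round(b.t_high, 1),
        }
        for item_id, item_bands in tmap.bands.items()
        for b in item_bands
    ]
    return pd.DataFrame(rows)


def map_from_frame(frame: pd.DataFrame, grid_step: float = DEFAULT_GRID_STEP) -> TScoreMap:
    bands: dict[str, list[Band]] = {}
    for _, row in frame.iterrows():
        bands.setdefault(str(row["item_id"]), []).append(
            Band(
                str(row["item_id"]),
                int(row["category"]),
                str(row["label"]),
                float(row["t_low"]),
                float(row["t_high"]),
            )
        )
    for item_bands in bands.values():
        item_bands.sort(key=lambda b: b.t_low)
    t_min = min(b.t_low for ib in bands.values() for b in ib)
    t_max = max(b.t_high for ib in bands.values() for b in ib)
    return TScoreMap(
        bank_id=str(frame["bank_id"].iloc[0]),
        t_min=t_min,
        t_max=t_max,
        bands=bands,
        grid_step=grid_step,
    )


def render_figure(tmap: TScoreMap, bank: ItemBank | None = None):
    """Matplotlib figure: a T-score ruler and one shaded band row per item.

    Timestamp metadata is suppressed on save so output files are
    byte-reproducible.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    item_ids = tmap.item_ids
    n_items = len(item_ids)
    fig, ax = plt.subplots(figsize=(10, 0.6 * n_items + 1.5))
    n_cat = max(b.category for ib in tmap.bands.values() for b in ib)
    cmap = colormaps["YlOrRd"]
    for row, item_id in enumerate(item_ids):
        y = n_items - 1 - row
        for band in tmap.bands[item_id]:
            bars = ax.barh(
                y,
                band.t_high - band.t_low,
                left=band.t_low,
                height=0.8,
                color=cmap(0.15 + 0.7 * (band.category - 1) / max(n_cat - 1, 1)),
                edgecolor="black",
                linewidth=0.5,
            )
            for patch in bars:
                patch.set_gid(f"band-{item_id}-{band.category}")
            ax.text(
                0.5 * (band.t_low + band.t_high),
                y,
                band.label,
                ha="center",
                va="center",
                fontsize=7,
                gid=f"bandlabel-{item_id}-{band.category}",
            )
    stems = {it.item_id: it.stem for it in bank.items} if bank else {}
    ax.set_yticks(range(n_items))
    ax.set_yticklabels(
        [stems.get(i) or i for i in reversed(item_ids)], fontsize=8
    )
    ax.set_xlim(tmap.t_min, tmap.t_max)
    ax.set_xlabel("T-score")
    ax.xaxis.set_ticks(np.arange(tmap.t_min, tmap.t_max + 1e-9, 5.0))
    ax.set_title(f"T-score Map: {tmap.bank_id}", gid="tscore-ruler-title")
    fig.tight_layout()
    return fig


def export_map(tmap: TScoreMap, fmt: str, bank: ItemBank | None = None) -> bytes:
    """Serialize a map as ``json``, ``csv``, ``svg`` or ``png`` bytes.

    JSON and CSV are deterministic and byte-stable; figure output suppresses
    embedded timestamps.
    """
    if fmt == "json":
        return (json.dumps(map_to_dict(tmap), indent=2, sort_keys=True) + "\n").encode()
    if fmt == "csv":
        return map_to_frame(tmap).to_csv(index=False).encode()
    if fmt in ("svg", "png"):
        import matplotlib.pyplot as plt

        fig = render_figure(tmap, bank)
        buf = io.BytesIO()
        fig.savefig(buf, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
        return buf.getvalue()
    raise ValueError(f"unknown export format {fmt!r}; use json, csv, svg or png")
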