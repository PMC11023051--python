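"""Space-covering surfactant screens on the 3-PC map.

Stage 1 (*screen1*) picks 8–10 surfactants that cover the map starting from an
origin (a known hit, or a centrally located designer surfactant such as
TPGS-750-M) by greedy maximin selection with optional top-q randomization.
Stage 2 (*screen2*) zooms into the neighbourhood of the best stage-1 hit,
returning its nearest neighbours. Distances are unweighted Euclidean in
(PC1, PC2, PC3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .mapping import FLOAT_FORMAT, MapCoordinates

DEFAULT_METRIC = "euclidean_pc123"


@dataclass
class ScreenPlan:
    """Ordered surfactant selection for one screening stage."""

    stage: int
    anchor_id: str
    selected: list[str]
    seed: Optional[int] = None
    metric: str = DEFAULT_METRIC

    def __post_init__(self) -> None:
        if self.stage not in (1, 2):
            raise ValueError(f"stage must be 1 or 2, got {self.stage}")
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("screen plan contains duplicate ids")
        if self.stage == 1 and (not self.selected or self.selected[0] != self.anchor_id):
            raise ValueError("stage-1 plans must start with the anchor (origin)")
        if self.stage == 2 and self.anchor_id in self.selected:
            raise ValueError("stage-2 plans must exclude the anchor (best hit)")


def select_screen1(
    coords: MapCoordinates,
    n: int = 8,
    origin_id: str = "",
    seed: int = 0,
    top_q: int = 3,
) -> ScreenPlan:
    """Seeded coverage-maximizing selection (greedy maximin from the origin).

    Starting from the origin surfactant, each step ranks the unselected
    candidates by their minimum Euclidean distance to the already-selected set
    and draws uniformly (from ``seed``) among the ``top_q`` best — randomizing
    the selection while maximizing coverage. ``top_q=1`` reduces to
    deterministic, seed-independent farthest-point sampling. Candidate
    ordering breaks distance ties lexicographically by id.
    """
    ids = coords.ids
    if origin_id not in ids:
        raise KeyError(f"unknown origin surfactant {origin_id!r}")
    if not 1 <= n <= len(ids):
        raise ValueError(f"n={n} outside 1..{len(ids)}")
    if top_q < 1:
        raise ValueError("top_q must be >= 1")
    pts = coords.points()
    rng = np.random.default_rng(seed)
    index = {sid: i for i, sid in enumerate(ids)}
    selected = [origin_id]
    min_dist = np.linalg.norm(pts - pts[index[origin_id]], axis=1)
    while len(selected) < n:
        chosen = set(selected)
        candidates = sorted(
            (sid for sid in ids if sid not in chosen),
            key=lambda sid: (-min_dist[index[sid]], sid),
        )
        pick = candidates[int(rng.integers(min(top_q, len(candidates))))]
        selected.append(pick)
        d_new = np.linalg.norm(pts - pts[index[pick]], axis=1)
        min_dist = np.minimum(min_dist, d_new)
    return ScreenPlan(stage=1, anchor_id=origin_id, selected=selected, seed=seed)


def select_screen2(
    coords: MapCoordinates,
    best_id: str,
    m: int = 5,
    exclude: Iterable[str] = (),
) -> ScreenPlan:
    """The ``m`` nearest surfactants around the best stage-1 hit.

    Excludes the best hit itself and any already-screened ids; distance ties
    break lexicographically by id. Deterministic.
    """
    ids = coords.ids
    if best_id not in ids:
        raise KeyError(f"unknown best-hit surfactant {best_id!r}")
    if m < 0:
        raise ValueError("m must be >= 0")
    excluded = set(exclude) | {best_id}
    pts = coords.points()
    anchor = coords.point_of(best_id)
    dist = np.linalg.norm(pts - anchor, axis=1)
    ranked = sorted(
        ((d, sid) for d, sid in zip(dist, ids) if sid not in excluded),
        key=lambda pair: (pair[0], pair[1]),
    )
    return ScreenPlan(stage=2, anchor_id=best_id, selected=[sid for _, sid in ranked[:m]])


def coverage_stats(coords: MapCoordinates, plan: ScreenPlan) -> dict:
    """Coverage of a plan: min pairwise distance and mean gap to unselected points.

    ``min_pairwise_distance`` is nan for plans smaller than 2;
    ``mean_nearest_unselected_distance`` is nan when the plan covers the map.
    """
    ids = coords.ids
    unknown = [sid for sid in plan.selected if sid not in ids]
    if unknown:
        raise KeyError(f"plan id(s) not in map: {unknown}")
    pts = coords.points()
    index = {sid: i for i, sid in enumerate(ids)}
    sel = np.array([index[sid] for sid in plan.selected], dtype=int)
    if sel.size >= 2:
        d = cdist(pts[sel], pts[sel])
        min_pairwise = float(d[np.triu_indices(sel.size, k=1)].min())
    else:
        min_pairwise = float("nan")
    unsel = np.array([i for i in range(len(ids)) if i not in set(sel)], dtype=int)
    if unsel.size and sel.size:
        mean_gap = float(cdist(pts[unsel], pts[sel]).min(axis=1).mean())
    else:
        mean_gap = float("nan")
    return {
        "min_pairwise_distance": min_pairwise,
        "mean_nearest_unselected_distance": mean_gap,
    }


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def plan_to_frame(coords: MapCoordinates, plan: ScreenPlan) -> pd.DataFrame:
    """Tabular plan: stage, anchor, rank, surfactant_id, distance_to_anchor."""
    anchor = coords.point_of(plan.anchor_id)
    rows = []
    for rank, sid in enumerate(plan.selected, start=1):
        d = float(np.linalg.norm(coords.point_of(sid) - anchor))
        rows.append(
            {
                "stage": plan.stage,
                "anchor": plan.anchor_id,
                "rank": rank,
                "surfactant_id": sid,
                "distance_to_anchor": d,
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["stage", "anchor", "rank", "surfactant_id", "distance_to_anchor"]
    )


def write_plan_csv(coords: MapCoordinates, plan: ScreenPlan, path) -> None:
    plan_to_frame(coords, plan).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_plan_json(plan: ScreenPlan, path) -> None:
    payload = {
        "stage": plan.stage,
        "anchor_id": plan.anchor_id,
        "selected": plan.selected,
        "seed": plan.seed,
        "metric": plan.metric,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
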