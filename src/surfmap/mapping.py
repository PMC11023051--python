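"""The 3-PC surfactant map: coordinates, loadings ranking, outliers, plots.

A fitted model's first three principal components place every surfactant in a
3D chemical space; charge classes cluster (cationic high on the charge-driven
PC, zwitterionic low), designer surfactants sit centrally, and loadings
rankings explain what each axis encodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mdpca import PCAModel
from .table import DescriptorSpec

#: 6 significant digits, locale-independent — used by all coordinate exports.
FLOAT_FORMAT = "%.6g"

CLASS_COLORS = {
    "cationic": "tab:red",
    "anionic": "tab:orange",
    "zwitterionic": "tab:green",
    "neutral": "tab:blue",
}


@dataclass
class MapCoordinates:
    """Per-surfactant PC1–3 positions with class/designer metadata.

    ``frame`` columns: id, charge_class, designer, pc1, pc2, pc3.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "charge_class", "designer", "pc1", "pc2", "pc3"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"coordinate frame lacks column(s) {missing}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate ids in map coordinates")
        if not np.all(np.isfinite(self.frame[["pc1", "pc2", "pc3"]].to_numpy())):
            raise ValueError("non-finite map coordinates")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def points(self) -> np.ndarray:
        """(n, 3) array of PC coordinates."""
        return self.frame[["pc1", "pc2", "pc3"]].to_numpy(dtype=float)

    def point_of(self, surfactant_id: str) -> np.ndarray:
        rows = self.frame.index[self.frame["id"] == surfactant_id]
        if len(rows) == 0:
            raise KeyError(f"unknown surfactant id {surfactant_id!r}")
        return self.points()[rows[0]]


def build_map(model: PCAModel, row_meta: pd.DataFrame) -> MapCoordinates:
    """Export the first three score columns with row metadata."""
    if model.k < 3:
        raise ValueError(f"need a model with k >= 3 components, got k={model.k}")
    if len(row_meta) != model.scores.shape[0]:
        raise ValueError("row metadata length does not match model scores")
    frame = pd.DataFrame(
        {
            "id": list(row_meta["id"]),
            "charge_class": list(row_meta["charge_class"]),
            "designer": list(row_meta["designer"]),
            "pc1": model.scores[:, 0],
            "pc2": model.scores[:, 1],
            "pc3": model.scores[:, 2],
        }
    )
    return MapCoordinates(frame)


def loadings_report(model: PCAModel, col_meta: Sequence[DescriptorSpec]) -> pd.DataFrame:
    """Per-PC descriptor loadings ranked by absolute value.

    Columns: pc (1-based), rank (1 = largest |loading|), descriptor, loading.
    Loading values are taken from the model bit-exactly.
    """
    names = [s.name for s in col_meta]
    if len(names) != model.loadings.shape[0]:
        raise ValueError("column metadata length does not match model loadings")
    records = []
    for c in range(model.k):
        col = model.loadings[:, c]
        order = np.argsort(-np.abs(col), kind="stable")
        for rank, j in enumerate(order, start=1):
            records.append(
                {"pc": c + 1, "rank": rank, "descriptor": names[j], "loading": col[j]}
            )
    return pd.DataFrame.from_records(records)


def flag_outliers(coords: MapCoordinates, factor: float = 3.0) -> list[str]:
    """Ids farther from the coordinate centroid than ``factor`` × median distance.

    Invariant under rigid rotation/translation of the map (distances only).
    """
    pts = coords.points()
    if len(pts) < 3:
        raise ValueError("need at least 3 points to flag outliers")
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    cutoff = factor * np.median(d)
    return [i for i, di in zip(coords.ids, d) if di > cutoff]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_coordinates(coords: MapCoordinates, path) -> None:
    frame = coords.frame.copy()
    frame["designer"] = frame["designer"].astype(int)
    frame = frame.rename(columns={"id": "surfactant_id", "charge_class": "class"})
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_coordinates(path) -> MapCoordinates:
    frame = pd.read_csv(path)
    frame = frame.rename(columns={"surfactant_id": "id", "class": "charge_class"})
    frame["designer"] = frame["designer"].astype(bool)
    return MapCoordinates(frame)


def write_loadings(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def plot_projections(coords: MapCoordinates, prefix) -> list[str]:
    """Three 2D projections (PC1–PC2, PC1–PC3, PC2–PC3), colored by class.

    Designer surfactants are drawn as stars. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pairs = [("pc1", "pc2"), ("pc1", "pc3"), ("pc2", "pc3")]
    for xcol, ycol in pairs:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cls, sub in coords.frame.groupby("charge_class"):
            color = CLASS_COLORS.get(cls, "tab:gray")
            plain = sub[~sub["designer"].astype(bool)]
            stars = sub[sub["designer"].astype(bool)]
            ax.scatter(plain[xcol], plain[ycol], s=18, c=color, label=cls)
            if len(stars):
                ax.scatter(stars[xcol], stars[ycol], s=70, c=color, marker="*",
                           edgecolors="k", linewidths=0.4)
        ax.set_xlabel(xcol.upper())
        ax.set_ylabel(ycol.upper())
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = f"{prefix}_{xcol}_{ycol}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written


def plot_map_3d(coords: MapCoordinates, path) -> str:
    """Static 3D scatter of the map (PC1, PC2, PC3), colored by class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for cls, sub in coords.frame.groupby("charge_class"):
        color = CLASS_COLORS.get(cls, "tab:gray")
        marker_sizes = np.where(sub["designer"].astype(bool), 60, 18)
        ax.scatter(sub["pc1"], sub["pc2"], sub["pc3"], s=marker_sizes, c=color, label=cls)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
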