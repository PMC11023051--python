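"""Synthetic descriptor tables with known ground truth.

Emulates the *shape* of the real surfactant table — low-rank structure, four
charge-class clusters, ~10.5% missing-completely-at-random cells, and a few
rows with concentrated experimental missingness — so that every pipeline stage
is testable without external data. Values are structural, not chemically
realistic: units and ranges of real descriptors are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .table import CHARGE_CLASSES, DescriptorSpec, DescriptorTable


class MaskError(RuntimeError):
    """No admissible missingness mask could be drawn."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic table generator.

    ``class_shift`` is the latent-space distance between adjacent class
    centroids (on the first latent axis); ``sparse_row_missing`` is the number
    of experimental cells blanked in each of the ``n_sparse_rows`` rows with
    concentrated missingness.
    """

    n_rows: int = 100
    n_cols: int = 25
    rank: int = 3
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    n_classes: int = 4
    class_shift: float = 4.0
    n_sparse_rows: int = 0
    sparse_row_missing: int = 6
    n_experimental_cols: int = 6
    designer_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank > min(self.n_rows, self.n_cols):
            raise ValueError("rank exceeds min(n_rows, n_cols)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in ("n_rows", "n_cols", "n_classes", "n_sparse_rows", "sparse_row_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_sparse_rows and self.sparse_row_missing > self.n_experimental_cols:
            raise ValueError("sparse_row_missing exceeds the number of experimental columns")


@dataclass
class GroundTruth:
    """What the generator planted: factors, loadings, labels, hidden values."""

    factors: np.ndarray  # n × rank latent scores (class shift included)
    loadings: np.ndarray  # p × rank orthonormal columns
    class_labels: np.ndarray  # n, strings
    values_full: np.ndarray  # n × p pre-masking matrix
    sparse_row_ids: list[str]

    def masked_values(self, mask: np.ndarray) -> np.ndarray:
        """True values of the cells hidden by ``mask`` (flat, row-major order)."""
        return self.values_full[~mask]


#: decreasing strengths of the latent axes — distinct component variances make
#: the planted subspace (and its ordering) identifiable.
_COMPONENT_SCALES = (3.0, 2.0, 1.0)


def _component_scales(rank: int) -> np.ndarray:
    if rank <= len(_COMPONENT_SCALES):
        return np.array(_COMPONENT_SCALES[:rank])
    extra = np.linspace(0.9, 0.5, rank - len(_COMPONENT_SCALES))
    return np.concatenate([_COMPONENT_SCALES, extra])


def generate_table(config: GeneratorConfig) -> tuple[DescriptorTable, GroundTruth]:
    """Low-rank class-clustered table with a controlled missingness mask.

    values = (class-shifted latent factors) · orthonormal loadingsᵀ + noise.
    The MCAR mask blanks an exact count of cells (round(rate × cells)) drawn
    without replacement over the non-sparse rows; sparse rows instead lose
    ``sparse_row_missing`` cells among the experimental columns. Masks are
    redrawn (up to 100 attempts) if any column would lose all but one
    observation, any row everything, or any non-sparse row would reach the
    sparse rows' experimental missing count — which keeps the planted sparse
    rows exactly the ones a ``drop_sparse_rows`` threshold below that count
    removes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p, r = cfg.n_rows, cfg.n_cols, cfg.rank

    classes = np.array([CHARGE_CLASSES[i % cfg.n_classes] for i in range(n)])
    centroid = {
        cls: cfg.class_shift * (i - (cfg.n_classes - 1) / 2.0)
        for i, cls in enumerate(CHARGE_CLASSES[: cfg.n_classes])
    }
    scales = _component_scales(r)
    shifted = r > 0 and cfg.n_classes > 1 and cfg.class_shift > 0
    if shifted:
        # the class centroids carry the first axis' variance; keep the
        # within-class spread at 1 so nearest-centroid assignment is clean
        scales = scales.copy()
        scales[0] = 1.0
    factors = rng.standard_normal((n, r)) * scales
    if shifted:
        factors[:, 0] += np.array([centroid[c] for c in classes])

    basis = np.linalg.qr(rng.standard_normal((p, r)))[0] if r > 0 else np.zeros((p, 0))
    values_full = factors @ basis.T + rng.normal(scale=cfg.noise_sd, size=(n, p))

    sparse_rows = rng.choice(n, size=cfg.n_sparse_rows, replace=False) if cfg.n_sparse_rows else np.array([], dtype=int)
    mask = _draw_mask(cfg, rng, sparse_rows)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    designer = rng.random(n) < cfg.designer_fraction
    row_meta = pd.DataFrame({"id": ids, "charge_class": classes, "designer": designer})
    col_meta = [
        DescriptorSpec(
            name=f"desc_{j + 1:02d}",
            block="micellar" if j < cfg.n_experimental_cols // 2 else (
                "emulsion" if j < cfg.n_experimental_cols else "molecular"
            ),
            source="literature" if j < cfg.n_experimental_cols // 2 else (
                "measured" if j < cfg.n_experimental_cols else "computed"
            ),
        )
        for j in range(p)
    ]
    table = DescriptorTable(np.where(mask, values_full, np.nan), mask, row_meta, col_meta)
    truth = GroundTruth(
        factors=factors,
        loadings=basis,
        class_labels=classes,
        values_full=values_full,
        sparse_row_ids=[ids[i] for i in sorted(sparse_rows)],
    )
    return table, truth


def _draw_mask(cfg: GeneratorConfig, rng: np.random.Generator, sparse_rows: np.ndarray) -> np.ndarray:
    n, p = cfg.n_rows, cfg.n_cols
    n_exp = cfg.n_experimental_cols
    sparse_set = set(int(i) for i in sparse_rows)
    nonsparse = np.array([i for i in range(n) if i not in sparse_set], dtype=int)
    n_mcar = int(round(cfg.missing_rate * nonsparse.size * p))
    for _ in range(100):
        mask = np.ones((n, p), dtype=bool)
        for i in sparse_rows:
            cols = rng.choice(n_exp, size=cfg.sparse_row_missing, replace=False)
            mask[i, cols] = False
        if n_mcar and nonsparse.size:
            flat = rng.choice(nonsparse.size * p, size=n_mcar, replace=False)
            mask[nonsparse[flat // p], flat % p] = False
        if not _mask_ok(cfg, mask, nonsparse):
            continue
        return mask
    raise MaskError("could not draw an admissible missingness mask in 100 attempts")


def _mask_ok(cfg: GeneratorConfig, mask: np.ndarray, nonsparse: np.ndarray) -> bool:
    if np.any(mask.sum(axis=0) < 2) or np.any(mask.sum(axis=1) < 1):
        return False
    if cfg.n_sparse_rows and nonsparse.size:
        exp_missing = (~mask[nonsparse, : cfg.n_experimental_cols]).sum(axis=1)
        if np.any(exp_missing >= cfg.sparse_row_missing):
            return False
    return True


# ---------------------------------------------------------------------------
# the canonical full-pipeline fixture
# ---------------------------------------------------------------------------

#: the published table's shape: 100 surfactants × 25 descriptors with 263
#: missing cells (10.5%), 9 of the surfactants lacking 6 experimental values.
PAPER_SHAPE = dict(n_rows=100, n_cols=25, n_sparse_rows=9, sparse_row_missing=6,
                   total_missing=263)


def paper_shape_config(seed: int = 0) -> GeneratorConfig:
    """Generator configuration reproducing the published table's shape."""
    shape = PAPER_SHAPE
    mcar_cells = shape["total_missing"] - shape["n_sparse_rows"] * shape["sparse_row_missing"]
    nonsparse_cells = (shape["n_rows"] - shape["n_sparse_rows"]) * shape["n_cols"]
    return GeneratorConfig(
        n_rows=shape["n_rows"],
        n_cols=shape["n_cols"],
        rank=3,
        noise_sd=0.1,
        missing_rate=mcar_cells / nonsparse_cells,
        n_classes=4,
        class_shift=4.0,
        n_sparse_rows=shape["n_sparse_rows"],
        sparse_row_missing=shape["sparse_row_missing"],
        seed=seed,
    )


def paper_shape_fixture(seed: int = 0) -> DescriptorTable:
    """100 × 25 rank-3 fixture, 4 classes, 263 missing cells, 9 sparse rows."""
    return generate_table(paper_shape_config(seed))[0]
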