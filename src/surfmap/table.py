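"""Domain types shared across the surfactant-map pipeline.

The central container is :class:`DescriptorTable`: a surfactants × descriptors
numeric matrix together with an observed-cell mask and row/column metadata.
Descriptors come in three blocks — micellar properties curated from the
literature (CMC, aggregation number, micelle size), emulsion properties
measured experimentally (contact angles, zeta potential, HLB) and molecular
properties computed from fragment structures or semi-empirical quantum
calculations. Experimental blocks carry missing values; the matrix stores
``nan`` at unobserved cells and the mask is the single source of truth for
observedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CHARGE_CLASSES = ("cationic", "anionic", "zwitterionic", "neutral")
BLOCKS = ("micellar", "emulsion", "molecular")
SOURCES = ("literature", "measured", "computed")

#: sources that correspond to experimental (literature-curated or measured)
#: descriptor columns; the sparse-row drop rule counts missingness over these.
EXPERIMENTAL_SOURCES = frozenset({"literature", "measured"})


class TableError(ValueError):
    """Raised when a descriptor table violates its structural invariants."""


@dataclass(frozen=True)
class DescriptorSpec:
    """Identity and provenance of one descriptor column."""

    name: str
    block: str
    source: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise TableError(f"unknown descriptor block {self.block!r} for {self.name!r}")
        if self.source not in SOURCES:
            raise TableError(f"unknown descriptor source {self.source!r} for {self.name!r}")


@dataclass(frozen=True)
class FragmentPair:
    """Hydrophilic/hydrophobic fragment structures for one surfactant (SMILES)."""

    surfactant_id: str
    hydrophilic: str
    hydrophobic: str


@dataclass
class SurfactantEntry:
    """One surfactant: metadata, optional fragments and curated descriptor values.

    ``charge_class`` is metadata attached to the row — never derived from the
    structure (nominal charge is deliberately not a descriptor; the map encodes
    charge continuously through the Hirshfeld-charge descriptor instead).
    """

    surfactant_id: str
    charge_class: str
    designer_flag: bool = False
    fragments: Optional[FragmentPair] = None
    curated: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge_class not in CHARGE_CLASSES:
            raise TableError(
                f"unknown charge class {self.charge_class!r} for {self.surfactant_id!r}"
            )
        for name, value in self.curated.items():
            if value is not None and not np.isfinite(value):
                raise TableError(
                    f"non-finite curated value {name}={value!r} for {self.surfactant_id!r}"
                )


@dataclass(frozen=True)
class QuantumRecord:
    """Externally computed quantum descriptors for one surfactant.

    Units: orbital energies in eV, dipoles in Debye, solvation free energy in
    kcal/mol, Hirshfeld charge in elementary charge units. Only finiteness is
    required; no sign convention is assumed.
    """

    surfactant_id: str
    homo_energy: float
    lumo_energy: float
    hydrophilic_dipole: float
    hydrophobic_dipole: float
    dG_solv_hydrophilic: float
    hirshfeld_min_charge: float


def default_descriptor_specs() -> list[DescriptorSpec]:
    """The canonical descriptor layout.

    Mirrors the published descriptor list: three literature-curated micellar
    properties (range-valued ones encoded as a single midpoint column), four
    measured emulsion properties (contact angles as two columns), and the
    molecular block of fragment-derived and quantum descriptors. The schema is
    column-count-agnostic; this is the default, not a constraint.
    """
    lit = [("cmc", "micellar"), ("aggregation_number", "micellar"), ("micelle_size", "micellar")]
    meas = [
        ("contact_angle_left", "emulsion"),
        ("contact_angle_right", "emulsion"),
        ("zeta_potential", "emulsion"),
        ("hlb", "emulsion"),
    ]
    computed = [
        "hydrophilic_rotatable_bonds",
        "hydrophobic_rotatable_bonds",
        "hydrophilic_longest_chain",
        "hydrophobic_longest_chain",
        "hydrophilic_volume",
        "hydrophobic_volume",
        "hydrophilic_surface_area",
        "hydrophobic_surface_area",
        "hydrophilic_oh_count",
        "hydrophobic_cis_double_bonds",
        "hydrophilic_dG_solv",
        "hydrophilic_dipole",
        "hydrophilic_homo",
        "hydrophilic_lumo",
        "hydrophobic_dipole",
        "hirshfeld_min_charge",
    ]
    specs = [DescriptorSpec(n, b, "literature") for n, b in lit]
    specs += [DescriptorSpec(n, b, "measured") for n, b in meas]
    specs += [DescriptorSpec(n, "molecular", "computed") for n in computed]
    return specs


@dataclass
class DescriptorTable:
    """Surfactants × descriptors matrix with missing-value mask and metadata.

    ``values`` is float64 with ``nan`` at unobserved cells; ``mask`` is True at
    observed cells. ``row_meta`` is a DataFrame with columns
    ``id, charge_class, designer`` aligned positionally with the matrix rows;
    ``col_meta`` is one :class:`DescriptorSpec` per column.
    """

    values: np.ndarray
    mask: np.ndarray
    row_meta: pd.DataFrame
    col_meta: Sequence[DescriptorSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.col_meta = list(self.col_meta)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape
        if self.mask.shape != (n, p):
            raise TableError(f"mask shape {self.mask.shape} != values shape {(n, p)}")
        if len(self.col_meta) != p:
            raise TableError(f"{len(self.col_meta)} column specs for {p} columns")
        if len(self.row_meta) != n:
            raise TableError(f"{len(self.row_meta)} metadata rows for {n} matrix rows")
        for col in ("id", "charge_class", "designer"):
            if col not in self.row_meta.columns:
                raise TableError(f"row metadata lacks required column {col!r}")
        ids = self.row_meta["id"]
        dup = ids[ids.duplicated()]
        if len(dup):
            raise TableError(f"duplicate surfactant id(s): {sorted(set(dup))}")
        names = [s.name for s in self.col_meta]
        if len(set(names)) != len(names):
            raise TableError("duplicate descriptor names in column metadata")
        if not np.all(np.isfinite(self.values[self.mask])):
            bad = np.argwhere(~np.isfinite(self.values) & self.mask)[0]
            raise TableError(
                f"non-finite observed value at row {bad[0]} ({ids.iloc[bad[0]]!r}), "
                f"column {names[bad[1]]!r}"
            )
    def check_observations(self) -> None:
        """Enforce the fitting-substrate invariants: every column needs >= 2
        observed values and every row >= 1. Newly assembled tables may be
        sparser than this; loading and fitting reject them with this check."""
        if self.n_rows == 0:  # degenerate but legal (e.g. drop rule removed every row)
            return
        names = self.descriptor_names
        col_obs = self.mask.sum(axis=0)
        if np.any(col_obs < 2):
            j = int(np.argmin(col_obs))
            raise TableError(
                f"column {names[j]!r} has {col_obs[j]} observed value(s); need >= 2"
            )
        row_obs = self.mask.sum(axis=1)
        if np.any(row_obs < 1):
            i = int(np.argmin(row_obs))
            raise TableError(f"row {self.ids[i]!r} has no observed values")

    # -- convenience --------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def ids(self) -> list[str]:
        return list(self.row_meta["id"])

    @property
    def descriptor_names(self) -> list[str]:
        return [s.name for s in self.col_meta]

    def missing_fraction(self) -> float:
        """Fraction of unobserved cells (0.105 for the 263/2500 table)."""
        return float((~self.mask).sum()) / self.mask.size

    def column_indices(self, sources: Iterable[str]) -> np.ndarray:
        """Positional indices of columns whose spec source is in ``sources``."""
        srcs = set(sources)
        return np.array([j for j, s in enumerate(self.col_meta) if s.source in srcs], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id/class/designer metadata followed by descriptors."""
        frame = self.row_meta.reset_index(drop=True).copy()
        data = pd.DataFrame(
            np.where(self.mask, self.values, np.nan), columns=self.descriptor_names
        )
        return pd.concat([frame, data], axis=1)

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            self.values.copy(),
            self.mask.copy(),
            self.row_meta.reset_index(drop=True).copy(),
            list(self.col_meta),
        )
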