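"""File formats for descriptor tables, fitted models and run configuration.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, header row required;
missing = empty cell or the token ``NA``. Descriptor tables are written with
full float precision so a write→read round trip is bit-exact. Column
provenance (block/source per descriptor) travels in a companion
``<table>.columns.json`` next to the CSV; when it is absent, columns are
classified by name against the default descriptor specs and otherwise assumed
computed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mdpca import PCAModel, ScalingParams
from .table import DescriptorSpec, DescriptorTable, TableError, default_descriptor_specs

_META_COLUMNS = ["surfactant_id", "class", "designer"]
NA_TOKENS = ["", "NA"]


def _columns_sidecar(path) -> Path:
    return Path(str(path) + ".columns.json")


def write_descriptor_table(table: DescriptorTable, path) -> None:
    """Write the table CSV (+ companion column-metadata JSON)."""
    frame = table.to_frame().rename(columns={"id": "surfactant_id", "charge_class": "class"})
    frame["designer"] = frame["designer"].astype(int)
    frame.to_csv(path, index=False, float_format="%.17g", na_rep="")
    specs = [{"name": s.name, "block": s.block, "source": s.source} for s in table.col_meta]
    _columns_sidecar(path).write_text(json.dumps(specs, indent=2) + "\n", encoding="utf-8")


def _specs_for(names: Sequence[str], path, specs: Optional[Sequence[DescriptorSpec]]) -> list[DescriptorSpec]:
    if specs is not None:
        by_name = {s.name: s for s in specs}
    elif _columns_sidecar(path).exists():
        raw = json.loads(_columns_sidecar(path).read_text(encoding="utf-8"))
        by_name = {d["name"]: DescriptorSpec(d["name"], d["block"], d["source"]) for d in raw}
    else:
        by_name = {s.name: s for s in default_descriptor_specs()}
    out = []
    for name in names:
        out.append(by_name.get(name, DescriptorSpec(name, "molecular", "computed")))
    return out


def read_descriptor_table(
    path,
    specs: Optional[Sequence[DescriptorSpec]] = None,
    rename_map: Optional[dict] = None,
) -> DescriptorTable:
    """Read a descriptor-table CSV; validates all table invariants.

    ``rename_map`` renames raw CSV headers to descriptor-spec names before
    classification (for externally deposited tables with different headers).
    """
    frame = pd.read_csv(
        path, keep_default_na=False, na_values=NA_TOKENS, float_precision="round_trip"
    )
    for col in _META_COLUMNS:
        if col not in frame.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    if rename_map:
        frame = frame.rename(columns=rename_map)
    ids = frame["surfactant_id"].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        first = dup.iloc[0]
        line = int(dup.index[0]) + 2  # header is line 1
        raise TableError(f"{path}: duplicate surfactant id {first!r} (line {line})")
    desc_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    try:
        values = frame[desc_cols].apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise TableError(f"{path}: non-numeric descriptor cell ({exc})") from exc
    mask = ~np.isnan(values)
    row_meta = pd.DataFrame(
        {
            "id": ids,
            "charge_class": frame["class"].astype(str),
            "designer": frame["designer"].astype(int).astype(bool),
        }
    )
    col_meta = _specs_for(desc_cols, path, specs)
    try:
        table = DescriptorTable(values, mask, row_meta, col_meta)
        table.check_observations()
        return table
    except TableError as exc:
        raise TableError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# fragment / curated / quantum input CSVs
# ---------------------------------------------------------------------------

def read_fragments_csv(path):
    """Fragment CSV -> list of (SurfactantEntry, FragmentPair-attached) entries.

    Columns: surfactant_id, class, designer (0/1), hydrophilic_smiles,
    hydrophobic_smiles. Empty SMILES cells mean no fragments for that row.
    """
    from .table import FragmentPair, SurfactantEntry

    frame = pd.read_csv(path, keep_default_na=False, na_values=NA_TOKENS)
    required = ["surfactant_id", "class", "designer", "hydrophilic_smiles", "hydrophobic_smiles"]
    for col in required:
        if col not in frame.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    entries = []
    for _, row in frame.iterrows():
        sid = str(row["surfactant_id"])
        fragments = None
        if pd.notna(row["hydrophilic_smiles"]) and pd.notna(row["hydrophobic_smiles"]):
            fragments = FragmentPair(sid, str(row["hydrophilic_smiles"]), str(row["hydrophobic_smiles"]))
        entries.append(
            SurfactantEntry(
                surfactant_id=sid,
                charge_class=str(row["class"]),
                designer_flag=bool(int(row["designer"])),
                fragments=fragments,
            )
        )
    return entries


def read_named_values_csv(path) -> dict[str, dict[str, float]]:
    """Generic id → {descriptor: value} reader for curated/quantum CSVs."""
    frame = pd.read_csv(path, keep_default_na=False, na_values=NA_TOKENS)
    if "surfactant_id" not in frame.columns:
        raise TableError(f"{path}: missing required column 'surfactant_id'")
    out: dict[str, dict[str, float]] = {}
    for _, row in frame.iterrows():
        sid = str(row["surfactant_id"])
        if sid in out:
            raise TableError(f"{path}: duplicate surfactant id {sid!r}")
        out[sid] = {
            col: float(row[col])
            for col in frame.columns
            if col != "surfactant_id" and pd.notna(row[col])
        }
    return out


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def write_model_json(model: PCAModel, path) -> None:
    payload = {
        "method": model.method,
        "k": model.k,
        "seed": model.seed,
        "scores": model.scores.tolist(),
        "loadings": model.loadings.tolist(),
        "r2_cumulative": np.asarray(model.r2_cumulative).tolist(),
        "converged": bool(model.converged),
        "iterations": int(model.iterations),
        "scaling": None
        if model.scaling is None
        else {"mean": model.scaling.mean.tolist(), "sd": model.scaling.sd.tolist()},
        "extras": _jsonable_extras(model.extras),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def _jsonable_extras(extras: dict) -> dict:
    out = {}
    for key, value in extras.items():
        if isinstance(value, np.ndarray):
            out[key] = value.tolist()
        elif isinstance(value, dict):
            out[key] = _jsonable_extras(value)
        elif isinstance(value, (np.floating, np.integer)):
            out[key] = value.item()
        else:
            out[key] = value
    return out


def read_model_json(path) -> PCAModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    scaling = payload.get("scaling")
    extras = payload.get("extras", {})
    if "network" in extras and extras["network"] is not None:
        extras["network"] = {k: np.asarray(v, dtype=float) for k, v in extras["network"].items()}
    return PCAModel(
        method=payload["method"],
        k=int(payload["k"]),
        scores=np.asarray(payload["scores"], dtype=float),
        loadings=np.asarray(payload["loadings"], dtype=float),
        scaling=None
        if scaling is None
        else ScalingParams(
            mean=np.asarray(scaling["mean"], dtype=float),
            sd=np.asarray(scaling["sd"], dtype=float),
        ),
        r2_cumulative=np.asarray(payload["r2_cumulative"], dtype=float),
        converged=bool(payload["converged"]),
        iterations=int(payload["iterations"]),
        seed=payload.get("seed"),
        extras=extras,
    )
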