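"""Readers and writers for screen tables.

Plate layouts and per-image measurement tables are comma-delimited CSV with a
header row (UTF-8). Interaction and annotation tables accept tab or comma
(delimiter sniffed from the header line), mirroring the loosely specified
flat-file exports such tables usually come from. Gene and protein symbols are
matched case-insensitively and stored uppercase.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx
import pandas as pd

from .exceptions import (
    IntegrityError,
    SchemaError,
    ValidationError,
    VocabularyError,
)

# ---------------------------------------------------------------------------
# Controlled vocabularies

SAMPLE = "sample"
POSITIVE_CONTROL = "positive_control"
NEGATIVE_CONTROL_UNTREATED = "negative_control_untreated"
NEGATIVE_CONTROL_LIPO = "negative_control_lipo"
EMPTY = "empty"

ROLES = frozenset(
    {SAMPLE, POSITIVE_CONTROL, NEGATIVE_CONTROL_UNTREATED, NEGATIVE_CONTROL_LIPO, EMPTY}
)
NEGATIVE_CONTROL_ROLES = frozenset({NEGATIVE_CONTROL_UNTREATED, NEGATIVE_CONTROL_LIPO})
CONTROL_ROLES = frozenset({POSITIVE_CONTROL}) | NEGATIVE_CONTROL_ROLES

#: Typed-edge vocabulary. The numeric codes follow the usual rendering of such
#: networks: (1) interacting proteins, (2) interacting phosphoproteins,
#: (3) substrates, (4) substrates that are also interacting phosphoproteins.
RELATION_CLASSES = {
    "interacting": 1,
    "interacting_phospho": 2,
    "substrate": 3,
    "substrate_phospho": 4,
}
RELATION_NAMES = {v: k for k, v in RELATION_CLASSES.items()}

LAYOUT_COLUMNS = ["plate_id", "well_id", "gene_symbol", "duplex_id", "role"]
MEASUREMENT_COLUMNS = [
    "plate_id",
    "well_id",
    "image_index",
    "dapi_count",
    "dapi_intensity",
    "ph3_count",
]
INTERACTION_COLUMNS = ["source", "target", "relation"]
ANNOTATION_COLUMNS = ["gene_symbol", "term_id", "term_name", "namespace"]
HIT_TABLE_COLUMNS = ["gene_symbol", "mi", "log2_mi", "zscore", "call", "group"]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# Plate layouts


def read_layout(path) -> pd.DataFrame:
    """Read and validate a plate-layout CSV.

    Returns a DataFrame with columns ``plate_id, well_id, gene_symbol,
    duplex_id, role``. ``(plate_id, well_id)`` must be unique, every
    ``sample`` well must name a gene, and roles must belong to the
    controlled vocabulary; control and empty wells need no gene.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, LAYOUT_COLUMNS, path)
    df = df[LAYOUT_COLUMNS].copy()
    for col in LAYOUT_COLUMNS:
        df[col] = df[col].str.strip()
    bad_roles = sorted(set(df["role"]) - ROLES)
    if bad_roles:
        raise VocabularyError(f"{path}: unknown role label(s): {', '.join(bad_roles)}")
    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        first = df.loc[dup, ["plate_id", "well_id"]].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate well {first['plate_id']},{first['well_id']}"
        )
    missing_gene = (df["role"] == SAMPLE) & (df["gene_symbol"] == "")
    if missing_gene.any():
        w = df.loc[missing_gene].iloc[0]
        raise IntegrityError(
            f"{path}: sample well {w['plate_id']},{w['well_id']} has no gene_symbol"
        )
    df["gene_symbol"] = df["gene_symbol"].str.upper()
    return df


def write_layout(layout: pd.DataFrame, path) -> None:
    layout.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Measurements


def read_measurements(
    path,
    layout: pd.DataFrame | None = None,
    images_per_well: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a per-image measurement CSV.

    If a layout is given, records are joined to it on ``(plate_id, well_id)``
    and gain the ``gene_symbol``, ``duplex_id`` and ``role`` columns.
    Records for wells absent from the layout are returned in a rejects table
    (with a ``reject_reason`` column), never silently dropped.

    Returns ``(records, rejects)``.
    """
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    df = df[MEASUREMENT_COLUMNS].copy()
    for col in ("plate_id", "well_id"):
        df[col] = df[col].astype(str).str.strip()
    for col in ("image_index", "dapi_count", "ph3_count"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise ValidationError(f"{path}: negative value in column '{col}'")
        if (vals != vals.round()).any():
            raise ValidationError(f"{path}: non-integer value in column '{col}'")
        df[col] = vals.astype(int)
    if (df["image_index"] < 1).any():
        raise ValidationError(f"{path}: image_index must be >= 1")
    if images_per_well is not None and (df["image_index"] > images_per_well).any():
        raise ValidationError(
            f"{path}: image_index exceeds configured images per well ({images_per_well})"
        )
    intensity = pd.to_numeric(df["dapi_intensity"], errors="raise")
    if (intensity < 0).any():
        raise ValidationError(f"{path}: negative dapi_intensity")
    df["dapi_intensity"] = intensity.astype(float)

    if layout is None:
        return df, df.iloc[0:0].assign(reject_reason=pd.Series(dtype=str))

    merged = df.merge(
        layout[["plate_id", "well_id", "gene_symbol", "duplex_id", "role"]],
        on=["plate_id", "well_id"],
        how="left",
        indicator=True,
    )
    unknown = merged["_merge"] == "left_only"
    rejects = (
        merged.loc[unknown, MEASUREMENT_COLUMNS]
        .assign(reject_reason="well not in layout")
        .reset_index(drop=True)
    )
    records = merged.loc[~unknown].drop(columns="_merge").reset_index(drop=True)
    return records, rejects


def write_measurements(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Interactions


def read_interactions(path, allow_self_loops: bool = False) -> pd.DataFrame:
    """Read a typed interaction table (TSV or CSV, sniffed).

    Columns ``source, target, relation``; the relation must be one of the
    four-class vocabulary (:data:`RELATION_CLASSES`). Self-loops are rejected
    unless ``allow_self_loops`` is set.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    _require_columns(df, INTERACTION_COLUMNS, path)
    df = df[INTERACTION_COLUMNS].copy()
    df["source"] = df["source"].str.strip().str.upper()
    df["target"] = df["target"].str.strip().str.upper()
    df["relation"] = df["relation"].str.strip().str.lower()
    bad = sorted(set(df["relation"]) - set(RELATION_CLASSES))
    if bad:
        raise VocabularyError(f"{path}: unknown relation label(s): {', '.join(bad)}")
    loops = df["source"] == df["target"]
    if loops.any() and not allow_self_loops:
        g = df.loc[loops, "source"].iloc[0]
        raise IntegrityError(f"{path}: self-loop on {g} (pass allow_self_loops to keep)")
    return df.reset_index(drop=True)


def write_interactions(interactions: pd.DataFrame, path, sep: str = "\t") -> None:
    interactions.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(path) -> pd.DataFrame:
    """Read a flat gene -> term annotation table (TSV or CSV, sniffed)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    df = df[ANNOTATION_COLUMNS].copy()
    df["gene_symbol"] = df["gene_symbol"].str.strip().str.upper()
    if (df["namespace"].str.strip() == "").any():
        raise IntegrityError(f"{path}: annotation row without a namespace tag")
    dup = df.duplicated(subset=["gene_symbol", "term_id"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"{path}: duplicate (gene, term) pair {r['gene_symbol']},{r['term_id']}"
        )
    return df


def write_annotations(annotations: pd.DataFrame, path, sep: str = "\t") -> None:
    annotations.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Hit tables and per-gene MI tables


def write_hit_table(hits: pd.DataFrame, path) -> None:
    cols = [c for c in HIT_TABLE_COLUMNS if c in hits.columns]
    cols += [c for c in hits.columns if c not in cols]
    hits[cols].to_csv(path, index=False)


def read_mi_table(path) -> tuple[pd.DataFrame, str]:
    """Read a summarized MI table for hit calling.

    Accepts either per-gene granularity (one row per gene) or per-duplex
    granularity (a ``duplex_id`` column present). Requires ``gene_symbol``
    plus at least one of ``log2_mi`` / ``mi``; ``log2_mi`` is derived from
    ``mi`` if absent. Returns ``(table, granularity)`` where granularity is
    ``"gene"`` or ``"duplex"``.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["gene_symbol"], path)
    if "log2_mi" not in df.columns:
        if "mi" not in df.columns:
            raise SchemaError(f"{path}: need a 'log2_mi' or 'mi' column")
        import numpy as np

        df["log2_mi"] = np.log2(df["mi"].astype(float))
    df["gene_symbol"] = df["gene_symbol"].astype(str).str.upper()
    granularity = "duplex" if "duplex_id" in df.columns else "gene"
    return df, granularity


# ---------------------------------------------------------------------------
# Graph export


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edgelist(graph: nx.Graph, path) -> None:
    """Write the typed edge list as TSV (source, target, relation class/name)."""
    rows = [
        {
            "source": u,
            "target": v,
            "relation_class": data.get("relation"),
            "relation": RELATION_NAMES.get(data.get("relation"), ""),
        }
        for u, v, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "relation_class", "relation"]).to_csv(
        path, sep="\t", index=False
    )


def atomic_path(path) -> str:
    """Temporary name used for atomic writes; renamed on success."""
    return f"{path}.partial"


def finalize(path) -> None:
    os.replace(atomic_path(path), path)
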