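"""Tabular input/output and the core matrix containers.

All tables are UTF-8 tab-separated text with ``.`` decimals; missing numeric
cells are empty strings on disk and ``NaN`` in memory.  Expression and
response matrices are features-by-samples with the feature identifier in the
first column and sample identifiers in the header row.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .activity import Interaction, PathwayLibrary

logger = logging.getLogger("pathscreen")

RESULTS_COLUMNS = [
    "tissue",
    "pathway_id",
    "entity_id",
    "n_sensitive",
    "n_not_sensitive",
    "u_statistic",
    "p_value",
    "q_value",
    "direction",
    "tier",
]


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``sample_annotations`` maps a sample id to at least ``tissue`` and
    ``state`` (``tumor``/``normal``/``unknown``); extra binary flags may ride
    along.
    """

    values: pd.DataFrame
    platform: str = "unspecified"
    sample_annotations: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        _check_unique(idx, "gene")
        _check_unique(cols, "sample")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value for gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value for gene {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}"
            )
        unknown = set(self.sample_annotations) - set(cols)
        if unknown:
            raise ValueError(f"annotations for unknown samples: {sorted(unknown)}")
        for s in cols:
            self.sample_annotations.setdefault(s, {})
            self.sample_annotations[s].setdefault("tissue", "unspecified")
            self.sample_annotations[s].setdefault("state", "unknown")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissue_of(self) -> dict[str, str]:
        return {s: self.sample_annotations[s]["tissue"] for s in self.sample_ids}


@dataclass
class ResponseMatrix:
    """Entities x cell lines response values with a tissue label per line.

    ``kind`` is ``drug`` (dose-response AUC values) or ``essentiality``
    (RNAi/CRISPR fitness-effect scores).  Missing measurements are NaN.
    """

    values: pd.DataFrame
    kind: str
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("drug", "essentiality"):
            raise ValueError(f"kind must be drug|essentiality, got {self.kind!r}")
        _check_unique(self.values.index, "entity")
        _check_unique(self.values.columns, "cell line")
        missing = [c for c in self.values.columns if c not in self.tissue_of]
        if missing:
            raise ValueError(f"cell lines without a tissue label: {missing}")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ResultsTable:
    """Screen results (one row per tissue/pathway/entity test) + provenance."""

    results: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULTS_COLUMNS if c not in self.results.columns]
        if missing:
            raise ValueError(f"results table missing columns: {missing}")
        self.results = self.results[RESULTS_COLUMNS].reset_index(drop=True)
        q = self.results["q_value"].to_numpy(dtype=float)
        if len(q) and ((q < 0) | (q > 1)).any():
            raise ValueError("q_value outside [0,1]")
        bad = set(self.results["tier"]) - {"significant", "near_significant", "none"}
        if bad:
            raise ValueError(f"unknown tier values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.results)


def _check_unique(ids: Iterable, what: str) -> None:
    seen: set = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id {i!r}")
        seen.add(i)


def _read_matrix_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, what)
    _check_unique(df.columns, "sample")
    n_empty = int((df.isna() | (df == "")).to_numpy().sum())
    if n_empty:
        logger.info("%s: %d empty cells read as missing", path, n_empty)
    return df.apply(pd.to_numeric, errors="raise")


def read_expression_matrix(
    path: str | Path,
    annotations_path: str | Path | None = None,
    platform: str = "unspecified",
) -> ExpressionMatrix:
    """Read a genes x samples expression TSV plus an optional annotation table.

    The annotation table has columns ``sample``, ``tissue``, ``state`` and any
    further flag columns.  Samples missing from it get state ``unknown``.
    """
    values = _read_matrix_tsv(path, "gene")
    annotations: dict[str, dict] = {}
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
        if "sample" not in ann.columns:
            raise FormatError("annotation table needs a 'sample' column")
        for _, row in ann.iterrows():
            annotations[str(row["sample"])] = {
                k: row[k] for k in ann.columns if k != "sample" and pd.notna(row[k])
            }
        annotations = {s: a for s, a in annotations.items() if s in values.columns}
    return ExpressionMatrix(values=values, platform=platform, sample_annotations=annotations)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_pathway_library(path: str | Path, dialect: str = "pathway_table") -> PathwayLibrary:
    """Read a pathway library from the interaction-table dialect or from GMT.

    The table dialect has columns ``pathway_id``, ``pathway_name``,
    ``interaction_id``, ``gene_symbol``, ``role`` with one row per interaction
    input.  GMT import creates one single-input activator interaction per
    member gene, so pathway activity reduces to the mean UDP over the set.
    """
    if dialect == "pathway_table":
        df = pd.read_csv(path, sep="\t", dtype=str)
        needed = ["pathway_id", "pathway_name", "interaction_id", "gene_symbol", "role"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"pathway table missing columns: {missing}")
        bad = set(df["role"]) - {"activator", "inhibitor"}
        if bad:
            raise FormatError(f"unknown interaction role(s): {sorted(bad)}")
        pathways: dict[str, dict] = {}
        for (pid, iid), grp in df.groupby(["pathway_id", "interaction_id"], sort=False):
            entry = pathways.setdefault(
                pid, {"name": grp["pathway_name"].iloc[0], "interactions": []}
            )
            inputs = list(zip(grp["gene_symbol"], grp["role"]))
            entry["interactions"].append(Interaction(interaction_id=iid, inputs=inputs))
        return PathwayLibrary(
            pathways={
                pid: (e["name"], e["interactions"]) for pid, e in pathways.items()
            }
        )
    if dialect == "gmt":
        pathways = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    raise FormatError(f"malformed GMT line: {line!r}")
                name, genes = parts[1], [g for g in parts[2:] if g]
                if not genes:
                    raise FormatError(f"GMT set {parts[0]!r} has no genes")
                inters = [
                    Interaction(interaction_id=f"{parts[0]}:{g}", inputs=[(g, "activator")])
                    for g in genes
                ]
                pathways[parts[0]] = (name, inters)
        return PathwayLibrary(pathways=pathways)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_pathway_library(library: PathwayLibrary, path: str | Path) -> None:
    rows = []
    for pid, (name, interactions) in library.pathways.items():
        for inter in interactions:
            for gene, role in inter.inputs:
                rows.append((pid, name, inter.interaction_id, gene, role))
    pd.DataFrame(
        rows,
        columns=["pathway_id", "pathway_name", "interaction_id", "gene_symbol", "role"],
    ).to_csv(path, sep="\t", index=False)


def read_response_matrix(
    path: str | Path, tissue_path: str | Path, kind: str
) -> ResponseMatrix:
    """Read an entities x cell lines response TSV and the tissue lookup table.

    The tissue table has columns ``cell_line`` and ``tissue``; every cell line
    in the matrix must appear in it exactly once.
    """
    values = _read_matrix_tsv(path, "entity")
    tis = pd.read_csv(tissue_path, sep="\t", dtype=str)
    if not {"cell_line", "tissue"} <= set(tis.columns):
        raise FormatError("tissue table needs 'cell_line' and 'tissue' columns")
    _check_unique(tis["cell_line"], "cell line")
    tissue_of = dict(zip(tis["cell_line"], tis["tissue"]))
    unlabeled = [c for c in values.columns if c not in tissue_of]
    if unlabeled:
        raise ValueError(f"cell lines without a tissue label: {unlabeled}")
    return ResponseMatrix(values=values, kind=kind, tissue_of=tissue_of)


def write_response_matrix(
    matrix: ResponseMatrix, path: str | Path, tissue_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="entity")
    if tissue_path is not None:
        pd.DataFrame(
            {"cell_line": matrix.cell_line_ids,
             "tissue": [matrix.tissue_of[c] for c in matrix.cell_line_ids]}
        ).to_csv(tissue_path, sep="\t", index=False)


def write_results(table: ResultsTable, path: str | Path) -> None:
    """Write a results table as TSV in the fixed documented column order.

    Numeric columns keep >= 6 significant digits so q-values near a tier
    boundary round-trip faithfully.
    """
    table.results.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path: str | Path) -> ResultsTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("tissue", "pathway_id", "entity_id", "direction", "tier")},
    )
    if df.empty and list(df.columns) != RESULTS_COLUMNS:
        df = pd.DataFrame(columns=RESULTS_COLUMNS)
    if len(df):
        df = df.astype(
            {"n_sensitive": int, "n_not_sensitive": int,
             "u_statistic": float, "p_value": float, "q_value": float}
        )
    return ResultsTable(results=df)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance_record(paths: Mapping[str, str | Path], params: Mapping, seed: int | None) -> dict:
    return {
        "input_hashes": {k: file_sha256(p) for k, p in paths.items()},
        "parameters": dict(params),
        "seed": seed,
    }
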