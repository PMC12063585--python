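"""Readers and writers for the pipeline's file formats.

One tabular dialect throughout: tab-separated UTF-8 with '.' decimals.
Trees are newick, reports are JSON.  All writers use fixed column orders
and fixed float formatting so outputs are byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import pandas as pd

from .containers import (
    BUG_COLUMNS,
    SchemaError,
    LineageMatrix,
    validate_bug_table,
    validate_climate,
    validate_read_matrix,
)

__all__ = [
    "read_metadata", "write_metadata",
    "read_counts", "write_counts",
    "read_tree", "write_tree",
    "read_climate", "write_climate",
    "write_lineage_matrix",
    "write_partition", "read_partition",
    "write_json_report", "sha256_of",
]


# ---------------------------------------------------------------------------
# bug metadata

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a bug-metadata TSV into a validated BugRecord table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"bug_id": str, "cage_id": str, "treatment": str,
                               "stage": str, "sex": str, "origin": str},
    )
    missing = [c for c in BUG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file missing columns: {missing}")
    for col in ("alive", "symbiont_positive"):
        if df[col].dtype == object:
            bad = ~df[col].isin(["True", "False", True, False])
            if bad.any():
                raise SchemaError(
                    f"column {col!r} must be True/False; offending rows: "
                    f"{df.loc[bad, 'bug_id'].tolist()}"
                )
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
        df[col] = df[col].astype(bool)
    df["year"] = df["year"].astype(int)
    return validate_bug_table(df[list(BUG_COLUMNS)])


def write_metadata(bugs: pd.DataFrame, path: str | Path) -> None:
    validate_bug_table(bugs)
    bugs[list(BUG_COLUMNS)].to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# count matrices

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a samples x ASVs TSV (first column sample id) into an int matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric counts in column {col!r}: {exc}") from None
    validate_read_matrix(df)
    return df.astype("int64")


def write_counts(matrix: pd.DataFrame, path: str | Path) -> None:
    validate_read_matrix(matrix)
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_lineage_matrix(lm: LineageMatrix, counts_path: str | Path,
                         mapping_path: str | Path) -> None:
    """Write a lineage count table plus its asv -> lineage mapping TSV."""
    write_counts(lm.counts, counts_path)
    rows = [
        {"asv_id": asv, "lineage_id": lin,
         "is_archetype": lm.archetypes.get(lin) == asv}
        for asv, lin in sorted(lm.mapping.items())
    ]
    pd.DataFrame(rows, columns=["asv_id", "lineage_id", "is_archetype"]).to_csv(
        mapping_path, sep="\t", index=False
    )


def write_partition(partition: dict[str, list[str]], path: str | Path) -> None:
    """Write a true lineage partition as (asv_id, lineage_id) TSV."""
    rows = [
        {"asv_id": asv, "lineage_id": lin}
        for lin in sorted(partition) for asv in sorted(partition[lin])
    ]
    pd.DataFrame(rows, columns=["asv_id", "lineage_id"]).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(rec.lineage_id, []).append(rec.asv_id)
    return out


# ---------------------------------------------------------------------------
# trees

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"could not parse newick tree {path}: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = {lab for lab in labels if labels.count(lab) > 1}
    if dup:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dup)}")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
    )


# ---------------------------------------------------------------------------
# climate

def read_climate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", parse_dates=["timestamp"])
    return validate_climate(df)


def write_climate(series: pd.DataFrame, path: str | Path) -> None:
    validate_climate(series)
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# reports and digests

def write_json_report(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
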