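"""Table readers/writers and provenance sidecars.

TSV is the canonical interchange format: samples as rows, taxa as columns,
``sample_id`` as the first column.  A minimal BIOM-style JSON reader is
provided as a read-only convenience for count tables.  Taxon lineages parse
from semicolon-delimited ``class;order;family;genus`` strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("class", "order", "family", "genus")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("sample_id").to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return read_biom_json(path)
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    for col in df.columns:
        vals = df[col]
        if not np.array_equal(vals, vals.astype(int)):
            bad = vals[vals != vals.astype(int)].index[0]
            raise ValueError(f"non-integer count at ({bad}, {col})")
    return df.astype(int)


def read_biom_json(path: str | Path) -> pd.DataFrame:
    """Read a (dense or sparse) BIOM-style JSON count table.

    Expects ``rows``/``columns`` lists of ``{"id": ...}`` records and a
    ``data`` payload; rows are observations (taxa) and columns samples, per
    the BIOM convention, so the result is transposed to samples x taxa.
    """
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)), dtype=float)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=pd.Index(samples, name="sample_id"), columns=taxa)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in BIOM table")
    return df.astype(int)


def write_table(df: pd.DataFrame, path: str | Path, index_name: str | None = None) -> None:
    out = df.rename_axis(index_name) if index_name else df
    out.to_csv(path, sep="\t", index=index_name is not None)


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_qpcr(qpcr: pd.DataFrame, path: str | Path) -> None:
    qpcr.rename_axis("sample_id").to_csv(path, sep="\t")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_copy_numbers(cn: pd.DataFrame, path: str | Path) -> None:
    cn.to_csv(path, sep="\t", index=False)


def read_copy_numbers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``class;order;family;genus``; empty levels warn and stay empty."""
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) < len(LINEAGE_RANKS):
        parts += [""] * (len(LINEAGE_RANKS) - len(parts))
    if "" in parts[: len(LINEAGE_RANKS)]:
        warnings.warn(f"lineage {lineage!r} has empty level(s)", stacklevel=2)
    return dict(zip(LINEAGE_RANKS, parts[: len(LINEAGE_RANKS)]))


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    lin = taxonomy.apply(
        lambda r: ";".join([r["class"], r["order"], r["family"], r.name]), axis=1)
    pd.DataFrame({"taxon": taxonomy.index, "lineage": lin.values}).to_csv(
        path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rows = {}
    for _, rec in df.iterrows():
        d = parse_lineage(rec["lineage"])
        rows[rec["taxon"]] = {"family": d["family"], "order": d["order"],
                              "class": d["class"]}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genus"
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(run_dir: str | Path, config: dict,
                     inputs: dict[str, str | Path]) -> Path:
    """Sidecar JSON: config, input hashes, package version."""
    from qmpipe import __version__

    payload = {
        "qmpipe_version": __version__,
        "config": config,
        "inputs": {k: {"path": str(p), "sha256": file_sha256(p)}
                   for k, p in inputs.items() if Path(p).exists()},
    }
    out = Path(run_dir) / "provenance.json"
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return out
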