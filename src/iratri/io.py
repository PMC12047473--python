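"""Readers and writers for the standard single-cell / repertoire file formats.

All on-disk formats are plain text: a Matrix Market triplet for counts
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``), a TSV cell-metadata
table, a contig CSV in either the 10x (``barcode, chain, cdr3``) or AIRR
(``cell_id, locus, junction_aa``) dialect, and GMT gene-set collections.
Matrix Market files are 1-based on disk; everything in memory is 0-based.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import CountMatrix

CELL_META_COLUMNS = [
    "barcode",
    "sample_id",
    "patient_id",
    "cancer_type",
    "treatment",
    "response",
    "cell_type",
]

#: column dialects accepted for contig tables, tried in order
CONTIG_DIALECTS = {
    "10x": {"barcode": "barcode", "chain": "chain", "cdr3": "cdr3"},
    "airr": {"barcode": "cell_id", "chain": "locus", "cdr3": "junction_aa"},
}


# ---------------------------------------------------------------------------
# count matrices


def write_mtx_triplet(matrix: CountMatrix, out_dir: str) -> list[str]:
    """Write ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` under *out_dir*."""
    os.makedirs(out_dir, exist_ok=True)
    mtx = os.path.join(out_dir, "matrix.mtx")
    feats = os.path.join(out_dir, "features.tsv")
    bcs = os.path.join(out_dir, "barcodes.tsv")
    spio.mmwrite(mtx, sparse.coo_matrix(matrix.counts), field="integer")
    with open(feats, "w") as fh:
        fh.write("\n".join(map(str, matrix.genes)) + "\n")
    with open(bcs, "w") as fh:
        fh.write("\n".join(map(str, matrix.cells)) + "\n")
    return [mtx, feats, bcs]


def read_mtx_triplet(in_dir: str) -> CountMatrix:
    """Read the triplet written by :func:`write_mtx_triplet` (genes x cells)."""
    counts = sparse.csr_matrix(spio.mmread(os.path.join(in_dir, "matrix.mtx")))
    genes = _read_lines(os.path.join(in_dir, "features.tsv"))
    cells = _read_lines(os.path.join(in_dir, "barcodes.tsv"))
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(genes)} features x {len(cells)} barcodes"
        )
    return CountMatrix(genes=np.asarray(genes), cells=np.asarray(cells), counts=counts)


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# cell metadata


def write_cell_metadata(meta: pd.DataFrame, path: str) -> str:
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_cell_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata at {path} lacks columns {missing}")
    return meta


# ---------------------------------------------------------------------------
# contig tables


def read_contigs(path: str, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a contig table, auto-detecting the 10x or AIRR column dialect.

    Returns a frame with canonical columns ``barcode``, ``chain``, ``cdr3``.
    AIRR locus values (``TRA``/``TRB``) are already chain names; an explicit
    *column_map* (canonical name -> file column) overrides auto-detection.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map is None:
        for dialect in CONTIG_DIALECTS.values():
            if all(col in df.columns for col in dialect.values()):
                column_map = dialect
                break
        else:
            raise ValueError(
                f"could not detect contig dialect in {path}: columns {list(df.columns)}; "
                "pass an explicit column_map"
            )
    out = pd.DataFrame(
        {canon: df[column_map[canon]] for canon in ("barcode", "chain", "cdr3")}
    )
    return out


def write_contigs(contigs: pd.DataFrame, path: str) -> str:
    contigs.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Parse a GMT file: ``name <tab> description <tab> gene...`` per line.

    Empty tokens (e.g. from trailing tabs) are dropped; duplicate genes
    within a set are removed keeping first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = tokens[0]
            genes = [t for t in tokens[2:] if t]
            seen: set[str] = set()
            uniq = [g for g in genes if not (g in seen or seen.add(g))]
            sets[name] = uniq
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str,
              descriptions: Mapping[str, str] | None = None) -> str:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj, path: str) -> str:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
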