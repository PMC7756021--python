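"""Readers and writers for the pipeline's plain-text formats.

Matrices and tables travel as TSV (with an optional ``#``-prefixed header
carrying the run's config hash and seed), sparse single-cell counts as
MatrixMarket plus row/column annotation TSVs, gene sets as GMT, and
configurations as YAML.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from braincyto.enrichment import GeneSetCollection

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str, header_comment: str | None = None) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def read_tsv(path: str, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_mtx(counts: np.ndarray, genes: np.ndarray, cells: np.ndarray, prefix: str) -> None:
    """Sparse counts as <prefix>.mtx with <prefix>.genes.tsv / .cells.tsv."""
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts))
    pd.Series(genes, name="gene").to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
    pd.Series(cells, name="cell").to_csv(f"{prefix}.cells.tsv", sep="\t", index=False)


def read_mtx(prefix: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = np.asarray(spio.mmread(f"{prefix}.mtx").todense())
    genes = pd.read_csv(f"{prefix}.genes.tsv", sep="\t")["gene"].to_numpy()
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t")["cell"].to_numpy()
    return counts, genes, cells


def read_gmt(path: str, source: str | None = None) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets, source=source or path)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.source or "na"
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def write_yaml(obj: dict, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
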