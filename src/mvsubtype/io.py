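"""CSV readers/writers for the pipeline's tabular interfaces.

Every table carries a mandatory ``sample_id`` first column; views are joined
on it with a canonical sort so file row order never matters.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MultiviewDataset

logger = logging.getLogger(__name__)

__all__ = ["load_views", "read_table", "write_embedding", "read_genotypes_raw"]


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory sample_id column")
    return df


def load_views(paths: list[str | Path]) -> MultiviewDataset:
    """Load view tables and inner-join them on ``sample_id``.

    Rows are canonically sorted by id; views with duplicated ids are
    refused; samples missing from any view are dropped (and logged).
    """
    tables = []
    for path in paths:
        df = read_table(path)
        if df["sample_id"].duplicated().any():
            raise ValueError(f"{path}: duplicated sample_id values")
        if df.drop(columns="sample_id").isna().any().any():
            raise ValueError(f"{path}: missing values in feature columns")
        tables.append(df.set_index("sample_id").sort_index())

    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        counts = ", ".join(f"view {j}: {len(t)}" for j, t in enumerate(tables))
        raise ValueError(f"views share no sample ids ({counts})")
    for j, t in enumerate(tables):
        dropped = len(t) - len(common)
        if dropped:
            logger.warning("view %d: dropped %d samples absent elsewhere", j, dropped)

    views = [t.loc[common].to_numpy(dtype=float) for t in tables]
    names = [list(t.columns) for t in tables]
    return MultiviewDataset(
        views=views, sample_ids=list(common), feature_names=names
    )


def write_embedding(path: str | Path, sample_ids, G: np.ndarray) -> None:
    """Write an embedding matrix with component columns c1..ck."""
    df = pd.DataFrame(G, columns=[f"c{i + 1}" for i in range(G.shape[1])])
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)


def read_genotypes_raw(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read the PLINK additive text dialect (.raw-style): FID IID PAT MAT
    SEX PHENOTYPE then one 0/1/2 column per SNP. Returns (genotypes with
    sample_id column, 0/1 phenotype)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if df.columns[: len(meta)].tolist() != meta:
        raise ValueError(f"{path}: not a PLINK .raw-style file")
    snp_cols = [c for c in df.columns if c not in meta]
    genotypes = df[snp_cols].copy()
    genotypes.insert(0, "sample_id", df["IID"].astype(str))
    phenotype = (df["PHENOTYPE"].to_numpy() == 2).astype(int)
    return genotypes, phenotype
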