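"""Readers and writers for matrices, phenotypes and result tables.

Canonical on-disk form: a delimited text matrix whose first column holds
site identifiers and whose header holds subject identifiers, plus a
two-column phenotype table mapping every subject to a binary group label
(1 = diseased / case, 0 = non-diseased / control).  Tab-separated is the
canonical dialect; commas are accepted on input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import InvalidInputError, MethylationMatrix

logger = logging.getLogger("methvar")

__all__ = ["read_matrix", "write_matrix", "write_phenotype", "beta_to_m"]


def _read_table(path: str | Path) -> pd.DataFrame:
    # sniff tab vs comma from the first line
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_matrix(path: str | Path, phenotype_path: str | Path) -> MethylationMatrix:
    """Load a sites x subjects matrix and its phenotype file.

    Sites with any missing value are dropped (the drop count is logged).
    Subject columns are reordered to the phenotype file's order; every
    phenotype subject must be present in the matrix header and vice versa.
    """
    frame = _read_table(path)
    pheno = _read_table(phenotype_path)
    if pheno.shape[1] < 1:
        raise InvalidInputError("phenotype file needs a group column")
    group = pheno.iloc[:, 0]
    matrix_subjects = [str(c) for c in frame.columns]
    pheno_subjects = [str(i) for i in pheno.index]
    missing_in_matrix = sorted(set(pheno_subjects) - set(matrix_subjects))
    if missing_in_matrix:
        raise InvalidInputError(
            f"phenotype subjects absent from matrix: {missing_in_matrix[:10]}"
        )
    missing_in_pheno = sorted(set(matrix_subjects) - set(pheno_subjects))
    if missing_in_pheno:
        raise InvalidInputError(
            f"matrix subjects absent from phenotype: {missing_in_pheno[:10]}"
        )
    frame = frame[pheno.index.astype(frame.columns.dtype)]
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"non-numeric cell in matrix: {exc}") from exc
    site_ids = [str(s) for s in frame.index]
    if len(set(site_ids)) != len(site_ids):
        dupes = frame.index[frame.index.duplicated()].unique()
        raise InvalidInputError(f"duplicate site ids: {list(dupes[:10])}")
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d sites with missing values", n_dropped)
        values = values[complete]
        site_ids = [s for s, keep in zip(site_ids, complete) if keep]
    labels = group.to_numpy()
    return MethylationMatrix(values, site_ids, pheno_subjects, labels)


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write a matrix as a tab-separated site x subject table."""
    frame = pd.DataFrame(
        matrix.values, index=matrix.site_ids, columns=matrix.subject_ids
    )
    frame.index.name = "site_id"
    frame.to_csv(path, sep="\t")


def write_phenotype(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write the companion phenotype table (subject_id, group)."""
    pd.DataFrame(
        {"group": matrix.labels}, index=pd.Index(matrix.subject_ids, name="subject_id")
    ).to_csv(path, sep="\t")


def beta_to_m(beta, clip: bool = False, eps: float = 1e-6):
    """Logistic (logit, base 2) transform of methylation beta-values.

    M = log2(beta / (1 - beta)).  Beta-values must lie strictly inside
    (0, 1); with ``clip=True`` boundary values are clipped to
    [eps, 1 - eps] instead of raising.
    """
    b = np.asarray(beta, dtype=float)
    if clip:
        b = np.clip(b, eps, 1.0 - eps)
    elif ((b <= 0) | (b >= 1)).any():
        raise InvalidInputError("beta-values must lie strictly in (0, 1)")
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out
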