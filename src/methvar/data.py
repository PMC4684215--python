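"""Core containers: the sites-by-subjects matrix and per-site test results.

All tests in :mod:`methvar.variance_tests` consume a
:class:`MethylationMatrix` — a dense real matrix of methylation levels
(M-values or simulated units) with one row per CpG site and one column per
subject, plus a binary group label per subject (1 = diseased,
0 = non-diseased).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical names of the seven equal-variance tests.
TEST_NAMES = ("F", "Bartlett", "Levene", "L.trim", "BF", "PO.AD", "PO.SQ")

#: Columns of a tabular result, one row per site.
RESULT_COLUMNS = ("site_id", "test", "statistic", "df1", "df2", "p_value", "degenerate")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class MethylationMatrix:
    """Sites × subjects methylation levels with a binary group factor.

    Parameters
    ----------
    values
        Real matrix, shape ``(n_sites, n_subjects)``; no missing values.
    site_ids
        Unique identifier per row.
    subject_ids
        Identifier per column.
    labels
        Binary membership per subject: 1 = diseased, 0 = non-diseased.
        Both groups must be non-empty.
    """

    values: np.ndarray
    site_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.site_ids = list(self.site_ids)
        self.subject_ids = list(self.subject_ids)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D sites x subjects matrix")
        n_sites, n_subjects = self.values.shape
        if len(self.site_ids) != n_sites:
            raise InvalidInputError(
                f"{len(self.site_ids)} site ids for {n_sites} rows"
            )
        if len(self.subject_ids) != n_subjects:
            raise InvalidInputError(
                f"{len(self.subject_ids)} subject ids for {n_subjects} columns"
            )
        if self.labels.shape != (n_subjects,):
            raise InvalidInputError("one label per subject column is required")
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidInputError("labels must be binary (0/1)")
        if (self.labels == 1).sum() == 0 or (self.labels == 0).sum() == 0:
            raise InvalidInputError("both groups must be non-empty")
        if np.isnan(self.values).any():
            raise InvalidInputError("missing values are not allowed")
        if len(set(self.site_ids)) != n_sites:
            raise InvalidInputError("site ids must be unique")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    @property
    def n_diseased(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_control(self) -> int:
        return int((self.labels == 0).sum())

    def group_values(self, group: int) -> np.ndarray:
        """Submatrix of the given group (1 = diseased, 0 = non-diseased)."""
        return self.values[:, self.labels == group]

    def subset_sites(self, site_ids: Sequence[str]) -> "MethylationMatrix":
        """Row subset preserving the order of ``site_ids``."""
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in index]
        if missing:
            raise InvalidInputError(f"sites absent from matrix: {missing[:10]}")
        rows = [index[s] for s in site_ids]
        return MethylationMatrix(
            self.values[rows], list(site_ids), self.subject_ids, self.labels
        )

    @classmethod
    def from_arrays(
        cls, values: np.ndarray, labels: np.ndarray, prefix: str = "cg"
    ) -> "MethylationMatrix":
        """Build a matrix with auto-generated site/subject identifiers."""
        values = np.asarray(values, dtype=float)
        n_sites, n_subjects = values.shape
        site_ids = [f"{prefix}{i:06d}" for i in range(n_sites)]
        subject_ids = [f"s{j:04d}" for j in range(n_subjects)]
        return cls(values, site_ids, subject_ids, np.asarray(labels))


@dataclass
class SiteTestResult:
    """Outcome of one equal-variance test at one site."""

    statistic: float
    df1: float
    df2: float
    p_value: float
    test_name: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class DeviationMatrix:
    """Group-centred deviation scores z = |x - c| or (x - c)^2.

    ``c`` is a per-site, per-group centrality measure (mean, median or
    trimmed mean); the deviation scores carry the group structure of the
    source matrix so that downstream location tests (ANOVA F, moderated t)
    become tests of equal spread on the original scale.
    """

    z_values: np.ndarray
    labels: np.ndarray
    mode: str  # "abs" | "square"
    center: str  # "group_mean" | "group_median" | "group_trimmed_mean"
    trim_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.z_values < 0).any():
            raise InvalidInputError("deviation scores must be non-negative")


@dataclass
class FDistHyperparams:
    """Prior of the variance model s_g^2 ~ s0^2 * F(d_g, d0).

    ``d0`` is the prior degrees of freedom (may be ``inf``: all sites share
    the prior variance) and ``s0_sq`` the prior variance toward which
    per-site variances are shrunk; the same two parameters define the
    scaled inverse chi-squared law of the hierarchical simulator.  Fitting
    always returns d0 > 0; d0 = 0 is accepted as the explicit
    no-moderation limit (shrinkage weight zero, ordinary t).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise InvalidInputError("prior degrees of freedom d0 must be >= 0")
        if not self.s0_sq > 0:
            raise InvalidInputError("prior variance s0_sq must be > 0")


def result_table(
    site_ids: Sequence[str],
    test_name: str,
    statistic: np.ndarray,
    df1: np.ndarray,
    df2: np.ndarray,
    p_value: np.ndarray,
    degenerate: np.ndarray,
) -> pd.DataFrame:
    """Assemble per-site test outcomes into the canonical result table."""
    n = len(site_ids)
    table = pd.DataFrame(
        {
            "site_id": list(site_ids),
            "test": test_name,
            "statistic": np.broadcast_to(np.asarray(statistic, float), (n,)).copy(),
            "df1": np.broadcast_to(np.asarray(df1, float), (n,)).copy(),
            "df2": np.broadcast_to(np.asarray(df2, float), (n,)).copy(),
            "p_value": np.broadcast_to(np.asarray(p_value, float), (n,)).copy(),
            "degenerate": np.broadcast_to(np.asarray(degenerate, bool), (n,)).copy(),
        }
    )
    bad = ~(
        ((table["p_value"] >= 0) & (table["p_value"] <= 1)) | table["p_value"].isna()
    )
    if bad.any():
        raise InvalidInputError("computed p-values escaped [0, 1]")
    return table
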