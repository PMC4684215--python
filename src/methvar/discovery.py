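"""Two-cohort discovery / validation workflow for differential variability.

A discovery cohort is screened with one of the equal-variance tests under
Benjamini-Hochberg FDR control; the significant sites are then re-tested
in an independent validation cohort, where an unadjusted p-value below
alpha counts as validated.  Because the classical F and Bartlett tests are
outlier-sensitive, the workflow also flags sites containing 1.5 x IQR
outliers within either group and reports how many significant sites carry
outliers in the discovery cohort alone and in both cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import InvalidInputError, MethylationMatrix, TEST_NAMES
from .variance_tests import run_test

__all__ = [
    "DiscoveryReport",
    "bh_adjust",
    "discover",
    "validate",
    "iqr_outlier_sites",
    "outlier_overlap",
    "discovery_validation_report",
]


@dataclass
class DiscoveryReport:
    """Per-test summary of the discovery/validation workflow."""

    test_name: str
    n_significant: int
    significant_site_ids: list[str]
    n_validated: int
    proportion_validated: float  # NaN when nothing was discovered
    n_outlier_sites_discovery: int
    n_outlier_sites_both: int

    def __post_init__(self) -> None:
        if self.n_validated > self.n_significant:
            raise InvalidInputError("validated count exceeds discovered count")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def discover(
    matrix: MethylationMatrix,
    test_name: str,
    fdr_level: float = 0.05,
    trim_fraction: float = 0.10,
) -> list[str]:
    """Sites whose BH-adjusted p-value falls below ``fdr_level``."""
    table = run_test(matrix, test_name, trim_fraction=trim_fraction)
    adjusted = bh_adjust(table["p_value"].to_numpy())
    keep = adjusted < fdr_level
    return [s for s, k in zip(table["site_id"], keep) if k]


def validate(
    sites: Sequence[str],
    validation_matrix: MethylationMatrix,
    test_name: str,
    alpha: float = 0.05,
    trim_fraction: float = 0.10,
) -> tuple[list[str], float]:
    """Re-test discovered sites in the validation cohort.

    A site is validated when its unadjusted p-value is below ``alpha``.
    Returns the validated subset and the validated proportion (NaN when
    ``sites`` is empty).
    """
    sites = list(sites)
    if not sites:
        return [], float("nan")
    subset = validation_matrix.subset_sites(sites)  # errors on missing ids
    table = run_test(subset, test_name, trim_fraction=trim_fraction)
    keep = table["p_value"].to_numpy() < alpha
    validated = [s for s, k in zip(table["site_id"], keep) if k]
    return validated, len(validated) / len(sites)


def iqr_outlier_sites(
    matrix: MethylationMatrix, quantile_method: str = "linear"
) -> np.ndarray:
    """Flag sites containing a 1.5 x IQR outlier within either group.

    A subject's value is an outlier when it lies strictly below
    Q1 - 1.5*IQR or strictly above Q3 + 1.5*IQR of its own group at that
    site.  ``quantile_method`` is passed to ``numpy.quantile`` (default:
    linear interpolation between order statistics).
    """
    flagged = np.zeros(matrix.n_sites, dtype=bool)
    for group in (0, 1):
        x = matrix.group_values(group)
        q1 = np.quantile(x, 0.25, axis=1, method=quantile_method)
        q3 = np.quantile(x, 0.75, axis=1, method=quantile_method)
        iqr = q3 - q1
        low = (q1 - 1.5 * iqr)[:, None]
        high = (q3 + 1.5 * iqr)[:, None]
        flagged |= ((x < low) | (x > high)).any(axis=1)
    return flagged


def outlier_overlap(
    discovery_matrix: MethylationMatrix,
    validation_matrix: MethylationMatrix,
    significant_sites: Sequence[str],
    quantile_method: str = "linear",
) -> tuple[int, int]:
    """Outlier-site counts among significant sites.

    Returns ``(n_discovery, n_both)``: significant sites flagged by the
    IQR rule in the discovery cohort, and the subset of those also flagged
    in the validation cohort.
    """
    sites = list(significant_sites)
    if not sites:
        return 0, 0
    disc = discovery_matrix.subset_sites(sites)
    val = validation_matrix.subset_sites(sites)
    disc_flag = iqr_outlier_sites(disc, quantile_method)
    val_flag = iqr_outlier_sites(val, quantile_method)
    n_discovery = int(disc_flag.sum())
    n_both = int((disc_flag & val_flag).sum())
    return n_discovery, n_both


def discovery_validation_report(
    discovery_matrix: MethylationMatrix,
    validation_matrix: MethylationMatrix,
    tests: Sequence[str] = TEST_NAMES,
    fdr_level: float = 0.05,
    alpha: float = 0.05,
    trim_fraction: float = 0.10,
) -> pd.DataFrame:
    """Run the full workflow for several tests; one report row per test.

    Columns mirror the canonical summary tables: discovered count,
    validated count and proportion, and outlier-site counts/proportions in
    the discovery cohort and in both cohorts.
    """
    rows = []
    for test_name in tests:
        sig = discover(discovery_matrix, test_name, fdr_level, trim_fraction)
        validated, prop = validate(
            sig, validation_matrix, test_name, alpha, trim_fraction
        )
        n_out_disc, n_out_both = outlier_overlap(
            discovery_matrix, validation_matrix, sig
        )
        report = DiscoveryReport(
            test_name,
            len(sig),
            sig,
            len(validated),
            prop,
            n_out_disc,
            n_out_both,
        )
        rows.append(
            {
                "test": test_name,
                "nCpG": report.n_significant,
                "nCpG.validated": report.n_validated,
                "proportion": report.proportion_validated,
                "nOutlier.discovery": n_out_disc,
                "pOutlier.discovery": (
                    n_out_disc / len(sig) if sig else float("nan")
                ),
                "nOutlier.both": n_out_both,
                "pOutlier.both": (
                    n_out_both / n_out_disc if n_out_disc else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
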