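"""The seven tests of equal variance between two groups of subjects.

Given per-site methylation levels ``x_ik`` (subject *i*, group *k*) the null
hypothesis at each CpG site is H0: sigma_d^2 = sigma_n^2 against a two-sided
alternative, where the two sigmas are the diseased- and non-diseased-group
variances.  The tests are:

``F``
    ratio of the two unbiased sample variances against an F(m_d-1, m_n-1)
    law, p-value formed by doubling the smaller tail.
``Bartlett``
    the classical chi-squared statistic on log pooled/group variances,
    defined for k >= 2 groups.
``Levene`` / ``L.trim`` / ``BF``
    one-way ANOVA F on absolute deviations from the within-group mean,
    trimmed mean, or median respectively.
``PO.AD`` / ``PO.SQ``
    empirical-Bayes moderated t on absolute or squared deviations from the
    within-group mean: per-site residual variances of the deviation scores
    are shrunk toward a prior fitted across all sites before forming the
    two-sample t statistic (the DiffVar construction).

All seven run vectorised over an entire sites x subjects matrix; scalar
entry points are provided for single-site use.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .data import (
    DeviationMatrix,
    FDistHyperparams,
    InvalidInputError,
    MethylationMatrix,
    SiteTestResult,
    TEST_NAMES,
    result_table,
)

__all__ = [
    "f_test",
    "bartlett_test",
    "center_deviations",
    "trimmed_mean",
    "anova_f_on_deviations",
    "fit_fdist",
    "squeeze_var",
    "moderated_t_table",
    "po_test",
    "run_test",
]


# ---------------------------------------------------------------------------
# F test
# ---------------------------------------------------------------------------

def _f_arrays(x_d: np.ndarray, x_n: np.ndarray):
    """Vectorised variance-ratio test; rows are sites."""
    m_d, m_n = x_d.shape[1], x_n.shape[1]
    s2_d = x_d.var(axis=1, ddof=1)
    s2_n = x_n.var(axis=1, ddof=1)
    degenerate = (s2_d == 0) & (s2_n == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(degenerate, 0.0, s2_d / np.where(s2_n == 0, np.nan, s2_n))
    stat = np.where((s2_n == 0) & ~degenerate, np.inf, stat)
    df1, df2 = float(m_d - 1), float(m_n - 1)
    cdf = stats.f.cdf(stat, df1, df2)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, 1.0 - cdf))
    p = np.where(degenerate, 1.0, p)
    stat = np.where(degenerate, 0.0, stat)
    return stat, np.full_like(stat, df1), np.full_like(stat, df2), p, degenerate


def f_test(group_d: Sequence[float], group_n: Sequence[float]) -> SiteTestResult:
    """Two-sided variance-ratio F test for a single site.

    The statistic is the unbiased sample variance of the diseased group over
    that of the non-diseased group; orientation does not affect the doubled
    two-sided p-value.
    """
    x_d = np.atleast_2d(np.asarray(group_d, dtype=float))
    x_n = np.atleast_2d(np.asarray(group_n, dtype=float))
    if x_d.shape[1] < 2 or x_n.shape[1] < 2:
        raise InvalidInputError("each group needs at least 2 observations")
    stat, df1, df2, p, degen = _f_arrays(x_d, x_n)
    return SiteTestResult(
        float(stat[0]), float(df1[0]), float(df2[0]), float(p[0]), "F", bool(degen[0])
    )


# ---------------------------------------------------------------------------
# Bartlett's test
# ---------------------------------------------------------------------------

def _bartlett_arrays(groups: list[np.ndarray]):
    """Vectorised classical Bartlett statistic; each element rows=sites."""
    k = len(groups)
    n_i = np.array([g.shape[1] for g in groups], dtype=float)
    big_n = n_i.sum()
    s2 = np.stack([g.var(axis=1, ddof=1) for g in groups])  # (k, sites)
    sp2 = ((n_i - 1)[:, None] * s2).sum(axis=0) / (big_n - k)
    degenerate = sp2 == 0
    correction = 1.0 + (np.sum(1.0 / (n_i - 1)) - 1.0 / (big_n - k)) / (3.0 * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (
            (big_n - k) * np.log(sp2) - ((n_i - 1)[:, None] * np.log(s2)).sum(axis=0)
        ) / correction
    stat = np.where(degenerate, 0.0, stat)
    # a single constant group with positive pooled variance gives +inf
    stat = np.where(np.isnan(stat), np.inf, stat)
    p = stats.chi2.sf(stat, k - 1)
    p = np.where(degenerate, 1.0, p)
    df1 = np.full_like(stat, float(k - 1))
    return stat, df1, np.full_like(stat, np.inf), p, degenerate


def bartlett_test(groups: Sequence[Sequence[float]]) -> SiteTestResult:
    """Bartlett's chi-squared test of equal variances for k >= 2 groups."""
    if len(groups) < 2:
        raise InvalidInputError("Bartlett's test needs at least 2 groups")
    arrays = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if any(a.shape[1] < 2 for a in arrays):
        raise InvalidInputError("each group needs at least 2 observations")
    stat, df1, df2, p, degen = _bartlett_arrays(arrays)
    return SiteTestResult(
        float(stat[0]), float(df1[0]), float(df2[0]), float(p[0]), "Bartlett",
        bool(degen[0]),
    )


# ---------------------------------------------------------------------------
# Deviation scores
# ---------------------------------------------------------------------------

def trimmed_mean(values: Sequence[float], trim_fraction: float) -> float:
    """Mean after dropping floor(trim_fraction * n) values from each tail."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty vector")
    if not 0.0 <= trim_fraction < 0.5:
        raise InvalidInputError("trim_fraction must lie in [0, 0.5)")
    cut = int(trim_fraction * x.size)
    if x.size - 2 * cut <= 0:
        raise InvalidInputError("trimming removed every value")
    return float(stats.trim_mean(x, trim_fraction))


def _group_center(x: np.ndarray, center: str, trim_fraction: float) -> np.ndarray:
    if center == "group_mean":
        return x.mean(axis=1, keepdims=True)
    if center == "group_median":
        return np.median(x, axis=1, keepdims=True)
    if center == "group_trimmed_mean":
        if not 0.0 <= trim_fraction < 0.5:
            raise InvalidInputError("trim_fraction must lie in [0, 0.5)")
        if x.shape[1] - 2 * int(trim_fraction * x.shape[1]) <= 0:
            raise InvalidInputError("trimming removed every value")
        return np.asarray(stats.trim_mean(x, trim_fraction, axis=1))[:, None]
    raise InvalidInputError(f"unknown center {center!r}")


def center_deviations(
    matrix: MethylationMatrix,
    mode: str = "abs",
    center: str = "group_mean",
    trim_fraction: float = 0.0,
) -> DeviationMatrix:
    """Transform x_ik into deviation scores z_ik = |x_ik - c| or (x_ik - c)^2.

    ``c`` is the within-group mean, median, or trimmed mean of the site.
    """
    if mode not in ("abs", "square"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    z = np.empty_like(matrix.values)
    for group in (0, 1):
        cols = matrix.labels == group
        x = matrix.values[:, cols]
        dev = x - _group_center(x, center, trim_fraction)
        z[:, cols] = np.abs(dev) if mode == "abs" else dev**2
    return DeviationMatrix(z, matrix.labels, mode, center, trim_fraction)


# ---------------------------------------------------------------------------
# One-way ANOVA F on deviation scores (Levene family)
# ---------------------------------------------------------------------------

def _anova_f_arrays(z: np.ndarray, labels: np.ndarray):
    """Two-group one-way ANOVA F per row of z."""
    z_d, z_n = z[:, labels == 1], z[:, labels == 0]
    m_d, m_n = z_d.shape[1], z_n.shape[1]
    big_n = m_d + m_n
    mean_d = z_d.mean(axis=1)
    mean_n = z_n.mean(axis=1)
    grand = (m_d * mean_d + m_n * mean_n) / big_n
    ssb = m_d * (mean_d - grand) ** 2 + m_n * (mean_n - grand) ** 2
    ssw = ((z_d - mean_d[:, None]) ** 2).sum(axis=1) + (
        (z_n - mean_n[:, None]) ** 2
    ).sum(axis=1)
    df1, df2 = 1.0, float(big_n - 2)
    degenerate = (ssw == 0) & (ssb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (ssb / df1) / (ssw / df2)
    stat = np.where(degenerate, 0.0, stat)
    stat = np.where((ssw == 0) & ~degenerate, np.inf, stat)
    p = stats.f.sf(stat, df1, df2)
    p = np.where(degenerate, 1.0, p)
    return stat, np.full_like(stat, df1), np.full_like(stat, df2), p, degenerate


def anova_f_on_deviations(
    z: DeviationMatrix, site_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """One-way ANOVA F on deviation scores, one row per site.

    Composed with :func:`center_deviations` in ``abs`` mode this yields
    Levene's test (group mean centre), the trimmed-mean Levene test, or the
    Brown-Forsythe test (group median centre).
    """
    labels = z.labels
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise InvalidInputError("each group needs at least 2 subjects")
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(z.z_values.shape[0])]
    stat, df1, df2, p, degen = _anova_f_arrays(z.z_values, labels)
    name = {
        ("abs", "group_mean"): "Levene",
        ("abs", "group_trimmed_mean"): "L.trim",
        ("abs", "group_median"): "BF",
    }.get((z.mode, z.center), "LeveneType")
    return result_table(site_ids, name, stat, df1, df2, p, degen)


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t (Phipson & Oshlack's DiffVar tests)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise InvalidInputError("trigamma inverse requires a positive target")
    if x > 1e7:  # trigamma(y) ~ 1/y near 0
        return 1.0 / np.sqrt(x)
    if x < 1e-6:  # trigamma(y) ~ 1/y for large y
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < tol:
            break
    return float(y)


def fit_fdist(sample_variances: Sequence[float], residual_df: float) -> FDistHyperparams:
    """Fit the prior (d0, s0^2) of the scaled-F variance model by moment
    matching on log variances.

    Under s_g^2 ~ s0^2 * F(d, d0), the statistic
    e_g = log(s_g^2) - psi(d/2) + log(d/2) has mean log(s0^2) + psi(d0/2)
    - log(d0/2) and variance psi'(d/2) + psi'(d0/2); matching the observed
    mean and variance of e_g and inverting the trigamma function recovers
    the hyperparameters.  A non-positive excess variance clamps d0 to
    infinity (no between-site variance heterogeneity beyond sampling).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    if s2.size < 2:
        raise InvalidInputError("need at least 2 sample variances")
    if (s2 <= 0).any():
        raise InvalidInputError("sample variances must be positive")
    if not residual_df > 0:
        raise InvalidInputError("residual_df must be positive")
    d = float(residual_df)
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    mean_e = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return FDistHyperparams(np.inf, float(np.exp(mean_e)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return FDistHyperparams(d0, s0_sq)


def squeeze_var(s_g_sq: float, d_g: float, hyper: FDistHyperparams) -> float:
    """Posterior (shrunk) variance (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)."""
    if s_g_sq < 0 or not d_g > 0:
        raise InvalidInputError("need s_g_sq >= 0 and d_g > 0")
    if np.isinf(hyper.d0):
        return float(hyper.s0_sq)
    return float((hyper.d0 * hyper.s0_sq + d_g * s_g_sq) / (hyper.d0 + d_g))


def moderated_t_table(
    z: DeviationMatrix,
    site_ids: Sequence[str] | None = None,
    test_name: str = "ModT",
    hyper: FDistHyperparams | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t on deviation scores, borrowing strength
    across sites.

    Per site the pooled within-group variance of z (residual df
    m_d + m_n - 2) is squeezed toward the prior fitted across all sites,
    and the group difference in mean deviation is referred to a t law with
    d_g + d0 degrees of freedom (standard normal when d0 is infinite).
    Pass ``hyper`` to override the fitted prior (d0 = 0 disables
    moderation and recovers the ordinary pooled t).
    """
    labels = z.labels
    zv = z.z_values
    if zv.shape[0] < 2 and hyper is None:
        raise InvalidInputError(
            "moderation needs at least 2 sites to fit hyperparameters"
        )
    m_d = int((labels == 1).sum())
    m_n = int((labels == 0).sum())
    if m_d < 2 or m_n < 2:
        raise InvalidInputError("each group needs at least 2 subjects")
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(zv.shape[0])]
    z_d, z_n = zv[:, labels == 1], zv[:, labels == 0]
    mean_d, mean_n = z_d.mean(axis=1), z_n.mean(axis=1)
    d_g = float(m_d + m_n - 2)
    s2 = (
        ((z_d - mean_d[:, None]) ** 2).sum(axis=1)
        + ((z_n - mean_n[:, None]) ** 2).sum(axis=1)
    ) / d_g
    if hyper is None:
        positive = s2[s2 > 0]
        if positive.size < 2:
            raise InvalidInputError(
                "hyperparameters unidentifiable: fewer than 2 sites with "
                "positive residual variance"
            )
        hyper = fit_fdist(positive, d_g)
    d0 = hyper.d0
    if np.isinf(d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = d_g
    else:
        s2_post = (d0 * hyper.s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d_g + d0
    diff = mean_d - mean_n
    se = np.sqrt(s2_post * (1.0 / m_d + 1.0 / m_n))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate & (diff == 0), 0.0, diff / np.where(se == 0, np.nan, se))
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    return result_table(
        site_ids, test_name, t, np.ones_like(t), np.full_like(t, df_total), p,
        degenerate,
    )


def po_test(
    matrix: MethylationMatrix,
    mode: str = "AD",
    center: str = "group_mean",
) -> pd.DataFrame:
    """Phipson-Oshlack moderated-t equal-variance test (PO.AD / PO.SQ).

    ``mode="AD"`` uses absolute deviations from the within-group mean,
    ``mode="SQ"`` squared deviations.
    """
    if mode not in ("AD", "SQ"):
        raise InvalidInputError(f"unknown PO mode {mode!r}")
    if matrix.n_sites < 2:
        raise InvalidInputError("PO tests need at least 2 sites")
    z = center_deviations(
        matrix, mode="abs" if mode == "AD" else "square", center=center
    )
    return moderated_t_table(z, matrix.site_ids, test_name=f"PO.{mode}")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def run_test(
    matrix: MethylationMatrix,
    test_name: str,
    trim_fraction: float = 0.10,
    po_center: str = "group_mean",
) -> pd.DataFrame:
    """Run one of the seven equal-variance tests over every site.

    All p-values are two-sided.  ``trim_fraction`` applies to L.trim only
    (default 0.10 per tail); ``po_center`` selects the centring of the
    PO deviation scores.
    """
    if test_name not in TEST_NAMES:
        raise InvalidInputError(
            f"unknown test {test_name!r}; expected one of {TEST_NAMES}"
        )
    x_d = matrix.group_values(1)
    x_n = matrix.group_values(0)
    if x_d.shape[1] < 2 or x_n.shape[1] < 2:
        raise InvalidInputError("each group needs at least 2 subjects")
    if test_name == "F":
        stat, df1, df2, p, degen = _f_arrays(x_d, x_n)
        return result_table(matrix.site_ids, "F", stat, df1, df2, p, degen)
    if test_name == "Bartlett":
        stat, df1, df2, p, degen = _bartlett_arrays([x_n, x_d])
        return result_table(matrix.site_ids, "Bartlett", stat, df1, df2, p, degen)
    if test_name in ("Levene", "L.trim", "BF"):
        center = {
            "Levene": "group_mean",
            "L.trim": "group_trimmed_mean",
            "BF": "group_median",
        }[test_name]
        tf = trim_fraction if test_name == "L.trim" else 0.0
        z = center_deviations(matrix, mode="abs", center=center, trim_fraction=tf)
        return anova_f_on_deviations(z, matrix.site_ids)
    return po_test(matrix, mode=test_name.split(".")[1], center=po_center)
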