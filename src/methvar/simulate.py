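"""Synthetic-data engines for benchmarking the equal-variance tests.

Two generators are provided.

*Study-I style* (:func:`simulate_study1`): every site x subject value is an
i.i.d. draw from a fixed per-group distribution.  The distribution grid
crosses three families (chi-squared, t, normal) with four mean/variance
regimes (equal/different means x equal/different variances); the
different-mean variants use non-central distributions tuned so that only
the intended moment differs between groups.

*Study-II style* (:func:`simulate_study2`): a Bayesian hierarchical model
on the M-value scale.  Each site draws one latent variance per group from
a scaled inverse chi-squared law scale-inv-chi2(d0, s0^2); subject values
are then emitted either as Normal(group mean, latent variance) or as
chi-squared with the latent draw as (real-valued) degrees of freedom.
Sites are marginally correlated through the shared hyperparameters but
conditionally independent.

Both generators optionally contaminate the data with a single-subject
outlier per site: one diseased subject's value is replaced by the global
pre-injection maximum of the whole matrix
(:func:`inject_outlier`).  :func:`make_discovery_validation_pair` builds
two independent cohorts sharing a common set of truly differentially
variable sites, emulating a discovery/validation design.

Reproducibility: each dataset consumes one root seed; per-site streams are
derived by counter-based seed-sequence splitting, so enlarging ``n_sites``
never perturbs earlier sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import special

from .data import InvalidInputError, MethylationMatrix

__all__ = [
    "Distribution",
    "ScenarioSpec",
    "HierSpec",
    "SimulatedDataset",
    "table1_params",
    "simulate_study1",
    "simulate_study2",
    "r_scaled_inv_chisq",
    "inject_outlier",
    "make_discovery_validation_pair",
    "FAMILIES",
    "REGIMES",
]

FAMILIES = ("normal", "t", "chisq")
REGIMES = ("eqM_eqV", "diffM_eqV", "eqM_diffV", "diffM_diffV")


@dataclass(frozen=True)
class Distribution:
    """A univariate sampling distribution with closed-form first moments.

    ``kind`` is one of ``normal`` (params mu, variance), ``t`` (df),
    ``nct`` (df, ncp), ``chisq`` (df), ``ncx2`` (df, ncp).
    """

    kind: str
    params: tuple[float, ...]

    @property
    def mean(self) -> float:
        k, p = self.kind, self.params
        if k == "normal":
            return p[0]
        if k == "t":
            return 0.0
        if k == "nct":
            df, ncp = p
            return ncp * np.sqrt(df / 2.0) * np.exp(
                special.gammaln((df - 1.0) / 2.0) - special.gammaln(df / 2.0)
            )
        if k == "chisq":
            return p[0]
        if k == "ncx2":
            return p[0] + p[1]
        raise InvalidInputError(f"unknown distribution kind {k!r}")

    @property
    def var(self) -> float:
        k, p = self.kind, self.params
        if k == "normal":
            return p[1]
        if k == "t":
            df = p[0]
            return df / (df - 2.0)
        if k == "nct":
            df, ncp = p
            return df * (1.0 + ncp**2) / (df - 2.0) - self.mean**2
        if k == "chisq":
            return 2.0 * p[0]
        if k == "ncx2":
            return 2.0 * p[0] + 4.0 * p[1]
        raise InvalidInputError(f"unknown distribution kind {k!r}")

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        k, p = self.kind, self.params
        if k == "normal":
            return p[0] + np.sqrt(p[1]) * rng.standard_normal(size)
        if k == "t":
            return rng.standard_t(p[0], size)
        if k == "nct":
            df, ncp = p
            return (rng.standard_normal(size) + ncp) / np.sqrt(
                rng.chisquare(df, size) / df
            )
        if k == "chisq":
            return rng.chisquare(p[0], size)
        if k == "ncx2":
            return rng.noncentral_chisquare(p[0], p[1], size)
        raise InvalidInputError(f"unknown distribution kind {k!r}")

    def __str__(self) -> str:
        inner = ",".join(f"{v:g}" for v in self.params)
        return f"{self.kind}({inner})"


# Per-family distribution grid: the non-diseased group is fixed within a
# family; the diseased group realises the four mean/variance regimes.
# Annotated (mean, variance) pairs follow each entry.
_TABLE1: dict[tuple[str, str], tuple[Distribution, Distribution]] = {
    # chi-squared family; non-diseased chisq(2): (2, 4)
    ("chisq", "eqM_eqV"): (Distribution("chisq", (2.0,)), Distribution("chisq", (2.0,))),
    ("chisq", "diffM_eqV"): (
        Distribution("chisq", (2.0,)),
        Distribution("ncx2", (1.0, 0.5)),  # (1.5, 4)
    ),
    ("chisq", "eqM_diffV"): (
        Distribution("chisq", (2.0,)),
        Distribution("ncx2", (0.5, 1.5)),  # (2, 7)
    ),
    ("chisq", "diffM_diffV"): (
        Distribution("chisq", (2.0,)),
        Distribution("chisq", (4.0,)),  # (4, 8)
    ),
    # t family; non-diseased t(10): (0, 1.25)
    ("t", "eqM_eqV"): (Distribution("t", (10.0,)), Distribution("t", (10.0,))),
    ("t", "diffM_eqV"): (
        Distribution("t", (10.0,)),
        Distribution("nct", (15.0, 1.489)),  # (1.57, 1.25)
    ),
    ("t", "eqM_diffV"): (
        Distribution("t", (10.0,)),
        Distribution("t", (10.0 / 3.0,)),  # (0, 2.5)
    ),
    ("t", "diffM_diffV"): (
        Distribution("t", (10.0,)),
        Distribution("nct", (6.0, 2.393)),  # (2.75, 2.5)
    ),
    # normal family; non-diseased N(0,1)
    ("normal", "eqM_eqV"): (
        Distribution("normal", (0.0, 1.0)),
        Distribution("normal", (0.0, 1.0)),
    ),
    ("normal", "diffM_eqV"): (
        Distribution("normal", (0.0, 1.0)),
        Distribution("normal", (1.5, 1.0)),
    ),
    ("normal", "eqM_diffV"): (
        Distribution("normal", (0.0, 1.0)),
        Distribution("normal", (0.0, 2.0)),
    ),
    ("normal", "diffM_diffV"): (
        Distribution("normal", (0.0, 1.0)),
        Distribution("normal", (1.5, 2.0)),
    ),
}


def table1_params(family: str, regime: str) -> tuple[Distribution, Distribution]:
    """Per-group generating distributions (non-diseased, diseased) for a
    Study-I scenario."""
    try:
        return _TABLE1[(family, regime)]
    except KeyError:
        raise InvalidInputError(
            f"unknown scenario ({family!r}, {regime!r}); families {FAMILIES}, "
            f"regimes {REGIMES}"
        ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """One fixed-distribution (Study-I style) simulation scenario."""

    family: str
    regime: str
    n_per_group: int = 20
    n_sites: int = 1000
    outlier: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        table1_params(self.family, self.regime)  # validates the pair
        if self.n_per_group < 2:
            raise InvalidInputError("n_per_group must be >= 2")
        if self.n_sites < 1:
            raise InvalidInputError("n_sites must be >= 1")

    @property
    def is_null(self) -> bool:
        return "diffV" not in self.regime


@dataclass(frozen=True)
class HierSpec:
    """One hierarchical-variance (Study-II style) simulation scenario.

    Defaults encode the benchmark settings: prior df d0 = 20, control
    prior variance 0.64 (case 0.64 under the null, 1.5 under the
    alternative), group mean M-values +2 (case) and -2 (control) for the
    conditional-normal emission.
    """

    d0: float = 20.0
    s0_sq_control: float = 0.64
    s0_sq_case: float = 0.64
    emission: str = "normal"
    mean_case: float = 2.0
    mean_control: float = -2.0
    n_per_group: int = 20
    n_sites: int = 1000
    outlier: bool = False
    recenter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.emission not in ("normal", "chisq"):
            raise InvalidInputError("emission must be 'normal' or 'chisq'")
        if not (self.d0 > 0 and self.s0_sq_control > 0 and self.s0_sq_case > 0):
            raise InvalidInputError("d0 and scale factors must be positive")
        if self.n_per_group < 2:
            raise InvalidInputError("n_per_group must be >= 2")
        if self.n_sites < 1:
            raise InvalidInputError("n_sites must be >= 1")

    @property
    def is_null(self) -> bool:
        return self.s0_sq_case == self.s0_sq_control


@dataclass
class SimulatedDataset:
    """A simulated cohort plus per-site ground truth.

    ``truth`` flags sites that are truly differentially variable; the
    provenance records the generating specification.
    """

    matrix: MethylationMatrix
    truth: np.ndarray
    provenance: object = None

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.truth.shape != (self.matrix.n_sites,):
            raise InvalidInputError("one truth flag per site is required")


def _site_rng(seed: int, site: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(site,)))


def _labels(n_per_group: int) -> np.ndarray:
    # control columns first, then diseased
    return np.concatenate([np.zeros(n_per_group, int), np.ones(n_per_group, int)])


def simulate_study1(spec: ScenarioSpec) -> SimulatedDataset:
    """Generate one fixed-distribution dataset; sites i.i.d. across rows."""
    dist_n, dist_d = table1_params(spec.family, spec.regime)
    n = spec.n_per_group
    values = np.empty((spec.n_sites, 2 * n))
    for i in range(spec.n_sites):
        rng = _site_rng(spec.seed, i)
        values[i, :n] = dist_n.rvs(rng, n)
        values[i, n:] = dist_d.rvs(rng, n)
    matrix = MethylationMatrix.from_arrays(values, _labels(n))
    truth = np.full(spec.n_sites, not spec.is_null)
    dataset = SimulatedDataset(matrix, truth, spec)
    if spec.outlier:
        dataset = inject_outlier(dataset)
    return dataset


def r_scaled_inv_chisq(
    n: int, d0: float, s0_sq: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw from scale-inv-chi2(d0, s0^2), i.e. d0*s0^2 / chi2_{d0}."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not (d0 > 0 and s0_sq > 0):
        raise InvalidInputError("d0 and s0_sq must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return d0 * s0_sq / rng.chisquare(d0, n)


def simulate_study2(spec: HierSpec) -> SimulatedDataset:
    """Generate one hierarchical-variance dataset.

    Under the null (equal group scale factors) each site draws a single
    latent value from the scaled inverse chi-squared prior, shared by both
    groups — a non-differentially-variable site has one variance.  Under
    the alternative each group draws its own latent value from its own
    prior.  Conditional-normal emission uses the latent value as the
    variance around the group mean; conditional-chi-squared emission uses
    it as real-valued degrees of freedom, realised through the
    gamma(shape = v/2, scale = 2) representation.  The chi-squared
    emission keeps its natural location unless ``recenter`` is set, in
    which case each group is shifted to the nominal group mean.
    """
    n = spec.n_per_group
    values = np.empty((spec.n_sites, 2 * n))
    for i in range(spec.n_sites):
        rng = _site_rng(spec.seed, i)
        v_control = r_scaled_inv_chisq(1, spec.d0, spec.s0_sq_control, rng)[0]
        if spec.is_null:
            v_case = v_control
        else:
            v_case = r_scaled_inv_chisq(1, spec.d0, spec.s0_sq_case, rng)[0]
        if spec.emission == "normal":
            values[i, :n] = spec.mean_control + np.sqrt(v_control) * rng.standard_normal(n)
            values[i, n:] = spec.mean_case + np.sqrt(v_case) * rng.standard_normal(n)
        else:
            control = rng.gamma(v_control / 2.0, 2.0, n)
            case = rng.gamma(v_case / 2.0, 2.0, n)
            if spec.recenter:
                control = control - v_control + spec.mean_control
                case = case - v_case + spec.mean_case
            values[i, :n] = control
            values[i, n:] = case
    matrix = MethylationMatrix.from_arrays(values, _labels(n))
    truth = np.full(spec.n_sites, not spec.is_null)
    dataset = SimulatedDataset(matrix, truth, spec)
    if spec.outlier:
        dataset = inject_outlier(dataset)
    return dataset


def inject_outlier(
    dataset: SimulatedDataset, subject_index: Optional[int] = None
) -> SimulatedDataset:
    """Contaminate every site with one outlying diseased subject.

    The global maximum over the whole pre-injection matrix is computed once;
    at each site the value of one diseased subject (column ``subject_index``
    within the diseased group, default 0) is replaced by that maximum.
    """
    matrix = dataset.matrix
    diseased_cols = np.flatnonzero(matrix.labels == 1)
    if diseased_cols.size == 0:
        raise InvalidInputError("no diseased subjects to contaminate")
    idx = 0 if subject_index is None else int(subject_index)
    if not 0 <= idx < diseased_cols.size:
        raise InvalidInputError("subject_index outside the diseased group")
    global_max = float(matrix.values.max())
    values = matrix.values.copy()
    values[:, diseased_cols[idx]] = global_max
    contaminated = MethylationMatrix(
        values, matrix.site_ids, matrix.subject_ids, matrix.labels
    )
    return SimulatedDataset(contaminated, dataset.truth, dataset.provenance)


def make_discovery_validation_pair(
    n_sites: int = 1000,
    n_dv_sites: int = 100,
    n_per_group: int = 50,
    effect: float = 4.0,
    seed: int = 0,
    base_sd: float = 1.0,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Two independent cohorts sharing the same differentially variable sites.

    Null sites are N(0, base_sd^2) in both groups of both cohorts; in the
    first ``n_dv_sites`` sites the diseased group's variance is multiplied
    by ``effect`` (in both cohorts).  Truth flags are identical across the
    pair.
    """
    if n_dv_sites > n_sites:
        raise InvalidInputError("n_dv_sites cannot exceed n_sites")
    if effect <= 0:
        raise InvalidInputError("effect (variance ratio) must be positive")
    truth = np.zeros(n_sites, bool)
    truth[:n_dv_sites] = True
    cohorts = []
    for cohort_idx in range(2):
        values = np.empty((n_sites, 2 * n_per_group))
        for i in range(n_sites):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(cohort_idx, i))
            )
            sd_case = base_sd * (np.sqrt(effect) if truth[i] else 1.0)
            values[i, :n_per_group] = base_sd * rng.standard_normal(n_per_group)
            values[i, n_per_group:] = sd_case * rng.standard_normal(n_per_group)
        matrix = MethylationMatrix.from_arrays(values, _labels(n_per_group))
        cohorts.append(SimulatedDataset(matrix, truth.copy(), ("dv_pair", cohort_idx)))
    return cohorts[0], cohorts[1]
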