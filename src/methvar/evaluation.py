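"""Type-I-error / power estimation and the rank summary across scenarios.

For each scenario, ``n_datasets`` replicate cohorts are simulated and each
test's per-dataset rejection proportion at level alpha is recorded: under a
null scenario this estimates the type I error rate, under an alternative
the power.  A one-sided location test then asks whether a test's type I
error exceeds the nominal level; tests that fail this bound are excluded
from the power ranking of the scenario (missing rank).  Ranks ascend in
power (rank 1 = least powerful) with average ranks for ties; the final
summary per test is the median rank m over scenarios and the count
n_reject of scenarios where the type-I bound was rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import InvalidInputError, TEST_NAMES
from .simulate import HierSpec, ScenarioSpec, simulate_study1, simulate_study2
from .variance_tests import run_test

__all__ = [
    "PerformanceEstimate",
    "RankSummary",
    "rejection_rate",
    "run_comparison",
    "test_type1_bound",
    "rank_powers",
    "summarize_ranks",
    "study_grid",
    "run_grid",
    "evaluate_scenario",
]

Spec = Union[ScenarioSpec, HierSpec]


@dataclass
class PerformanceEstimate:
    """Per-dataset rejection proportions for one test under one scenario."""

    test_name: str
    scenario: object
    per_dataset_rates: np.ndarray
    is_null_scenario: bool

    def __post_init__(self) -> None:
        self.per_dataset_rates = np.asarray(self.per_dataset_rates, dtype=float)

    @property
    def mean_rate(self) -> float:
        return float(self.per_dataset_rates.mean())

    @property
    def sd_rate(self) -> float:
        if self.per_dataset_rates.size < 2:
            return float("nan")
        return float(self.per_dataset_rates.std(ddof=1))


@dataclass
class RankSummary:
    """Median power rank m and type-I rejection count per test."""

    median_rank: dict[str, float]  # NaN when ranked in no scenario
    n_reject: dict[str, int]
    n_scenarios: int

    def to_frame(self) -> pd.DataFrame:
        tests = list(self.median_rank)
        return pd.DataFrame(
            {
                "test": tests,
                "m": [self.median_rank[t] for t in tests],
                "n_reject": [self.n_reject[t] for t in tests],
            }
        )


def rejection_rate(p_values: Sequence[float], alpha: float = 0.05) -> float:
    """Proportion of p-values strictly below alpha (NaNs never count)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidInputError("empty p-value vector")
    with np.errstate(invalid="ignore"):
        return float((p < alpha).mean())


def _simulate(spec: Spec) -> "SimulatedDataset":
    if isinstance(spec, ScenarioSpec):
        return simulate_study1(spec)
    if isinstance(spec, HierSpec):
        return simulate_study2(spec)
    raise InvalidInputError(f"unknown scenario spec {type(spec).__name__}")


def run_comparison(
    scenario: Spec,
    tests: Sequence[str] = TEST_NAMES,
    n_datasets: int = 100,
    root_seed: int = 0,
    alpha: float = 0.05,
    trim_fraction: float = 0.10,
) -> list[PerformanceEstimate]:
    """Estimate rejection rates for several tests over replicate datasets.

    All tests see the identical simulated matrices (dataset seeds are
    derived from ``root_seed``), so per-dataset rates are paired across
    tests.
    """
    if n_datasets < 1:
        raise InvalidInputError("n_datasets must be >= 1")
    from dataclasses import replace

    dataset_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(root_seed).spawn(n_datasets)
    ]
    rates = {t: np.empty(n_datasets) for t in tests}
    is_null = scenario.is_null
    for d, seed in enumerate(dataset_seeds):
        dataset = _simulate(replace(scenario, seed=seed))
        for t in tests:
            table = run_test(dataset.matrix, t, trim_fraction=trim_fraction)
            # degenerate sites report p = 1 and therefore never reject
            rates[t][d] = rejection_rate(table["p_value"].to_numpy(), alpha)
    return [
        PerformanceEstimate(t, scenario, rates[t], is_null) for t in tests
    ]


def test_type1_bound(
    per_dataset_rates: Sequence[float],
    nominal: float = 0.05,
    method: str = "t",
    n_sites: Optional[int] = None,
) -> float:
    """P-value for H0: mean type I error <= nominal, against >.

    ``method="t"`` (default) is a one-sided one-sample t-test on the
    per-dataset rates; ``method="binomial"`` pools rejections over
    datasets (requires ``n_sites``) and uses an exact binomial upper tail.
    Constant rates are decided by direct comparison with the nominal level.
    """
    rates = np.asarray(per_dataset_rates, dtype=float)
    if rates.size < 2:
        raise InvalidInputError("need at least 2 per-dataset rates")
    if method == "binomial":
        if n_sites is None:
            raise InvalidInputError("binomial bound test needs n_sites")
        k = int(round(rates.sum() * n_sites))
        n = rates.size * n_sites
        return float(stats.binomtest(k, n, nominal, alternative="greater").pvalue)
    if method != "t":
        raise InvalidInputError(f"unknown method {method!r}")
    if np.ptp(rates) == 0:  # exactly constant rates: decide directly
        return 0.0 if rates[0] > nominal else 1.0
    res = stats.ttest_1samp(rates, nominal, alternative="greater")
    return float(res.pvalue)


test_type1_bound.__test__ = False  # plain function, not a pytest item


def rank_powers(
    mean_powers: Sequence[float],
    rejected_type1: Sequence[bool],
) -> np.ndarray:
    """Power ranks with missing entries for tests failing the type-I bound.

    Ranks ascend in power (1 = least powerful among the admissible tests);
    ties get average ranks.  Tests whose type-I bound was rejected receive
    NaN.
    """
    powers = np.asarray(mean_powers, dtype=float)
    rejected = np.asarray(rejected_type1, dtype=bool)
    if powers.shape != rejected.shape:
        raise InvalidInputError("mean_powers and rejected_type1 must align")
    ranks = np.full(powers.shape, np.nan)
    keep = ~rejected
    if keep.any():
        ranks[keep] = stats.rankdata(powers[keep], method="average")
    return ranks


def summarize_ranks(
    per_scenario_ranks: Sequence[Sequence[float]],
    tests: Sequence[str] | None = None,
) -> RankSummary:
    """Median rank m and rejection count n_reject per test over scenarios.

    ``per_scenario_ranks`` is a (scenarios x tests) array whose NaNs mark
    type-I rejections; m is NaN for a test ranked in no scenario.
    """
    ranks = np.asarray(per_scenario_ranks, dtype=float)
    if ranks.ndim != 2 or ranks.shape[0] < 1:
        raise InvalidInputError("need a (scenarios x tests) rank array")
    if tests is None:
        tests = list(TEST_NAMES[: ranks.shape[1]])
        if len(tests) < ranks.shape[1]:
            tests += [f"test{i}" for i in range(len(tests), ranks.shape[1])]
    if len(tests) != ranks.shape[1]:
        raise InvalidInputError("one test name per rank column is required")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        m = np.nanmedian(ranks, axis=0)
    n_reject = np.isnan(ranks).sum(axis=0)
    return RankSummary(
        {t: float(m[j]) for j, t in enumerate(tests)},
        {t: int(n_reject[j]) for j, t in enumerate(tests)},
        ranks.shape[0],
    )


def study_grid(
    sample_sizes: Sequence[int] = (20, 50, 200),
    n_sites: int = 1000,
) -> list[tuple[str, Spec, Spec]]:
    """The full benchmark grid of 48 paired null/alternative scenarios.

    Fixed-distribution scenarios cross 3 families x 2 mean settings x
    2 outlier settings x the sample sizes (36 comparisons); hierarchical
    scenarios cross 2 emissions x 2 outlier settings x the sample sizes
    (12 comparisons).  Each entry pairs the null scenario (equal
    variances, for type I error) with its alternative (different
    variances, for power).
    """
    from .simulate import FAMILIES

    grid: list[tuple[str, Spec, Spec]] = []
    for family in FAMILIES:
        for mean_setting in ("eqM", "diffM"):
            for outlier in (False, True):
                for n in sample_sizes:
                    name = f"S1:{family}:{mean_setting}:out{int(outlier)}:n{n}"
                    null = ScenarioSpec(family, f"{mean_setting}_eqV", n, n_sites, outlier)
                    alt = ScenarioSpec(family, f"{mean_setting}_diffV", n, n_sites, outlier)
                    grid.append((name, null, alt))
    for emission in ("normal", "chisq"):
        for outlier in (False, True):
            for n in sample_sizes:
                name = f"S2:{emission}:out{int(outlier)}:n{n}"
                null = HierSpec(emission=emission, n_per_group=n, n_sites=n_sites,
                                outlier=outlier)
                alt = HierSpec(s0_sq_case=1.5, emission=emission, n_per_group=n,
                               n_sites=n_sites, outlier=outlier)
                grid.append((name, null, alt))
    return grid


def run_grid(
    grid: Sequence[tuple[str, Spec, Spec]],
    tests: Sequence[str] = TEST_NAMES,
    n_datasets: int = 100,
    root_seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, RankSummary]:
    """Evaluate every scenario of a grid and summarise the power ranks.

    Returns the per-scenario/per-test performance table and the
    (m, n_reject) rank summary across scenarios.
    """
    frames = []
    ranks = []
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(root_seed).spawn(len(grid))
    ]
    for (name, null_spec, alt_spec), seed in zip(grid, seeds):
        frame = evaluate_scenario(
            null_spec, alt_spec, tests, n_datasets, root_seed=seed, alpha=alpha
        )
        frame.insert(0, "scenario", name)
        frames.append(frame)
        ranks.append(frame["rank"].to_numpy())
    summary = summarize_ranks(np.asarray(ranks), list(tests))
    return pd.concat(frames, ignore_index=True), summary


def evaluate_scenario(
    null_spec: Spec,
    alt_spec: Spec,
    tests: Sequence[str] = TEST_NAMES,
    n_datasets: int = 100,
    root_seed: int = 0,
    alpha: float = 0.05,
    bound_alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-scenario evaluation: type I error, power, bound test, ranks.

    Runs the paired null/alternative scenarios, tests each procedure's
    type-I bound on the null replicates, and ranks admissible procedures
    by mean power.  Returns one row per test.
    """
    null_perf = run_comparison(null_spec, tests, n_datasets, root_seed, alpha)
    alt_perf = run_comparison(alt_spec, tests, n_datasets, root_seed + 1, alpha)
    bound_p = np.array(
        [test_type1_bound(pe.per_dataset_rates, alpha) for pe in null_perf]
    )
    rejected = bound_p < bound_alpha
    powers = np.array([pe.mean_rate for pe in alt_perf])
    ranks = rank_powers(powers, rejected)
    return pd.DataFrame(
        {
            "test": list(tests),
            "type1": [pe.mean_rate for pe in null_perf],
            "type1_sd": [pe.sd_rate for pe in null_perf],
            "power": powers,
            "power_sd": [pe.sd_rate for pe in alt_perf],
            "bound_p": bound_p,
            "rejected_type1": rejected,
            "rank": ranks,
        }
    )
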