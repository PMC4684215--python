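# Methods

## Scientific setting

Each CpG site *g* carries methylation levels x_ik for subject *i* in
group *k* (k = d diseased, k = n non-diseased; m_d and m_n subjects).
Levels are analysed on the M-value scale, M = log2(β/(1−β)).  The null
hypothesis at every site is H₀: σ²_d = σ²_n against the two-sided
alternative; all seven tests return two-sided p-values.

## The seven tests

**F.**  statistic s²_d/s²_n with unbiased sample variances, referred to
F(m_d−1, m_n−1).  The two-sided p-value doubles the smaller tail and is
capped at 1.  The diseased-group variance sits in the numerator; the
doubled p-value is orientation-invariant, so this is a reporting
convention only.

**Bartlett.**  The classical statistic
[(N−k)·ln s²_p − Σ(n_i−1)·ln s²_i] / C with the usual correction C,
referred to χ²_{k−1} (upper tail).  Defined for k ≥ 2 groups, although
the benchmark uses k = 2 throughout.

**Levene / L.trim / BF.**  The data are replaced by deviation scores
z_ik = |x_ik − c| where c is, per site and group, the mean (Levene),
the trimmed mean (L.trim), or the median (BF), and a two-group one-way
ANOVA F with df (1, m_d+m_n−2) is applied to z.  L.trim trims
floor(0.10·n) observations per tail by default (the classical choice;
configurable), and centres *all* observations at the trimmed mean — the
trimming affects the centre only, not the ANOVA sample.  Medians of
even-length groups are midpoint medians.

**PO.AD / PO.SQ.**  Deviation scores from the within-group mean
(absolute for AD, squared for SQ; the centring is configurable) enter
an empirical-Bayes moderated two-sample t.  Per site the pooled
within-group variance s²_g of z (residual df d_g = m_d+m_n−2) is shrunk
to s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) fitted across
all sites, and t_g = (z̄_d − z̄_n)/√(s̃²_g(1/m_d + 1/m_n)) is referred
to t with d_g + d₀ degrees of freedom (standard normal when d₀ = ∞).
These tests need at least two sites; with a single site the prior is
unidentifiable and the call errors.

### Hyperparameter fitting

Under the scaled-F model s²_g ~ s₀²·F(d_g, d₀), the transformed
statistic e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2) has mean
ln s₀² + ψ(d₀/2) − ln(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2).
Moment matching gives ψ′(d₀/2) = Var(e) − ψ′(d_g/2); the trigamma
function is inverted by Newton iteration (tolerance 1e-8, at most 100
iterations, asymptotic starting values at the extremes).  A
non-positive excess variance clamps d₀ = ∞ with
s₀² = exp(mean(e)) — note this estimate carries the log-scale bias
correction exp(ln(d/2) − ψ(d/2)) relative to the arithmetic mean of
equal variances; the correction vanishes as the residual df grows.  d₀
is never truncated or rounded; fitted values are always positive, and
d₀ = 0 is accepted on input as the explicit no-moderation limit, in
which case the moderated t reduces exactly to the ordinary pooled t.
One independent check in the test suite reproduces the full moderated-t
table against the limma reference implementation (via Rscript) to 1e-6.

### Degenerate sites

A site whose test statistic is 0/0 (e.g. all deviation scores
identical, or both groups constant for F/Bartlett) is reported with
statistic 0, p = 1 and a `degenerate` flag: a constant site carries no
evidence against equal variances, and p = 1 keeps such sites out of
rejection counts without NaN propagation.  A site where only one
group's spread vanishes yields an infinite statistic and p = 0 from the
same formulas.

## Simulation engines

**Fixed-distribution grid.**  Three families (normal, t, chi-squared)
× four regimes (equal/different mean × equal/different variance).  The
non-diseased group is fixed per family (N(0,1), t₁₀, χ²₂); the diseased
group realises the regime using non-central t and non-central χ²
distributions whose parameters were chosen so that only the intended
moment differs — e.g. nct(15, 1.489) has mean 1.57 and variance 1.25,
matching t₁₀'s variance, and ncχ²(0.5, 1.5) has mean 2 (matching χ²₂)
with variance 7.  Closed-form moments (non-central t mean
ncp·√(df/2)·Γ((df−1)/2)/Γ(df/2), etc.) are part of the API and are
checked against Monte Carlo in the tests.  Non-central t is generated
as (Z + ncp)/√(χ²_df/df).

**Hierarchical model.**  Per site, a latent variance v ~
scale-inv-χ²(d₀, s₀²) = d₀s₀²/χ²_{d₀}.  Under the null (equal group
scale factors, the default s₀² = 0.64 with d₀ = 20) one draw is shared
by both groups — a non-differentially-variable site has a single
variance, and the per-site case/control variance ratio follows
F(d_g, d_g) marginally, which the tests exploit.  Under the
alternative each group draws from its own prior (case s₀² = 1.5 by
default).  Conditional-normal emission produces
N(±2, v) (case +2, control −2); conditional-chi-squared emission uses v
as real-valued degrees of freedom through gamma(v/2, scale 2), kept at
its natural location (mean v) unless the `recenter` flag shifts each
group to the nominal ±2 means — the mean shift is irrelevant to the
variance tests, so the default leaves it off.  Marginally each group's
sample variance satisfies s²_g/s₀² ~ F(d_g, d₀), the assertable
distributional identity.

**Outlier contamination.**  The global maximum of the pre-injection
matrix is computed once; at every site the value of one diseased
subject (index 0 of the diseased group by default; optionally any
index) is replaced by that maximum.  Injection is idempotent because
the replaced value is itself the retained maximum.

**Seeding.**  Each dataset consumes one root seed; per-site generator
streams are split off by counter-keyed seed sequences, so enlarging
n_sites appends sites without perturbing existing ones, and identical
seeds reproduce matrices bit-for-bit.

**Discovery/validation fixture.**  Two independent normal cohorts share
site identities and truth flags; differentially variable sites multiply
the case-group variance by a configurable ratio (default 4, with 100
such sites among 1000 and 50 subjects per group).  This emulates the
two-cohort replication design at a desk-computable scale.

## Performance evaluation

Per scenario, 100 replicate datasets of 1000 sites (the study default;
the grid driver and the ranking test use 20 replicates to keep the full
48-scenario sweep to about two minutes on one CPU) are simulated and
each test's rejection proportion at α = 0.05 recorded per dataset; all
tests see identical matrices, so rates are paired.  The bound
H₀: type I ≤ 0.05 is assessed by a one-sided one-sample t-test on the
per-dataset rates (an exact pooled binomial test is available as an
option); exactly constant rates are decided by direct comparison.
Tests rejecting the bound are excluded from that scenario's power
ranking; the rest are ranked ascending in power (largest rank = most
powerful, so a higher median rank reads as better power), with average
ranks for ties.  The cross-scenario summary reports the median rank m
over the scenarios where a test was ranked and n_reject, the number of
scenarios where it failed the bound.

## Discovery / validation workflow

Discovery applies one test to the discovery cohort and selects sites
with Benjamini-Hochberg adjusted p < 0.05 (adjustment delegated to
statsmodels; an independent brute-force step-up implementation guards
it in the tests).  Validation re-tests exactly those sites in the
second cohort with the same test and counts unadjusted p < 0.05.  The
IQR rule flags a site when any subject lies strictly outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] of its own group; quartiles use linear
interpolation between order statistics by default (the common software
default; the convention is a parameter, and flag status can differ
between conventions only for values near a fence).  The outlier
overlap report counts significant sites flagged in the discovery
cohort and the subset also flagged in the validation cohort.

## What the synthetic benchmarks do and do not show

The generators reproduce the moment structure, skewness regimes,
hierarchical variance sharing and single-point contamination that drive
the relative behaviour of variance tests.  They do not emulate probe-
level technical artefacts, batch effects, cell-type composition,
spatial correlation along the genome, or the bounded β-scale; sites are
independent (fixed-distribution engine) or only marginally dependent
through shared hyperparameters (hierarchical engine).  Passing the
suite therefore certifies the statistical machinery and its documented
operating characteristics under these models, not performance on any
particular array platform.  Re-analysing the two public cervical-smear
cohorts the workflow is modelled on requires downloading and QC-ing the
corresponding GEO series; the workflow accepts any matrix + phenotype
pair, and site exclusions (e.g. SNP-residing probes) can be applied by
the caller before testing.

## Known limitations

- The deviation-score tests are implemented for two groups (Bartlett
  accepts k ≥ 2 as its definition requires).
- No covariate adjustment, paired designs or robust (sandwich)
  variants.
- The moderated-t deviation scores are conditionally correlated within
  a site and not conditionally normal, so the PO tests' model
  assumptions are only approximations — visible in the benchmark as
  PO.AD's anticonservative behaviour.
- The trimmed-mean Levene variant follows the centre-only trimming
  convention; implementations that also trim the ANOVA sample (e.g.
  scipy's `levene(center="trimmed")`) give different numbers.
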