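"""Inferential statistics for temporal haplotype-frequency data.

The core procedure tests, for each haplotype and each earlier temporal
group, whether its observed count could plausibly arise by sampling from
the haplotype frequencies of a reference period (by default the most
recent one).  The null is Binomial(n_period, f_ref): `resampling_test`
estimates its tails by Monte Carlo (matching the original resampling
design), while `exact_test_oracle` computes them in closed form; the two
must agree within Monte-Carlo error and both are exposed.

Haplotypes absent from the reference sample get a substitute frequency f
solving (1 - f)^n_ref = alpha -- the frequency at which absence from a
reference sample of that size has exactly probability alpha.

A meta-level binomial test asks whether the *number* of nominally
significant cells exceeds the count expected by chance; chi-square
homogeneity tests check for differential spatial sampling across periods;
rarefaction/extrapolation (Chao1-anchored) compares haplotype richness
across unequal sample sizes; and standing diversity indices (haplotype
diversity h, nucleotide diversity pi) summarise each period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from haplochron.seqio import HaplotypeCatalog, HaplotypeTable, InputError
from haplochron.haplonet import pairwise_distance

TailRule = Literal["two_tailed_2p5", "outside_95_mass"]


@dataclass(frozen=True)
class TestConfig:
    """Settings for the temporal frequency-change test.

    alpha            nominal significance level (per cell)
    replicates       Monte-Carlo draws per (haplotype, period) cell
    seed             base seed; per-cell streams derive from it
    tail_rule        'two_tailed_2p5' flags a cell when either tail
                     probability is below alpha/2; 'outside_95_mass'
                     flags an observation outside the central
                     equal-tailed (1 - alpha) mass of the null
    reference_period period supplying the null frequencies (default:
                     last column of the table)
    """

    alpha: float = 0.05
    replicates: int = 100_000
    seed: int = 0
    tail_rule: TailRule = "two_tailed_2p5"
    reference_period: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha {self.alpha} outside (0, 1)")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")


@dataclass
class ResamplingTestResult:
    """Per-cell outcome of the frequency-change test.

    ``cells`` has one row per (haplotype, non-reference period) with
    columns: haplotype, period, observed, n, ref_freq, substitute,
    lower_tail (P[X <= observed]), upper_tail (P[X >= observed]),
    significant.
    """

    cells: pd.DataFrame
    config: TestConfig
    reference_period: str
    method: str  # "monte_carlo" or "exact"

    def cell(self, haplotype: str, period: str) -> pd.Series:
        m = (self.cells["haplotype"] == haplotype) & (self.cells["period"] == period)
        sub = self.cells[m]
        if sub.empty:
            raise KeyError((haplotype, period))
        return sub.iloc[0]

    def significant_cells(self) -> list[tuple[str, str]]:
        sig = self.cells[self.cells["significant"]]
        return list(zip(sig["haplotype"], sig["period"]))

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        # information-only Bonferroni column; no per-cell correction is
        # applied to the significance call itself
        n_tests = len(out)
        two_sided = 2 * np.minimum(out["lower_tail"], out["upper_tail"]).clip(upper=0.5)
        out["bonferroni_p"] = np.minimum(two_sided * n_tests, 1.0)
        out.to_csv(path, sep="\t", index=False)


def substitute_frequency(n_ref: int, alpha: float = 0.05) -> float:
    """Frequency f with P(absent from a sample of n_ref) = alpha.

    Solves (1 - f)^n_ref = alpha, i.e. f = 1 - alpha^(1/n_ref).  Used as
    the null frequency for haplotypes never observed in the reference
    sample, for which the naive estimate of zero would make any later
    observation impossible under the null.
    """
    if n_ref < 1:
        raise InputError(f"n_ref must be >= 1, got {n_ref}")
    if not 0 < alpha < 1:
        raise InputError(f"alpha {alpha} outside (0, 1)")
    return 1.0 - alpha ** (1.0 / n_ref)


def _reference_frequencies(
    table: HaplotypeTable, config: TestConfig
) -> tuple[str, pd.Series, pd.Series]:
    """Null frequency per haplotype, with the substitute rule applied."""
    ref = config.reference_period or table.period_labels[-1]
    if ref not in table.period_labels:
        raise InputError(f"reference period {ref!r} not in table")
    col = table.column(ref)
    n_ref = int(col.sum())
    if n_ref == 0:
        raise InputError(f"reference period {ref!r} has no samples")
    freqs = col / n_ref
    is_sub = col == 0
    freqs = freqs.where(~is_sub, substitute_frequency(n_ref, config.alpha))
    return ref, freqs.astype(float), is_sub


def _test_periods(table: HaplotypeTable, ref: str) -> list[str]:
    periods = [p for p in table.period_labels if p != ref]
    if not periods:
        raise InputError("need at least two periods")
    for p in periods:
        if table.column(p).sum() == 0:
            raise InputError(f"period {p!r} has no samples")
    return periods


def _significant(
    obs: int, lower: float, upper: float, draws: np.ndarray | None,
    f: float, n: int, alpha: float, rule: TailRule,
) -> bool:
    if rule == "two_tailed_2p5":
        return lower < alpha / 2 or upper < alpha / 2
    if rule == "outside_95_mass":
        if draws is not None:
            lo = np.quantile(draws, alpha / 2, method="inverted_cdf")
            hi = np.quantile(draws, 1 - alpha / 2, method="inverted_cdf")
        else:
            lo = stats.binom.ppf(alpha / 2, n, f)
            hi = stats.binom.ppf(1 - alpha / 2, n, f)
        return obs < lo or obs > hi
    raise InputError(f"unknown tail rule {rule!r}")


def resampling_test(table: HaplotypeTable, config: TestConfig) -> ResamplingTestResult:
    """Monte-Carlo test of per-haplotype frequency change vs the reference.

    For each haplotype h and non-reference period p, draws
    ``config.replicates`` binomial counts Bin(n_p, f_h) where f_h is h's
    frequency in the reference period (or the substitute frequency when h
    is absent there), and compares the observed count against the
    resulting empirical distribution.  Each cell uses an RNG stream
    derived from (seed, haplotype index, period index), so results do not
    depend on iteration order.
    """
    ref, freqs, is_sub = _reference_frequencies(table, config)
    periods = _test_periods(table, ref)
    rows = []
    for hi, hap in enumerate(table.labels):
        f = float(freqs[hap])
        for pi, period in enumerate(periods):
            n = int(table.column(period).sum())
            obs = int(table.counts.loc[hap, period])
            rng = np.random.default_rng([config.seed, hi, pi])
            draws = rng.binomial(n, f, size=config.replicates)
            lower = float(np.mean(draws <= obs))
            upper = float(np.mean(draws >= obs))
            rows.append({
                "haplotype": hap,
                "period": period,
                "observed": obs,
                "n": n,
                "ref_freq": f,
                "substitute": bool(is_sub[hap]),
                "lower_tail": lower,
                "upper_tail": upper,
                "significant": _significant(
                    obs, lower, upper, draws, f, n, config.alpha, config.tail_rule
                ),
            })
    return ResamplingTestResult(
        cells=pd.DataFrame(rows), config=config,
        reference_period=ref, method="monte_carlo",
    )


def exact_test_oracle(table: HaplotypeTable, config: TestConfig) -> ResamplingTestResult:
    """Closed-form version of :func:`resampling_test`.

    The Monte-Carlo null is exactly Binomial(n_p, f_h), so the tail
    probabilities are binomial CDF values; no randomness is involved.
    """
    ref, freqs, is_sub = _reference_frequencies(table, config)
    periods = _test_periods(table, ref)
    rows = []
    for hap in table.labels:
        f = float(freqs[hap])
        for period in periods:
            n = int(table.column(period).sum())
            obs = int(table.counts.loc[hap, period])
            lower = float(stats.binom.cdf(obs, n, f))
            upper = float(stats.binom.sf(obs - 1, n, f))
            rows.append({
                "haplotype": hap,
                "period": period,
                "observed": obs,
                "n": n,
                "ref_freq": f,
                "substitute": bool(is_sub[hap]),
                "lower_tail": lower,
                "upper_tail": upper,
                "significant": _significant(
                    obs, lower, upper, None, f, n, config.alpha, config.tail_rule
                ),
            })
    return ResamplingTestResult(
        cells=pd.DataFrame(rows), config=config,
        reference_period=ref, method="exact",
    )


def count_significant(result: ResamplingTestResult) -> tuple[int, int]:
    """(number of significant cells, number of haplotypes with >= 1)."""
    sig = result.cells[result.cells["significant"]]
    return len(sig), sig["haplotype"].nunique()


def meta_binomial(
    n_tests: int, n_significant: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Expected chance significances and P(at least the observed number).

    Treats the per-cell tests as independent Bernoulli(alpha) trials:
    returns (n_tests * alpha, P[X >= n_significant]) for
    X ~ Binomial(n_tests, alpha).
    """
    if not 0 <= n_significant <= n_tests:
        raise InputError("n_significant must be in [0, n_tests]")
    expected = n_tests * alpha
    p_at_least = float(stats.binom.sf(n_significant - 1, n_tests, alpha))
    return expected, p_at_least


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    low_expected_flag: bool  # >20% of expected cells below 5
    expected: np.ndarray = field(repr=False, default=None)


def chi_square_homogeneity(cont_table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity on a contingency table.

    Flags the result when more than 20% of the expected cell counts fall
    below 5, the usual validity rule of thumb for the chi-square
    approximation.
    """
    arr = np.asarray(cont_table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise InputError("negative counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise InputError("zero marginal row or column")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    frac_low = np.mean(expected < 5)
    return ChiSquareResult(
        statistic=float(chi2), df=int(df), p=float(p),
        low_expected_flag=bool(frac_low > 0.2), expected=expected,
    )


@dataclass
class RarefactionCurve:
    """Expected haplotype richness across sample sizes for one period."""

    m_grid: np.ndarray
    richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    asymptote: float  # bias-corrected Chao1
    n: int
    observed_richness: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "m": self.m_grid,
            "richness": self.richness,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness estimate from a count vector.

    S_obs + f1^2 / (2 f2) when doubletons exist, else the bias-corrected
    form S_obs + f1 (f1 - 1) / 2 (with the (f2 + 1) denominator collapsing
    to 1 at f2 = 0).
    """
    c = np.asarray([x for x in counts if x > 0], dtype=int)
    s_obs = len(c)
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def _rarefy_expected(counts: np.ndarray, m: int) -> float:
    """Hurlbert expectation: sum_h 1 - C(n - n_h, m) / C(n, m)."""
    n = int(counts.sum())
    if m > n:
        raise ValueError("interpolation requires m <= n")
    # log-space binomial ratio; C(n - n_h, m) = 0 when n - n_h < m
    total = 0.0
    for nh in counts:
        rem = n - int(nh)
        if rem < m:
            total += 1.0
        else:
            log_ratio = (
                gammaln(rem + 1) - gammaln(m + 1) - gammaln(rem - m + 1)
                - (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
            )
            total += 1.0 - float(np.exp(log_ratio))
    return total


def _extrapolate(counts: np.ndarray, m: int) -> float:
    """Chao1-anchored extrapolation to m > n individuals.

    S(n + m*) = S_obs + f0 [1 - (1 - f1 / (n f0 + f1))^m*], with f0 the
    Chao1 estimate of the number of undetected haplotypes.
    """
    n = int(counts.sum())
    s_obs = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f0 = chao1(counts) - s_obs
    m_star = m - n
    if f0 <= 0 or f1 == 0:
        return float(s_obs)
    return s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** m_star)


def rarefy_richness(
    counts: Sequence[int],
    m_grid: Sequence[int],
    n_boot: int = 200,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve of haplotype richness.

    For m <= n the expected richness in a subsample of m individuals
    drawn without replacement (hypergeometric interpolation); for m > n
    extrapolation toward the bias-corrected Chao1 asymptote.  Percentile
    bootstrap confidence bounds come from resampling individuals with
    replacement ``n_boot`` times.
    """
    c = np.asarray(counts, dtype=int)
    c = c[c > 0]
    n = int(c.sum())
    if n < 1:
        raise InputError("empty sample")
    m_arr = np.asarray(m_grid, dtype=int)
    if (m_arr <= 0).any():
        raise InputError("sample sizes in m_grid must be positive")

    def curve(cnt: np.ndarray) -> np.ndarray:
        nn = int(cnt.sum())
        return np.array([
            _rarefy_expected(cnt, m) if m <= nn else _extrapolate(cnt, m)
            for m in m_arr
        ])

    richness = curve(c)
    rng = np.random.default_rng(seed)
    individuals = np.repeat(np.arange(len(c)), c)
    boot = np.empty((n_boot, len(m_arr)))
    for b in range(n_boot):
        draw = rng.choice(individuals, size=n, replace=True)
        cnt = np.bincount(draw, minlength=len(c))
        boot[b] = curve(cnt)
    ci_low = np.quantile(boot, 0.025, axis=0)
    ci_high = np.quantile(boot, 0.975, axis=0)
    return RarefactionCurve(
        m_grid=m_arr, richness=richness, ci_low=ci_low, ci_high=ci_high,
        asymptote=chao1(c), n=n, observed_richness=int(np.sum(c > 0)),
    )


@dataclass(frozen=True)
class DiversityStats:
    haplotype_diversity: float
    nucleotide_diversity: float | None


def diversity(
    counts: Sequence[int],
    catalog: HaplotypeCatalog | None = None,
    labels: Sequence[str] | None = None,
    gap_mode: Literal["fifth_state", "ignore"] = "ignore",
) -> DiversityStats:
    """Haplotype diversity h and (optionally) nucleotide diversity pi.

    h = n/(n-1) (1 - sum p_i^2), the unbiased gene-diversity estimator.
    pi is the mean per-site pairwise difference over all sample pairs and
    requires the haplotype sequences (``catalog`` plus the ``labels``
    matching ``counts``); gap columns are handled per ``gap_mode``.
    """
    c = np.asarray(counts, dtype=int)
    n = int(c.sum())
    if n < 2:
        raise InputError("need at least 2 samples for diversity")
    p = c / n
    h = (n / (n - 1)) * (1.0 - float(np.sum(p * p)))

    pi = None
    if catalog is not None:
        if labels is None:
            labels = list(catalog.labels)[: len(c)]
        if len(labels) != len(c):
            raise InputError("labels and counts differ in length")
        seqs = [catalog.sequence(lab) for lab in labels]
        length = len(seqs[0])
        num = 0.0
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                if c[i] and c[j]:
                    d = pairwise_distance(seqs[i], seqs[j], gap_mode)
                    num += c[i] * c[j] * d / length
        pi = num / (n * (n - 1) / 2)
    return DiversityStats(haplotype_diversity=h, nucleotide_diversity=pi)
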