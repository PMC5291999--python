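"""Normality-gated comparison and correlation battery.

Every scalar variable first passes a Kolmogorov-Smirnov normality gate
(one-sample KS against a normal with the sample's own mean and SD — the
classic SPSS-style usage; the Lilliefors caveat that this inflates the gate's
p-values is logged once).  The gate decides the branch:

* two groups — independent t-test (parametric) or Mann-Whitney U;
* three groups — one-way ANOVA with LSD post-hoc (pairwise t on the pooled
  within-group variance, uncorrected, only after a significant omnibus), or
  Kruskal-Wallis with pairwise Mann-Whitney at Bonferroni-corrected alpha/3;
* association — Pearson (both variables parametric) or Spearman.

All tests are two-sided.  95 % CIs use the t distribution.  Groups below the
configured minimum size are reported as skipped, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .errors import ContractError, UndefinedCorrelationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    min_group_size: int = 5     # groups below this skip hypothesis testing
    gate_min_n: int = 5         # below this the gate forces nonparametric
    gate_per_group: bool = True  # gate each group; any failure -> nonparametric


@dataclass
class GateResult:
    is_parametric: bool
    statistic: float
    p_value: float
    note: str = ""


def normality_gate(sample: Sequence[float], config: StatsConfig = StatsConfig()
                   ) -> GateResult:
    """One-sample KS test of ``sample`` against N(sample mean, sample sd).

    ``is_parametric`` iff p >= alpha.  Degenerate samples (n below
    ``gate_min_n`` or zero SD) force the nonparametric branch with a note.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < config.gate_min_n:
        log.warning("normality gate: n=%d below %d; forcing nonparametric",
                    x.size, config.gate_min_n)
        return GateResult(False, np.nan, np.nan, note=f"n={x.size} too small")
    sd = x.std(ddof=1)
    if sd == 0:
        return GateResult(False, np.nan, np.nan, note="zero variance")
    stat, p = _stats.kstest(x, "norm", args=(x.mean(), sd))
    return GateResult(bool(p >= config.alpha), float(stat), float(p))


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    ci95: tuple[float, float]
    median: float

    @classmethod
    def from_values(cls, label: str, values: np.ndarray) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        mean = float(values.mean()) if values.size else np.nan
        half = 0.0
        if values.size > 1:
            sd = values.std(ddof=1)
            half = float(_stats.t.ppf(0.975, values.size - 1)
                         * sd / np.sqrt(values.size))
        return cls(label=label, n=int(values.size), mean=mean,
                   ci95=(mean - half, mean + half),
                   median=float(np.median(values)) if values.size else np.nan)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    p_raw: float
    p_corrected: float
    significant: bool


@dataclass
class ComparisonResult:
    variable: str
    groups: list[GroupSummary]
    test: str                      # t | mann-whitney | anova-lsd | kruskal-mw-bonferroni
    statistic: float
    p_value: float
    parametric: bool
    posthoc: list[PairwiseResult] = field(default_factory=list)
    skipped: bool = False
    note: str = ""
    family: str = ""  # comparison family (which deformity's grid row)

    @property
    def significant(self) -> bool:
        return (not self.skipped) and self.p_value < 0.05


def _gate_groups(groups: Mapping[str, np.ndarray], config: StatsConfig) -> bool:
    """True when every group (or the pooled sample) passes the gate."""
    if config.gate_per_group:
        return all(normality_gate(v, config).is_parametric
                   for v in groups.values())
    pooled = np.concatenate([np.asarray(v, dtype=float)
                             for v in groups.values()])
    return normality_gate(pooled, config).is_parametric


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       labels: tuple[str, str] = ("group_a", "group_b"),
                       variable: str = "",
                       config: StatsConfig = StatsConfig(),
                       parametric: bool | None = None) -> ComparisonResult:
    """Independent t-test or Mann-Whitney U, chosen by the normality gate.

    ``parametric`` overrides the gate when given (used for forced-branch
    oracle checks).  Groups below ``min_group_size`` yield a descriptive-only
    result flagged as skipped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    summaries = [GroupSummary.from_values(labels[0], a),
                 GroupSummary.from_values(labels[1], b)]
    if min(a.size, b.size) < config.min_group_size:
        return ComparisonResult(variable=variable, groups=summaries, test="none",
                                statistic=np.nan, p_value=np.nan,
                                parametric=False, skipped=True,
                                note="insufficient comparator group")
    if parametric is None:
        parametric = _gate_groups({labels[0]: a, labels[1]: b}, config)
    if parametric:
        stat, p = _stats.ttest_ind(a, b, equal_var=True)
        test = "t"
    else:
        stat, p = _stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    return ComparisonResult(variable=variable, groups=summaries, test=test,
                            statistic=float(stat), p_value=float(p),
                            parametric=parametric)


def compare_three_groups(groups: Mapping[str, Sequence[float]],
                         variable: str = "",
                         config: StatsConfig = StatsConfig(),
                         parametric: bool | None = None) -> ComparisonResult:
    """One-way ANOVA + LSD post-hoc, or Kruskal-Wallis + Bonferroni MW.

    LSD (least significant difference) post-hoc is pairwise t on the pooled
    within-group mean square with N - k degrees of freedom, uncorrected —
    applied only when the omnibus is significant.  The nonparametric branch
    runs pairwise Mann-Whitney tests at alpha / (number of pairs), and also
    reports Bonferroni-corrected p-values (min(1, k*p)).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) != 3:
        raise ContractError(f"expected 3 groups, got {len(arrays)}")
    summaries = [GroupSummary.from_values(k, v) for k, v in arrays.items()]
    if min(v.size for v in arrays.values()) < config.min_group_size:
        return ComparisonResult(variable=variable, groups=summaries, test="none",
                                statistic=np.nan, p_value=np.nan,
                                parametric=False, skipped=True,
                                note="insufficient comparator group")
    if parametric is None:
        parametric = _gate_groups(arrays, config)
    values = list(arrays.values())
    labels = list(arrays)
    posthoc: list[PairwiseResult] = []
    if parametric:
        stat, p = _stats.f_oneway(*values)
        if p < config.alpha:
            n_total = sum(v.size for v in values)
            mse = (sum((v.size - 1) * v.var(ddof=1) for v in values)
                   / (n_total - len(values)))
            df = n_total - len(values)
            for (la, va), (lb, vb) in combinations(zip(labels, values), 2):
                t = (va.mean() - vb.mean()) / np.sqrt(
                    mse * (1.0 / va.size + 1.0 / vb.size))
                p_pair = float(2.0 * _stats.t.sf(abs(t), df))
                posthoc.append(PairwiseResult(
                    pair=(la, lb), p_raw=p_pair, p_corrected=p_pair,
                    significant=p_pair < config.alpha))
        test = "anova-lsd"
    else:
        stat, p = _stats.kruskal(*values)
        n_pairs = len(list(combinations(labels, 2)))
        for (la, va), (lb, vb) in combinations(zip(labels, values), 2):
            _, p_pair = _stats.mannwhitneyu(va, vb, alternative="two-sided")
            corrected = min(1.0, n_pairs * float(p_pair))
            posthoc.append(PairwiseResult(
                pair=(la, lb), p_raw=float(p_pair), p_corrected=corrected,
                significant=p_pair < config.alpha / n_pairs))
        test = "kruskal-mw-bonferroni"
    return ComparisonResult(variable=variable, groups=summaries, test=test,
                            statistic=float(stat), p_value=float(p),
                            parametric=parametric, posthoc=posthoc)


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str                   # pearson | spearman
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def correlate(x: Sequence[float], y: Sequence[float],
              pair: tuple[str, str] = ("x", "y"),
              config: StatsConfig = StatsConfig(),
              parametric: bool | None = None) -> CorrelationResult:
    """Pearson (both variables pass the gate) or Spearman correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ContractError("correlate needs paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {pair[0] if x.std() == 0 else pair[1]!r}")
    if parametric is None:
        parametric = (normality_gate(x, config).is_parametric
                      and normality_gate(y, config).is_parametric)
    if parametric:
        r, p = _stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = _stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(pair=pair, method=method, r=float(r),
                             p_value=float(p), n=int(x.size))
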