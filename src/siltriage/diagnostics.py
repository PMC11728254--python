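"""Diagnostic-accuracy statistics for ordinal severity scores.

Everything needed to evaluate a "higher is worse" score against a binary
in-hospital mortality outcome: 2x2 statistics at a cutoff, binomial
confidence intervals, prevalence-adjusted predictive values, empirical
ROC/AUC with DeLong or bootstrap confidence intervals, paired AUC
comparison, odds ratios, chi-square tests, and per-score-value mortality
strata.

A positive test is always defined as ``score >= cutoff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError, UndefinedValueError

__all__ = [
    "ConfusionCounts",
    "AccuracyReport",
    "AucEstimate",
    "Stratum",
    "StratumTable",
    "AssociationResult",
    "dichotomize",
    "sens_spec",
    "prevalence_adjusted_pv",
    "empirical_auc",
    "auc_ci",
    "compare_auc",
    "odds_ratio_2x2",
    "chi_square_2x2",
    "stratum_mortality",
    "expected_vs_found",
    "roc_points",
    "youden_cutoff",
    "accuracy_report",
]

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(name, "counts must be non-negative")

    @property
    def deaths(self) -> int:
        return self.tp + self.fn

    @property
    def survivors(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyReport:
    """Operating characteristics of a score dichotomized at ``cutoff``."""

    cutoff: float
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    ppv: float
    npv: float
    prevalence: float
    counts: ConfusionCounts


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self):
        if not (self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise InvalidInputError("auc", "point estimate must lie inside its CI")


@dataclass(frozen=True)
class Stratum:
    score_value: int
    n_total: int
    n_deaths: int
    expected_mortality: Optional[float] = None  # percent

    def __post_init__(self):
        if self.n_deaths > self.n_total:
            raise InvalidInputError("n_deaths", "cannot exceed n_total")
        if self.n_total < 0 or self.n_deaths < 0:
            raise InvalidInputError("n_total", "counts must be non-negative")


@dataclass(frozen=True)
class StratumTable:
    """Ordered per-score-value counts of patients and deaths."""

    strata: Tuple[Stratum, ...] = field(default_factory=tuple)

    def __init__(self, strata: Iterable[Stratum]):
        object.__setattr__(
            self, "strata",
            tuple(sorted(strata, key=lambda s: s.score_value)),
        )

    def __iter__(self):
        return iter(self.strata)

    def __len__(self):
        return len(self.strata)

    @property
    def n(self) -> int:
        return sum(s.n_total for s in self.strata)

    @property
    def deaths(self) -> int:
        return sum(s.n_deaths for s in self.strata)

    def expand(self) -> Tuple[np.ndarray, np.ndarray]:
        """Per-patient (scores, outcomes) arrays realizing the counts."""
        scores, outcomes = [], []
        for s in self.strata:
            scores.extend([s.score_value] * s.n_total)
            outcomes.extend([1] * s.n_deaths + [0] * (s.n_total - s.n_deaths))
        return np.asarray(scores), np.asarray(outcomes)

    @classmethod
    def from_records(cls, scores, outcomes) -> "StratumTable":
        scores = np.asarray(scores)
        outcomes = np.asarray(outcomes)
        return cls(
            Stratum(
                score_value=int(v),
                n_total=int(np.sum(scores == v)),
                n_deaths=int(np.sum(outcomes[scores == v])),
            )
            for v in np.unique(scores)
        )


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


# ---------------------------------------------------------------------------
# 2x2 statistics
# ---------------------------------------------------------------------------

def _aligned(scores, outcomes):
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes)
    if scores.size == 0:
        raise InvalidInputError("scores", "must not be empty")
    if scores.shape != outcomes.shape:
        raise InvalidInputError("outcomes", "length does not match scores")
    if not np.isin(outcomes, (0, 1)).all():
        raise InvalidInputError("outcomes", "must be binary 0/1")
    return scores, outcomes.astype(int)


def dichotomize(scores, outcomes, cutoff: float) -> ConfusionCounts:
    """Count the 2x2 table with positive test defined as score >= cutoff."""
    scores, outcomes = _aligned(scores, outcomes)
    positive = scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(positive & (outcomes == 1))),
        fp=int(np.sum(positive & (outcomes == 0))),
        fn=int(np.sum(~positive & (outcomes == 1))),
        tn=int(np.sum(~positive & (outcomes == 0))),
    )


def _proportion_ci(k: int, n: int, method: str) -> Tuple[float, float]:
    if method == "wald":
        p = k / n
        half = _Z95 * math.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    if method in ("wilson", "beta"):
        lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
        return (float(lo), float(hi))
    raise InvalidInputError("ci_method", f"unknown CI method {method!r}")


def sens_spec(counts: ConfusionCounts, ci_method: str = "wald"):
    """Sensitivity and specificity with binomial 95% CIs.

    Returns ``(sensitivity, sens_ci, specificity, spec_ci)``.  Wald
    intervals (clipped to [0, 1]) by default; ``ci_method="wilson"`` is
    available.
    """
    if counts.deaths < 1:
        raise UndefinedValueError("sensitivity undefined: no deaths")
    if counts.survivors < 1:
        raise UndefinedValueError("specificity undefined: no survivors")
    sens = counts.tp / counts.deaths
    spec = counts.tn / counts.survivors
    return (
        sens,
        _proportion_ci(counts.tp, counts.deaths, ci_method),
        spec,
        _proportion_ci(counts.tn, counts.survivors, ci_method),
    )


def prevalence_adjusted_pv(
    sensitivity: float, specificity: float, prevalence: float
) -> Tuple[float, float]:
    """Predictive values adjusted to a stated prevalence (Bayes' theorem).

    ppv = sens*prev / (sens*prev + (1-spec)*(1-prev))
    npv = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev)
    """
    for name, v in (("sensitivity", sensitivity),
                    ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0 <= v <= 1:
            raise InvalidInputError(name, "must lie in [0, 1]")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    if ppv_den == 0 or npv_den == 0:
        raise UndefinedValueError(
            "predictive value undefined: zero post-test denominator"
        )
    ppv = sensitivity * prevalence / ppv_den
    npv = specificity * (1 - prevalence) / npv_den
    return ppv, npv


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def empirical_auc(table_or_scores, outcomes=None) -> float:
    """Empirical AUC: P(case scores higher than control), ties counted half.

    Accepts either a :class:`StratumTable` or per-patient
    ``(scores, outcomes)``.  Equivalent to the trapezoidal area under the
    empirical ROC of a discrete ordinal score.
    """
    if isinstance(table_or_scores, StratumTable):
        scores, outcomes = table_or_scores.expand()
    else:
        scores = table_or_scores
    scores, outcomes = _aligned(scores, outcomes)
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    if cases.size == 0 or controls.size == 0:
        raise UndefinedValueError("AUC undefined: need both outcome classes")
    # rank-sum formulation handles ties exactly and runs in O(n log n)
    ranks = stats.rankdata(scores)
    rank_sum = ranks[outcomes == 1].sum()
    m = cases.size
    return float((rank_sum - m * (m + 1) / 2) / (m * controls.size))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_covariance(score_list: Sequence[np.ndarray], outcomes: np.ndarray):
    """AUCs and the DeLong covariance matrix for paired score vectors."""
    pos = outcomes == 1
    m = int(pos.sum())
    n = int((~pos).sum())
    if m == 0 or n == 0:
        raise UndefinedValueError("AUC undefined: need both outcome classes")
    k = len(score_list)
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for i, sc in enumerate(score_list):
        x, y = sc[pos], sc[~pos]
        tx, ty = _midrank(x), _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[i] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[i] = (tz[:m] - tx) / n
        v01[i] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10, bias=False) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01, bias=False) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


def auc_ci(
    scores,
    outcomes,
    method: str = "delong",
    reps: int = 1000,
    seed: Optional[int] = None,
) -> AucEstimate:
    """AUC with a 95% confidence interval.

    ``method="delong"`` (default) gives the asymptotic nonparametric CI;
    ``method="bootstrap"`` gives a seeded percentile CI over ``reps``
    patient resamples.
    """
    scores, outcomes = _aligned(scores, outcomes)
    point = empirical_auc(scores, outcomes)
    if method == "delong":
        aucs, cov = _delong_covariance([scores], outcomes)
        se = math.sqrt(max(cov[0, 0], 0.0))
        lo = max(0.0, point - _Z95 * se)
        hi = min(1.0, point + _Z95 * se)
        return AucEstimate(point, lo, hi, "delong")
    if method == "bootstrap":
        if reps < 1:
            raise InvalidInputError("reps", "must be >= 1")
        rng = np.random.default_rng(seed)
        n = scores.size
        vals = []
        while len(vals) < reps:
            idx = rng.integers(0, n, size=n)
            out = outcomes[idx]
            if out.min() == out.max():  # resample lost a class; redraw
                continue
            vals.append(empirical_auc(scores[idx], out))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return AucEstimate(point, min(float(lo), point), max(float(hi), point),
                           "bootstrap")
    raise InvalidInputError("method", f"unknown CI method {method!r}")


def compare_auc(scores_a, scores_b, outcomes) -> float:
    """Two-sided paired DeLong test p-value for equality of two AUCs."""
    scores_a, outcomes = _aligned(scores_a, outcomes)
    scores_b, _ = _aligned(scores_b, outcomes)
    aucs, cov = _delong_covariance([scores_a, scores_b], outcomes)
    delta = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-16:
        return 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def roc_points(scores, outcomes) -> pd.DataFrame:
    """Empirical ROC as a (cutoff, fpr, tpr) table over all distinct cutoffs.

    Includes the (1, 1) and (0, 0) endpoints (cutoffs -inf and +inf).
    """
    scores, outcomes = _aligned(scores, outcomes)
    cutoffs = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    rows = []
    deaths = outcomes.sum()
    survivors = outcomes.size - deaths
    if deaths == 0 or survivors == 0:
        raise UndefinedValueError("ROC undefined: need both outcome classes")
    for c in cutoffs:
        positive = scores >= c
        rows.append({
            "cutoff": c,
            "tpr": float(np.sum(positive & (outcomes == 1)) / deaths),
            "fpr": float(np.sum(positive & (outcomes == 0)) / survivors),
        })
    return pd.DataFrame(rows)


def youden_cutoff(scores, outcomes) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties resolve to the lowest qualifying cutoff.
    """
    scores, outcomes = _aligned(scores, outcomes)
    best_cut, best_j = None, -np.inf
    for c in np.unique(scores):
        counts = dichotomize(scores, outcomes, c)
        sens = counts.tp / counts.deaths
        spec = counts.tn / counts.survivors
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_cut, best_j = float(c), j
    return best_cut


def accuracy_report(
    scores,
    outcomes,
    cutoff: Optional[float] = None,
    prevalence: Optional[float] = None,
    ci_method: str = "wald",
) -> AccuracyReport:
    """Full operating-characteristic report at one cutoff.

    ``cutoff=None`` selects the Youden-optimal cutoff.  Predictive values
    are prevalence-adjusted; ``prevalence=None`` uses the sample
    prevalence, which makes them coincide with the raw-count formulas.
    """
    scores, outcomes = _aligned(scores, outcomes)
    if cutoff is None:
        cutoff = youden_cutoff(scores, outcomes)
    counts = dichotomize(scores, outcomes, cutoff)
    sens, sens_ci, spec, spec_ci = sens_spec(counts, ci_method=ci_method)
    if prevalence is None:
        prevalence = counts.deaths / counts.n
    ppv, npv = prevalence_adjusted_pv(sens, spec, prevalence)
    return AccuracyReport(
        cutoff=float(cutoff),
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def odds_ratio_2x2(
    exposed_deaths: int,
    exposed_survivors: int,
    unexposed_deaths: int,
    unexposed_survivors: int,
) -> AssociationResult:
    """Cross-product odds ratio with a Wald log-scale 95% CI.

    Applies the Haldane-Anscombe 0.5 correction to every cell when any
    cell is zero.  The p-value is the Yates-corrected chi-square.
    """
    a, b, c, d = (exposed_deaths, exposed_survivors,
                  unexposed_deaths, unexposed_survivors)
    for name, v in zip(("exposed_deaths", "exposed_survivors",
                        "unexposed_deaths", "unexposed_survivors"),
                       (a, b, c, d)):
        if v < 0:
            raise InvalidInputError(name, "counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise UndefinedValueError("odds ratio undefined: zero table margin")
    p_value = chi_square_2x2(a, b, c, d)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return AssociationResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - _Z95 * se),
        ci_high=math.exp(log_or + _Z95 * se),
        p_value=p_value,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = True) -> float:
    """Pearson chi-square p-value for a 2x2 table.

    Yates continuity correction is applied by default, matching the R
    default the source analysis used.
    """
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedValueError("chi-square undefined: zero table margin")
    result = stats.chi2_contingency(table, correction=correction)
    return float(result.pvalue)


# ---------------------------------------------------------------------------
# stratum tables
# ---------------------------------------------------------------------------

def stratum_mortality(
    table: StratumTable,
    subgroups: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> dict:
    """Observed mortality per stratum and overall, as percentages.

    ``subgroups`` maps a label to ``(deaths, total)`` counts for extra
    margins (e.g. diagnosis classes) reported alongside.  The result also
    carries a monotonicity flag: whether per-stratum mortality never
    decreases as the score rises.
    """
    if len(table) == 0:
        raise InvalidInputError("table", "must contain at least one stratum")
    per_stratum = {
        s.score_value: 100.0 * s.n_deaths / s.n_total if s.n_total else float("nan")
        for s in table
    }
    rates = [per_stratum[s.score_value] for s in table if s.n_total]
    out = {
        "per_stratum": per_stratum,
        "overall": 100.0 * table.deaths / table.n,
        "monotone_increasing": all(
            rates[i] <= rates[i + 1] + 1e-12 for i in range(len(rates) - 1)
        ),
    }
    for label, (deaths, total) in (subgroups or {}).items():
        out[label] = 100.0 * deaths / total
    return out


def expected_vs_found(table: StratumTable) -> pd.DataFrame:
    """Expected vs observed mortality per stratum with exact binomial CIs.

    Requires every stratum to carry ``expected_mortality`` (percent).
    CIs on the observed percentage are Clopper-Pearson.
    """
    if any(s.expected_mortality is None for s in table):
        raise InvalidInputError("expected_mortality",
                                "every stratum needs an expected percentage")
    rows = []
    for s in table:
        found = 100.0 * s.n_deaths / s.n_total
        lo, hi = proportion_confint(s.n_deaths, s.n_total, alpha=0.05, method="beta")
        rows.append({
            "score_value": s.score_value,
            "n_total": s.n_total,
            "n_deaths": s.n_deaths,
            "expected_pct": s.expected_mortality,
            "found_pct": found,
            "found_ci_low_pct": 100.0 * lo,
            "found_ci_high_pct": 100.0 * hi,
            "difference_pct": found - s.expected_mortality,
        })
    return pd.DataFrame(rows)
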