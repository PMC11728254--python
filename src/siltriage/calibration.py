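"""Bootstrap calibration curves for discrete severity scores.

The construction: fit a single-predictor logistic model of death on the
score, group patients by score value (merging sparse bins), then
bootstrap the per-bin observed mortality to get percentile uncertainty
bands around the predicted-vs-observed comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError, UndefinedValueError

__all__ = ["CalibrationBin", "CalibrationCurve", "fit_calibration"]

#: Bins smaller than this are merged with the adjacent lower bin.
MIN_BIN_SIZE = 5


@dataclass(frozen=True)
class CalibrationBin:
    label: str
    score_values: Tuple[float, ...]
    n: int
    mean_predicted: float
    observed: float
    band_low: float
    band_high: float


@dataclass(frozen=True)
class CalibrationCurve:
    bins: Tuple[CalibrationBin, ...]
    reps: int
    seed: int
    intercept: float
    slope: float
    merged_bins: Tuple[str, ...]  # merge events, for the run log

    @property
    def n(self) -> int:
        return sum(b.n for b in self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [b.label for b in self.bins],
                "n": [b.n for b in self.bins],
                "mean_predicted": [b.mean_predicted for b in self.bins],
                "observed": [b.observed for b in self.bins],
                "band_low": [b.band_low for b in self.bins],
                "band_high": [b.band_high for b in self.bins],
            }
        )


def _merge_sparse(values: np.ndarray, counts: np.ndarray) -> Tuple[List[List[float]], List[str]]:
    """Group score values so every group holds >= MIN_BIN_SIZE patients.

    A sparse group joins the adjacent lower group; a sparse lowest group
    joins the one above it.  Returns the groups and a log of merges.
    """
    groups: List[List[float]] = []
    sizes: List[int] = []
    log: List[str] = []
    for v, c in zip(values, counts):
        if groups and sizes[-1] < MIN_BIN_SIZE:
            log.append(f"merged score {v} into bin {groups[-1][0]} (n={sizes[-1]})")
            groups[-1].append(v)
            sizes[-1] += c
        else:
            groups.append([v])
            sizes.append(c)
    if len(groups) > 1 and sizes[-1] < MIN_BIN_SIZE:
        log.append(
            f"merged trailing bin {groups[-1][0]} (n={sizes[-1]}) into bin {groups[-2][0]}"
        )
        groups[-2].extend(groups.pop())
        sizes[-2] += sizes.pop()
    return groups, log


def fit_calibration(
    scores,
    outcomes,
    reps: int = 1000,
    seed: Optional[int] = None,
) -> CalibrationCurve:
    """Predicted vs observed mortality per score bin with bootstrap bands.

    Fits ``P(death) = logit^-1(a + b * score)``, bins patients by score
    value (sparse bins merged downward), and for ``reps`` seeded
    resamples with replacement recomputes each bin's observed mortality;
    the 2.5/97.5 percentiles of those replicates form the bands.
    """
    if reps < 1:
        raise InvalidInputError("reps", "must be >= 1")
    if seed is None:
        raise InvalidInputError("seed", "a seed is required for reproducibility")
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores.shape != outcomes.shape or scores.size == 0:
        raise InvalidInputError("scores", "scores/outcomes must be aligned, non-empty")
    if outcomes.min() == outcomes.max():
        raise UndefinedValueError("calibration undefined: need both outcome classes")

    model = sm.GLM(outcomes, sm.add_constant(scores), family=sm.families.Binomial())
    fit = model.fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    predicted = np.asarray(fit.fittedvalues)

    values, counts = np.unique(scores, return_counts=True)
    groups, merge_log = _merge_sparse(values, counts)
    bin_index = np.full(scores.size, -1, dtype=int)
    for gi, group in enumerate(groups):
        bin_index[np.isin(scores, group)] = gi
    n_bins = len(groups)

    rng = np.random.default_rng(seed)
    n = scores.size
    boot = np.full((reps, n_bins), np.nan)
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        bi = bin_index[idx]
        tot = np.bincount(bi, minlength=n_bins)
        dead = np.bincount(bi, weights=outcomes[idx], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            boot[r] = np.where(tot > 0, dead / np.maximum(tot, 1), np.nan)
    band_low = np.nanpercentile(boot, 2.5, axis=0)
    band_high = np.nanpercentile(boot, 97.5, axis=0)

    bins = []
    for gi, group in enumerate(groups):
        mask = bin_index == gi
        label = (
            f"{group[0]:g}" if len(group) == 1
            else f"{min(group):g}-{max(group):g}"
        )
        bins.append(
            CalibrationBin(
                label=label,
                score_values=tuple(group),
                n=int(mask.sum()),
                mean_predicted=float(predicted[mask].mean()),
                observed=float(outcomes[mask].mean()),
                band_low=float(band_low[gi]),
                band_high=float(band_high[gi]),
            )
        )
    return CalibrationCurve(
        bins=tuple(bins),
        reps=reps,
        seed=seed,
        intercept=intercept,
        slope=slope,
        merged_bins=tuple(merge_log),
    )
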