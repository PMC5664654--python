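"""Outcome and exposure construction for longitudinal survey cohorts.

Battery scoring (mean/sum aggregation with reverse coding, per-battery
missingness caps and optional relationship-domain averaging), adverse-category
dichotomization, outcome outlier exclusion, and the rank-based inverse-normal
transform used in sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BatterySpec",
    "STANDARD_BATTERIES",
    "compute_battery_score",
    "score_battery_frame",
    "dichotomize_exposure",
    "filter_bmi_outliers",
    "OutlierReport",
    "inverse_normal_transform",
]


@dataclass(frozen=True)
class BatterySpec:
    """Scoring rules for one questionnaire battery.

    Parameters
    ----------
    name
        Battery label (e.g., ``"ANGERIN"``).
    n_items
        Number of items (per relationship domain when ``domains`` is set).
    scale_min, scale_max
        Integer response bounds; responses outside raise a validation error.
    reverse_items
        1-based indices of items to reverse-code (``v -> min + max - v``)
        before aggregation.
    aggregation
        ``"mean"`` or ``"sum"`` over non-missing items.
    max_missing
        Largest number of missing items tolerated before the (domain) score
        becomes missing.
    domains
        If set, the battery is asked once per relationship domain and the
        final score is the average of non-missing domain scores.
    """

    name: str
    n_items: int
    scale_min: int
    scale_max: int
    reverse_items: tuple[int, ...] = ()
    aggregation: Literal["mean", "sum"] = "mean"
    max_missing: int = 0
    domains: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing < self.n_items):
            raise ValueError(
                f"{self.name}: max_missing must satisfy 0 <= max_missing < n_items"
            )
        bad = [i for i in self.reverse_items if not 1 <= i <= self.n_items]
        if bad:
            raise ValueError(f"{self.name}: reverse_items out of range: {bad}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(
                f"{self.name}: unknown aggregation {self.aggregation!r}"
            )


#: Scoring rules for the nine standard exposures.  CSES/ASES are education
#: cut-points, not batteries, so they do not appear here.
STANDARD_BATTERIES: dict[str, BatterySpec] = {
    # trait anger: 4 items, 1-4, mean; missing if >2 items missing
    "ANGERIN": BatterySpec("ANGERIN", 4, 1, 4, aggregation="mean", max_missing=2),
    # state anger: 7 items, 1-4, mean; missing if >3 items missing
    "ANGEROUT": BatterySpec("ANGEROUT", 7, 1, 4, aggregation="mean", max_missing=3),
    # chronic burden: 8 items, 1-4, summed composite
    "BURDEN": BatterySpec("BURDEN", 8, 1, 4, aggregation="sum", max_missing=0),
    # stressful life events: 6 yes/no items, summed count
    "SLE": BatterySpec("SLE", 6, 0, 1, aggregation="sum", max_missing=0),
    # positive social support: 3 items x 4 relationship domains, all reversed,
    # domain mean; domain missing if >1 item missing
    "PSS": BatterySpec(
        "PSS", 3, 1, 4, reverse_items=(1, 2, 3), aggregation="mean",
        max_missing=1, domains=4,
    ),
    # negative social support: 4 items x 4 domains, all reversed, domain mean;
    # domain missing if >2 items missing
    "NSS": BatterySpec(
        "NSS", 4, 1, 4, reverse_items=(1, 2, 3, 4), aggregation="mean",
        max_missing=2, domains=4,
    ),
    # 8 yes/no depressive-symptom items; items 4 and 6 ("happy", "enjoyed
    # life") count when answered no; summed score in 0..8
    "CESD": BatterySpec(
        "CESD", 8, 0, 1, reverse_items=(4, 6), aggregation="sum", max_missing=0
    ),
}


def reverse_code(spec: BatterySpec, responses: np.ndarray) -> np.ndarray:
    """Map reverse-keyed items ``v -> scale_min + scale_max - v`` (an involution)."""
    out = np.asarray(responses, dtype=float).copy()
    for idx in spec.reverse_items:
        out[idx - 1] = spec.scale_min + spec.scale_max - out[idx - 1]
    return out


def _score_one_battery(spec: BatterySpec, responses: np.ndarray) -> float:
    if len(responses) != spec.n_items:
        raise ValueError(
            f"{spec.name}: expected {spec.n_items} responses, got {len(responses)}"
        )
    finite = ~np.isnan(responses)
    bad = finite & (
        (responses < spec.scale_min) | (responses > spec.scale_max)
    )
    if bad.any():
        items = [int(i) + 1 for i in np.flatnonzero(bad)]
        raise ValueError(
            f"{spec.name}: response out of [{spec.scale_min}, {spec.scale_max}] "
            f"at item(s) {items}"
        )
    if (~finite).sum() > spec.max_missing:
        return np.nan
    coded = reverse_code(spec, responses)
    values = coded[finite]
    if spec.aggregation == "mean":
        return float(np.mean(values))
    return float(np.sum(values))


def compute_battery_score(
    spec: BatterySpec, responses: Sequence[float] | np.ndarray
) -> float:
    """Score one battery administration; returns ``nan`` when missing.

    ``responses`` holds per-item values with ``nan`` for missing.  For domain
    batteries it is the concatenation of ``domains`` blocks of ``n_items``
    each; domain scores are averaged over non-missing domains, so a domain
    that was never administered (e.g., no spouse) is skipped rather than
    propagating missingness.
    """
    responses = np.asarray(responses, dtype=float)
    if spec.domains is None:
        return _score_one_battery(spec, responses)
    expected = spec.n_items * spec.domains
    if len(responses) != expected:
        raise ValueError(
            f"{spec.name}: expected {expected} responses "
            f"({spec.domains} domains x {spec.n_items} items), got {len(responses)}"
        )
    domain_scores = [
        _score_one_battery(spec, responses[d * spec.n_items : (d + 1) * spec.n_items])
        for d in range(spec.domains)
    ]
    valid = [s for s in domain_scores if not np.isnan(s)]
    if not valid:
        return np.nan
    return float(np.mean(valid))


def score_battery_frame(
    spec: BatterySpec, frame: pd.DataFrame, item_columns: Sequence[str]
) -> pd.Series:
    """Apply :func:`compute_battery_score` row-wise over ``item_columns``."""
    values = frame[list(item_columns)].to_numpy(dtype=float)
    return pd.Series(
        [compute_battery_score(spec, row) for row in values],
        index=frame.index,
        name=spec.name,
    )


def dichotomize_exposure(
    scores: pd.Series,
    rule: Literal["group_median", "zero_reference", "education_cut"],
    groups: pd.Series | None = None,
    threshold: float = 12.0,
    inclusive: bool = False,
    adverse_low: bool = False,
) -> pd.Series:
    """Map raw exposure scores to 0/1 with 1 = adverse category.

    ``group_median``: 1 iff the score strictly exceeds the within-group median
    pooled over all exams (values at the median are reference).  For scales
    where *low* values are adverse (social support), pass ``adverse_low=True``
    to flip the comparison (1 iff strictly below the pooled median).
    ``zero_reference``: 1 iff score > 0 (count scales).
    ``education_cut``: 1 iff years < ``threshold`` (or <= with
    ``inclusive=True``; adult-education coding uses <= 12).
    Missing scores stay missing.
    """
    scores = pd.to_numeric(scores, errors="raise").astype(float)
    out = pd.Series(np.nan, index=scores.index, name=scores.name)
    valid = scores.notna()

    if rule == "zero_reference":
        out[valid] = (scores[valid] > 0).astype(float)
        return out
    if rule == "education_cut":
        if inclusive:
            out[valid] = (scores[valid] <= threshold).astype(float)
        else:
            out[valid] = (scores[valid] < threshold).astype(float)
        return out
    if rule != "group_median":
        raise ValueError(f"unknown dichotomization rule {rule!r}")

    if groups is None:
        groups = pd.Series("all", index=scores.index)
    groups = groups.reindex(scores.index)
    for label, idx in scores.groupby(groups).groups.items():
        grp = scores.loc[idx]
        grp_valid = grp.dropna()
        if grp_valid.empty:
            raise ValueError(f"group {label!r} has no non-missing scores")
        med = float(grp_valid.median())
        mask = grp.notna()
        if adverse_low:
            out.loc[grp.index[mask]] = (grp[mask] < med).astype(float)
        else:
            out.loc[grp.index[mask]] = (grp[mask] > med).astype(float)
    return out


@dataclass
class OutlierReport:
    """Result of the k-SD outcome outlier rule."""

    mask: pd.Series  # True = retained
    excluded: list  # row labels excluded
    mean: float
    sd: float
    n_sd: float

    @property
    def lower(self) -> float:
        return self.mean - self.n_sd * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.n_sd * self.sd


def filter_bmi_outliers(values: pd.Series, n_sd: float = 6.0) -> OutlierReport:
    """Flag observations farther than ``n_sd`` standard deviations from the mean.

    Mean and SD are computed once on the full pooled non-missing sample (no
    iterative re-computation); the rule is strict (a value exactly at
    mean + ``n_sd``·SD is retained).  Missing values are retained in the mask
    (they carry no outlier evidence) but reported separately by callers.
    """
    values = pd.to_numeric(values, errors="raise").astype(float)
    nonmiss = values.dropna()
    if len(nonmiss) < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(nonmiss.mean())
    sd = float(nonmiss.std(ddof=1))
    dev = (values - mean).abs()
    excluded_mask = dev > n_sd * sd
    excluded_mask = excluded_mask.fillna(False)
    mask = ~excluded_mask
    return OutlierReport(
        mask=mask,
        excluded=list(values.index[excluded_mask]),
        mean=mean,
        sd=sd,
        n_sd=n_sd,
    )


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Maps value of rank r (average rank for ties) among n non-missing values
    to ``Phi^{-1}((r - 3/8) / (n + 1/4))``.  Missing entries stay missing.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    finite = ~np.isnan(arr)
    x = arr[finite]
    if len(np.unique(x)) < 2:
        raise ValueError("inverse-normal transform undefined: <2 distinct values")
    ranks = stats.rankdata(x, method="average")
    out[finite] = stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))
    return out
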