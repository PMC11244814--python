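"""Per-nucleus and per-genotype morphometry summaries.

Covers the routine quantifications reported alongside interference analyses:
focus counts, SC segment numbers and lengths, crossover density per micron of
SC, the linear regression of focus count on SC length, and a two-sample
t comparison between genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, InsufficientDataError, ParameterError, ValidationError
from .interference import adjacent_distances
from .model import Cohort

log = logging.getLogger(__name__)

QUANTITIES = ("focus_count", "total_sc_length", "n_segments", "mean_inter_focus_distance")


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD of one per-nucleus quantity in one genotype."""

    genotype: str
    quantity: str
    n: int
    mean: float
    sd: float
    values: tuple[float, ...]


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least squares of focus count on total SC length."""

    slope: float  # foci per micron
    intercept: float  # foci
    r_squared: float
    n: int


def _nucleus_value(nucleus, quantity: str) -> float:
    if quantity == "focus_count":
        return float(nucleus.total_focus_count)
    if quantity == "total_sc_length":
        return nucleus.total_sc_length
    if quantity == "n_segments":
        return float(nucleus.total_n_segments)
    if quantity == "mean_inter_focus_distance":
        dists: list[float] = []
        for t in nucleus.tracks:
            dists.extend(adjacent_distances(t, within_segments=True))
        return float(np.mean(dists)) if dists else float("nan")
    raise ParameterError(f"unknown quantity {quantity!r}; choose one of {QUANTITIES}")


def summarize(cohort: Cohort, quantity: str) -> GroupSummary:
    """Per-nucleus quantity, summarised as mean and sample SD (n-1 denominator).

    ``mean_inter_focus_distance`` nuclei without any adjacent focus pair are
    excluded from the summary.  A single-nucleus cohort yields sd = 0 with a
    logged warning.
    """
    if cohort.n_nuclei == 0:
        raise InsufficientDataError("summarize needs a non-empty cohort")
    values = [_nucleus_value(nuc, quantity) for nuc in cohort.nuclei]
    values = [v for v in values if not np.isnan(v)]
    if not values:
        raise InsufficientDataError(f"no nucleus provides quantity {quantity!r}")
    arr = np.asarray(values)
    if len(arr) == 1:
        log.warning("summarize(%s): single observation, reporting sd = 0", quantity)
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return GroupSummary(
        genotype=cohort.genotype,
        quantity=quantity,
        n=len(arr),
        mean=float(arr.mean()),
        sd=sd,
        values=tuple(float(v) for v in arr),
    )


def co_density(cohort: Cohort) -> GroupSummary:
    """Crossover foci per micron of SC, per nucleus, summarised over the cohort."""
    if cohort.n_nuclei == 0:
        raise InsufficientDataError("co_density needs a non-empty cohort")
    values = []
    for nuc in cohort.nuclei:
        total = nuc.total_sc_length
        if total <= 0:
            raise ValidationError(f"nucleus {nuc.nucleus_id} has zero SC length")
        values.append(nuc.total_focus_count / total)
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return GroupSummary(
        genotype=cohort.genotype,
        quantity="co_density_per_um",
        n=len(arr),
        mean=float(arr.mean()),
        sd=sd,
        values=tuple(float(v) for v in arr),
    )


def regress_count_on_length(cohort: Cohort) -> RegressionFit:
    """OLS of per-nucleus focus count on total SC length (closed form).

    slope = Sxy / Sxx, intercept = ybar - slope * xbar,
    r_squared = 1 - SSres / SStot.
    """
    if cohort.n_nuclei < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 nuclei, got {cohort.n_nuclei}"
        )
    x = np.asarray([nuc.total_sc_length for nuc in cohort.nuclei])
    y = np.asarray([float(nuc.total_focus_count) for nuc in cohort.nuclei])
    sxx = float(np.sum((x - x.mean()) ** 2))
    # relative threshold so numerically constant designs are caught too
    if sxx <= 1e-20 * len(x) * max(1.0, float(x.mean()) ** 2):
        raise DegenerateSampleError("all SC lengths identical: regression design is degenerate")
    slope = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r_squared, n=len(x))


def two_sample_test(group_a, group_b, flavor: str = "student"):
    """Unpaired two-tailed t test between two value lists.

    ``student`` (default) pools the variances; ``welch`` does not assume
    equal variances.  Returns ``(statistic, dof, p_value)``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if flavor == "student":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif flavor == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ParameterError(f"unknown flavor {flavor!r}; use 'student' or 'welch'")
    return float(res.statistic), float(res.df), float(res.pvalue)
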