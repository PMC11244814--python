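"""Crossover-interference statistics.

Two complementary measures of interference are implemented:

* the shape parameter nu of a gamma distribution fitted by maximum
  likelihood to the distances between adjacent crossover foci (nu = 1
  corresponds to a Poisson, i.e. non-interfering, process; larger nu means
  more even spacing), and
* the coefficient-of-coincidence (CoC) curve: each bivalent is divided into
  equal intervals, and for every pair of intervals the observed frequency of
  bivalents with a crossover in both is divided by the frequency expected
  under independence.  The inter-interval distance at which the curve first
  reaches CoC = 0.5 ("interference distance") summarises interference
  strength as a single length.

The E-distribution (proportion of units carrying exactly k foci) captures
the obligatory-crossover property through its E0 class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma

from .errors import DegenerateSampleError, InsufficientDataError, ParameterError
from .model import FocusTrack

log = logging.getLogger(__name__)

#: sentinel returned when a CoC curve never attains the threshold
NOT_REACHED = "not reached"

SHAPE_MIN = 1e-2
SHAPE_MAX = 1e3


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit to inter-focus spacings."""

    shape: float
    scale: float
    n_spacings: int
    loglik: float
    shape_uncertainty: float
    units_flag: str  # "microns" or "percent_of_axis"


@dataclass(frozen=True)
class CoCPoint:
    distance: float  # inter-interval distance, microns
    coc: float
    n_pairs: int
    n_skipped: int


@dataclass(frozen=True)
class CoCCurve:
    group: str
    n_intervals: int
    interval_length: float  # group-mean interval length, microns
    points: tuple[CoCPoint, ...]
    interference_distance: float | str  # microns, 0.0, or NOT_REACHED


@dataclass(frozen=True)
class EDistribution:
    """Proportions of units (bivalents or SC segments) with exactly k foci."""

    proportions: tuple[float, ...]
    n_units: int

    def __post_init__(self) -> None:
        total = sum(self.proportions)
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"E-distribution proportions sum to {total}, not 1")

    @property
    def e0(self) -> float:
        return self.proportions[0]


# ---------------------------------------------------------------------------
# inter-focus distances


def adjacent_distances(track: FocusTrack, within_segments: bool = True) -> list[float]:
    """Distances between successive foci (focus centre to focus centre).

    With ``within_segments`` (the default), a pair of adjacent foci lying in
    two different SC segments spans a synapsis gap and is excluded, matching
    measurement along SC segments in fragmented-SC nuclei.
    """
    pos = track.focus_positions
    if len(pos) < 2:
        return []
    out = []
    for a, b in zip(pos[:-1], pos[1:]):
        if within_segments and track.segment_index(a) != track.segment_index(b):
            continue
        out.append(b - a)
    return out


def relative_distances(distances, axis_length: float) -> list[float]:
    """Express distances as percentages of the axis length."""
    if axis_length <= 0:
        raise ParameterError(f"axis_length must be > 0, got {axis_length}")
    return [100.0 * d / axis_length for d in distances]


def pooled_distances(tracks, units: str = "microns", within_segments: bool = True) -> list[float]:
    """Pool adjacent-focus distances over tracks, in microns or percent of axis."""
    out: list[float] = []
    for t in tracks:
        d = adjacent_distances(t, within_segments=within_segments)
        if units == "percent_of_axis":
            d = relative_distances(d, t.axis_length)
        elif units != "microns":
            raise ParameterError(f"unknown units {units!r}")
        out.extend(d)
    return out


# ---------------------------------------------------------------------------
# gamma shape MLE


def _gamma_profile_loglik(shape: float, mean: float, mean_log: float, n: int) -> float:
    # profile log-likelihood with scale = mean/shape substituted
    return n * (
        -gammaln(shape) - shape * math.log(mean / shape) + (shape - 1.0) * mean_log - shape
    )


def _solve_shape(s: float) -> float:
    """Solve log(k) - digamma(k) = s for k by safeguarded Newton iteration.

    ``s`` is log(sample mean) - mean(log sample), strictly positive for any
    non-degenerate sample.  Falls back to bisection whenever a Newton step
    leaves the current bracket.
    """
    lo, hi = SHAPE_MIN, SHAPE_MAX

    def g(k: float) -> float:
        return math.log(k) - digamma(k) - s

    # g is strictly decreasing in k; bracket the root
    if g(lo) < 0:  # root below clamp: extremely heavy-tailed sample
        return lo
    if g(hi) > 0:  # root above clamp: nearly zero-variance sample
        return hi
    # standard closed-form starting value (Minka / Choi-Wette)
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    k = min(max(k, lo), hi)
    for _ in range(100):
        gk = g(k)
        if gk > 0:
            lo = k
        else:
            hi = k
        dg = 1.0 / k - polygamma(1, k)
        step = gk / dg
        k_new = k - step
        if not (lo < k_new < hi):
            k_new = 0.5 * (lo + hi)
        if abs(k_new - k) <= 1e-12 * max(1.0, k):
            return k_new
        k = k_new
    return k


def fit_gamma_shape(
    distances,
    n_bootstrap: int = 0,
    seed: int | None = None,
    units_flag: str = "microns",
) -> GammaFit:
    """Fit a gamma distribution to inter-focus distances by maximum likelihood.

    The shape is obtained on the profile likelihood by safeguarded Newton
    iteration on ``log(k) - digamma(k) = log(mean) - mean(log x)`` with the
    scale concentrated out (``scale = mean/shape``).  Non-positive distances
    are dropped with a logged count (the gamma likelihood is undefined at 0
    for shape > 1).  ``shape_uncertainty`` is the standard deviation of the
    shape over ``n_bootstrap`` seeded resamples of the spacing list (0.0 when
    ``n_bootstrap`` is 0).
    """
    x = np.asarray(list(distances), dtype=float)
    n_dropped = int(np.sum(x <= 0))
    if n_dropped:
        log.warning("fit_gamma_shape: dropped %d non-positive spacing(s)", n_dropped)
        x = x[x > 0]
    if len(x) < 2:
        raise InsufficientDataError(
            f"need >= 2 positive spacings to fit a gamma, got {len(x)}"
        )
    mean = float(x.mean())
    mean_log = float(np.mean(np.log(x)))
    s = math.log(mean) - mean_log
    if s <= 0:
        raise DegenerateSampleError(
            "all spacings equal: gamma likelihood is unbounded in the shape"
        )
    shape = _solve_shape(s)
    if shape in (SHAPE_MIN, SHAPE_MAX):
        log.warning("fit_gamma_shape: shape hit clamp at %g (degenerate sample?)", shape)
    scale = mean / shape
    loglik = _gamma_profile_loglik(shape, mean, mean_log, len(x))

    se = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            xb = rng.choice(x, size=len(x), replace=True)
            sb = math.log(xb.mean()) - float(np.mean(np.log(xb)))
            boot[b] = _solve_shape(sb) if sb > 0 else SHAPE_MAX
        se = float(np.std(boot, ddof=1))

    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        n_spacings=int(len(x)),
        loglik=float(loglik),
        shape_uncertainty=se,
        units_flag=units_flag,
    )


# ---------------------------------------------------------------------------
# coefficient of coincidence


def _interval_index(position: float, axis_length: float, n_intervals: int) -> int:
    """Interval index of a focus; boundary ties go to the lower-index interval."""
    size = axis_length / n_intervals
    if position <= 0:
        return 0
    idx = int(math.ceil(position / size)) - 1
    return min(max(idx, 0), n_intervals - 1)


def occupancy_matrix(tracks, n_intervals: int) -> np.ndarray:
    """Boolean (n_tracks, n_intervals) matrix: bivalent has >= 1 CO in interval.

    Each bivalent is divided into ``n_intervals`` equal intervals of its own
    axis length (relative-position binning), so the interval index is the
    coordinate shared across bivalents of unequal length.
    """
    occ = np.zeros((len(tracks), n_intervals), dtype=bool)
    for r, t in enumerate(tracks):
        for p in t.focus_positions:
            occ[r, _interval_index(p, t.axis_length, n_intervals)] = True
    return occ


def auto_n_intervals(tracks) -> int:
    """Default interval count: round-half-up of 5 x mean CO count, minimum 2."""
    mean_count = float(np.mean([t.n_foci for t in tracks]))
    return max(2, int(math.floor(5.0 * mean_count + 0.5)))


def coc_curve(
    tracks,
    n_intervals: int | str = "auto",
    group: str = "all",
    threshold: float = 0.5,
) -> CoCCurve:
    """Build a coefficient-of-coincidence curve from a group of bivalents.

    Procedure: divide each bivalent into ``n_intervals`` equal intervals of
    its own axis length; assign each CO to an interval; compute per-interval
    CO frequencies over bivalents; for every pair of distinct intervals
    compute observed (both occupied) / expected (product of marginals); pool
    pairs by inter-interval separation, the CoC of a pooled distance class
    being (sum observed) / (sum expected); convert separations to microns
    with the group-mean interval length.  Pairs with expected frequency 0
    are skipped and counted in ``n_skipped``.
    """
    tracks = list(tracks)
    if not tracks:
        raise InsufficientDataError("coc_curve needs at least one track")
    if n_intervals == "auto":
        n = auto_n_intervals(tracks)
    else:
        n = int(n_intervals)
        if n < 2:
            raise ParameterError(f"n_intervals must be >= 2, got {n}")

    occ = occupancy_matrix(tracks, n)
    n_biv = len(tracks)
    freq = occ.mean(axis=0)
    both = (occ.T.astype(np.int64) @ occ.astype(np.int64)) / n_biv
    mean_interval_len = float(np.mean([t.axis_length for t in tracks]) / n)

    points = []
    for d in range(1, n):
        obs_sum = 0.0
        exp_sum = 0.0
        n_pairs = 0
        n_skipped = 0
        for i in range(n - d):
            j = i + d
            expected = freq[i] * freq[j]
            if expected == 0.0:
                n_skipped += 1
                continue
            obs_sum += both[i, j]
            exp_sum += expected
            n_pairs += 1
        if n_pairs >= 1:
            points.append(
                CoCPoint(
                    distance=d * mean_interval_len,
                    coc=obs_sum / exp_sum,
                    n_pairs=n_pairs,
                    n_skipped=n_skipped,
                )
            )

    curve = CoCCurve(
        group=group,
        n_intervals=n,
        interval_length=mean_interval_len,
        points=tuple(points),
        interference_distance=NOT_REACHED,
    )
    dist = interference_distance(curve, threshold=threshold)
    return CoCCurve(
        group=group,
        n_intervals=n,
        interval_length=mean_interval_len,
        points=tuple(points),
        interference_distance=dist,
    )


def interference_distance(curve: CoCCurve, threshold: float = 0.5) -> float | str:
    """Inter-interval distance of the first upward crossing of ``threshold``.

    Returns 0.0 when the first curve point is already at or above the
    threshold (no detectable interference zone) and :data:`NOT_REACHED` when
    the curve never attains it.  The crossing abscissa is linearly
    interpolated between adjacent curve points.
    """
    if not curve.points:
        raise InsufficientDataError("CoC curve has no points")
    pts = curve.points
    if pts[0].coc >= threshold:
        return 0.0
    for prev, cur in zip(pts[:-1], pts[1:]):
        if cur.coc >= threshold:
            frac = (threshold - prev.coc) / (cur.coc - prev.coc)
            return prev.distance + frac * (cur.distance - prev.distance)
    return NOT_REACHED


# ---------------------------------------------------------------------------
# E-distribution


def e_distribution(counts) -> EDistribution:
    """Proportions of units with exactly k foci, k = 0..max(counts)."""
    counts = list(counts)
    if not counts:
        raise InsufficientDataError("e_distribution needs a non-empty count list")
    tally = np.bincount(np.asarray(counts, dtype=int))
    props = tally / tally.sum()
    return EDistribution(proportions=tuple(float(p) for p in props), n_units=len(counts))
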