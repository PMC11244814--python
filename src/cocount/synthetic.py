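"""Synthetic cohorts: gamma-renewal crossover placement along bivalents.

Crossover foci are placed as a stationary renewal process: inter-arrival
distances are i.i.d. gamma with shape ``nu`` and scale ``mean_spacing/nu``,
and the first arrival is drawn from the equilibrium (length-biased residual)
distribution so that statistics are translation-invariant along the axis and
free of chromosome-end edge bias.  shape = 1 recovers a homogeneous Poisson
process (no interference); larger shapes give the more even spacing that
crossover interference produces.

Two optional layers emulate biological features:

* ``obligate_co`` conditions each bivalent on carrying at least one focus by
  rejection sampling, which preserves the spacing law conditional on a
  non-zero count (the "obligatory crossover").
* ``fragmentation`` breaks the fully synapsed axis into several disjoint SC
  segments retaining a fraction of the total length, with placement biased
  towards the chromosome ends; foci falling outside retained segments are
  deleted.  This emulates mutants that form only end-biased SC segments and
  lose SC-associated crossover complexes elsewhere.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .model import Cohort, FocusTrack, Nucleus, assign_ranks

#: Default axis lengths (microns) for the 7 bivalents: a descending
#: arithmetic progression (step 0.95) summing to 52.2, the wild-type
#: total SC length per nucleus.
DEFAULT_CHROMOSOME_LENGTHS: tuple[float, ...] = tuple(
    52.2 / 7 + 0.95 * (3 - i) for i in range(7)
)

#: Default expected distance between adjacent crossovers (microns), chosen so
#: the expected total focus count per nucleus is ~22 (52.2 / 2.35 = 22.2).
DEFAULT_MEAN_SPACING = 2.35

#: Default gamma shape, the wild-type interference level.
DEFAULT_SHAPE = 5.0


@dataclass(frozen=True)
class FragmentationConfig:
    """Fragmented-SC mode: n_segments disjoint segments keeping
    ``retained_fraction`` of the axis, placed with an end bias."""

    n_segments: int = 2
    retained_fraction: float = 0.6
    end_bias: float = 2.0
    min_segment_length: float = 0.2  # microns, geometric feasibility floor


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the gamma-renewal cohort generator."""

    n_nuclei: int = 100
    chromosome_lengths: tuple[float, ...] = DEFAULT_CHROMOSOME_LENGTHS
    shape: float = DEFAULT_SHAPE
    mean_spacing: float = DEFAULT_MEAN_SPACING
    obligate_co: bool = False
    fragmentation: FragmentationConfig | None = None
    noise_sd: float = 0.0
    seed: int = 0
    genotype: str = "synthetic"
    stationary: bool = True  # first arrival from the equilibrium distribution
    #: coefficient of variation of a per-nucleus scale factor applied to all
    #: 7 axis lengths, emulating the ~10% nucleus-to-nucleus spread of total
    #: SC length (52.2 +/- 5.1 um in wild type).  0 disables it.
    nucleus_length_cv: float = 0.098

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ParameterError(f"n_nuclei must be >= 0, got {self.n_nuclei}")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ParameterError("all chromosome lengths must be > 0")
        if self.shape <= 0:
            raise ParameterError(f"shape must be > 0, got {self.shape}")
        if self.mean_spacing <= 0:
            raise ParameterError(f"mean_spacing must be > 0, got {self.mean_spacing}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.nucleus_length_cv < 0:
            raise ParameterError(
                f"nucleus_length_cv must be >= 0, got {self.nucleus_length_cv}"
            )


_MAX_REJECTIONS = 100_000


def simulate_track(
    length: float,
    shape: float,
    mean_spacing: float,
    obligate_co: bool = False,
    rng: np.random.Generator | None = None,
    *,
    stationary: bool = True,
    nucleus_id: str = "sim",
    genotype: str = "synthetic",
    bivalent_rank: int = 1,
) -> FocusTrack:
    """Simulate one fully synapsed bivalent.

    Inter-arrival distances are Gamma(shape, mean_spacing/shape).  Under
    ``stationary`` the first arrival is U * Gamma(shape + 1, scale): a draw
    from the length-biased spacing distribution thinned uniformly, which is
    exactly the equilibrium residual distribution of the renewal process.
    An infinite ``mean_spacing`` is the zero-intensity sentinel (no foci).
    """
    if length <= 0 or shape <= 0 or mean_spacing <= 0:
        raise ParameterError(
            f"length, shape, mean_spacing must be > 0, got "
            f"({length}, {shape}, {mean_spacing})"
        )
    if rng is None:
        rng = np.random.default_rng()
    if math.isinf(mean_spacing):
        if obligate_co:
            raise ParameterError("obligate_co is infeasible at zero intensity")
        return FocusTrack(nucleus_id, genotype, bivalent_rank, length)

    theta = mean_spacing / shape
    for _ in range(_MAX_REJECTIONS):
        if stationary:
            t = rng.uniform() * rng.gamma(shape + 1.0, theta)
        else:
            t = rng.gamma(shape, theta)
        positions = []
        while t < length:
            positions.append(t)
            t += rng.gamma(shape, theta)
        if positions or not obligate_co:
            return FocusTrack(
                nucleus_id, genotype, bivalent_rank, length, focus_positions=tuple(positions)
            )
    raise ParameterError(
        "obligate_co rejection sampling failed: zero-focus probability too high"
    )


def fragment_track(
    track: FocusTrack,
    n_segments: int,
    retained_fraction: float,
    end_bias: float,
    rng: np.random.Generator,
    min_segment_length: float = 0.2,
) -> FocusTrack:
    """Break a fully synapsed track into disjoint SC segments.

    The retained length ``retained_fraction * axis_length`` is split into
    ``n_segments`` pieces (each at least ``min_segment_length``); the free
    length is split into the n_segments + 1 gaps between/around them with
    exponential weights, the two outer gaps down-weighted by
    ``1 + end_bias`` so segments crowd towards the chromosome ends.  Foci
    outside retained segments are deleted; fragmentation never creates foci.
    """
    if not (0.0 < retained_fraction <= 1.0):
        raise ParameterError(f"retained_fraction must be in (0, 1], got {retained_fraction}")
    if n_segments < 1:
        raise ParameterError(f"n_segments must be >= 1, got {n_segments}")
    if end_bias < 0:
        raise ParameterError(f"end_bias must be >= 0, got {end_bias}")
    if track.n_segments != 1 or track.sc_length < track.axis_length - 1e-9:
        raise ParameterError("fragment_track expects a fully synapsed input track")

    L = track.axis_length
    retained = retained_fraction * L
    if n_segments * min_segment_length > retained + 1e-12:
        raise ParameterError(
            f"{n_segments} segments of >= {min_segment_length} um do not fit in "
            f"retained length {retained:.3f} um"
        )
    if retained_fraction == 1.0 and n_segments == 1:
        return track  # identity: nothing removed

    free = L - retained
    if n_segments > 1 and free <= 0:
        raise ParameterError("cannot place > 1 disjoint segment with retained_fraction = 1")

    # segment lengths: floor + Dirichlet split of the remainder
    extra = retained - n_segments * min_segment_length
    seg_lens = min_segment_length + rng.dirichlet(np.ones(n_segments)) * extra

    # gaps: exponential weights, outer gaps shrunk by the end bias
    w = rng.exponential(size=n_segments + 1)
    w[0] /= 1.0 + end_bias
    w[-1] /= 1.0 + end_bias
    gaps = free * w / w.sum()

    segments = []
    cursor = 0.0
    for k in range(n_segments):
        cursor += gaps[k]
        segments.append((cursor, cursor + seg_lens[k]))
        cursor += seg_lens[k]

    kept = tuple(
        p for p in track.focus_positions
        if any(a <= p <= b for a, b in segments)
    )
    return replace(track, segments=tuple(segments), focus_positions=kept)


def _clip_to_segment(position: float, segment: tuple[float, float]) -> float:
    return min(max(position, segment[0]), segment[1])


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate ``config.n_nuclei`` nuclei of 7 bivalents each.

    Bivalent ranks are assigned by descending axis length.  Optional Gaussian
    measurement noise of sd ``noise_sd`` is added to each focus position and
    clipped to its segment.  Identical config (including seed) yields an
    identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    ranks = assign_ranks(config.chromosome_lengths)
    nuclei = []
    for i in range(config.n_nuclei):
        nucleus_id = f"sim-{i:05d}"
        scale = 1.0
        if config.nucleus_length_cv > 0:
            # truncated-normal scale factor shared by all 7 axes of a nucleus
            while True:
                scale = 1.0 + rng.normal(0.0, config.nucleus_length_cv)
                if scale > 0.1:
                    break
        tracks = []
        for base_length, rank in zip(config.chromosome_lengths, ranks):
            length = base_length * scale
            track = simulate_track(
                length,
                config.shape,
                config.mean_spacing,
                obligate_co=config.obligate_co,
                rng=rng,
                stationary=config.stationary,
                nucleus_id=nucleus_id,
                genotype=config.genotype,
                bivalent_rank=rank,
            )
            if config.fragmentation is not None:
                f = config.fragmentation
                track = fragment_track(
                    track, f.n_segments, f.retained_fraction, f.end_bias, rng,
                    min_segment_length=f.min_segment_length,
                )
            if config.noise_sd > 0 and track.focus_positions:
                noisy = []
                for p in track.focus_positions:
                    seg = track.segments[track.segment_index(p)]
                    noisy.append(_clip_to_segment(p + rng.normal(0.0, config.noise_sd), seg))
                track = track.with_positions(sorted(noisy))
            tracks.append(track)
        nuclei.append(Nucleus(nucleus_id, config.genotype, tuple(tracks)))
    return Cohort(
        genotype=config.genotype,
        nuclei=tuple(nuclei),
        provenance=f"simulate_cohort(seed={config.seed})",
    )


def config_digest(config: SimConfig) -> str:
    """Short stable hash of a SimConfig, for manifests."""
    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]
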