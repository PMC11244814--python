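"""Core data model: per-bivalent focus tracks, nuclei, and genotype cohorts.

Positions are continuous, 0-based, in microns, measured along the chromosome
axis / synaptonemal complex (SC) from the end designated "start".  The origin
is arbitrary per track but must be used consistently.  A fully synapsed
bivalent carries a single segment spanning the whole axis; fragmented-SC
phenotypes are represented by several disjoint segments, and crossover foci
may only lie inside a segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ValidationError

#: absolute slack when testing whether a focus lies inside a segment
POSITION_TOL = 1e-9


@dataclass(frozen=True)
class FocusTrack:
    """One bivalent's axis geometry plus its ordered crossover-focus positions.

    Parameters
    ----------
    nucleus_id, genotype:
        Opaque labels linking the track to its nucleus and strain.
    bivalent_rank:
        Integer 1-7, rank 1 being the longest axis in its nucleus.
    axis_length:
        Full axis length in microns (> 0).
    segments:
        Ordered, disjoint ``(start, end)`` intervals in microns within
        ``[0, axis_length]`` along which SC is present.
    focus_positions:
        Ascending focus positions in microns, each inside some segment.
    """

    nucleus_id: str
    genotype: str
    bivalent_rank: int
    axis_length: float
    segments: tuple[tuple[float, float], ...] = ()
    focus_positions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.axis_length <= 0:
            raise ValidationError(
                f"axis_length must be > 0, got {self.axis_length!r} "
                f"(nucleus {self.nucleus_id}, rank {self.bivalent_rank})"
            )
        segments = tuple((float(a), float(b)) for a, b in self.segments)
        if not segments:
            segments = ((0.0, float(self.axis_length)),)
        object.__setattr__(self, "segments", tuple(sorted(segments)))
        object.__setattr__(
            self, "focus_positions", tuple(sorted(float(p) for p in self.focus_positions))
        )
        self._check_segments()
        self._check_foci()

    def _check_segments(self) -> None:
        prev_end = None
        total = 0.0
        for a, b in self.segments:
            if a < -POSITION_TOL or b > self.axis_length + POSITION_TOL or b <= a:
                raise ValidationError(
                    f"segment ({a}, {b}) outside [0, {self.axis_length}] or empty "
                    f"(nucleus {self.nucleus_id}, rank {self.bivalent_rank})"
                )
            if prev_end is not None and a < prev_end - POSITION_TOL:
                raise ValidationError(
                    f"segments overlap near {a} "
                    f"(nucleus {self.nucleus_id}, rank {self.bivalent_rank})"
                )
            prev_end = b
            total += b - a
        if total > self.axis_length + POSITION_TOL:
            raise ValidationError(
                f"sum of segment lengths {total} exceeds axis_length {self.axis_length}"
            )

    def _check_foci(self) -> None:
        for p in self.focus_positions:
            if not (0.0 <= p <= self.axis_length):
                raise ValidationError(
                    f"focus at {p} outside axis [0, {self.axis_length}] "
                    f"(nucleus {self.nucleus_id}, rank {self.bivalent_rank})"
                )
            if self.segment_index(p) is None:
                raise ValidationError(
                    f"focus at {p} lies outside every SC segment "
                    f"(nucleus {self.nucleus_id}, rank {self.bivalent_rank})"
                )

    def segment_index(self, position: float) -> int | None:
        """Index of the segment containing ``position``, or None."""
        for i, (a, b) in enumerate(self.segments):
            if a - POSITION_TOL <= position <= b + POSITION_TOL:
                return i
        return None

    @property
    def sc_length(self) -> float:
        """Total SC length (sum of segment lengths), microns."""
        return sum(b - a for a, b in self.segments)

    @property
    def n_foci(self) -> int:
        return len(self.focus_positions)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def with_positions(self, positions) -> "FocusTrack":
        return replace(self, focus_positions=tuple(positions))


@dataclass(frozen=True)
class Nucleus:
    """A set of up to 7 bivalent tracks sharing one nucleus."""

    nucleus_id: str
    genotype: str
    tracks: tuple[FocusTrack, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tracks", tuple(self.tracks))
        if len(self.tracks) > 7:
            raise ValidationError(
                f"nucleus {self.nucleus_id} has {len(self.tracks)} tracks (max 7)"
            )
        ranks = [t.bivalent_rank for t in self.tracks]
        if len(set(ranks)) != len(ranks):
            raise ValidationError(f"duplicate bivalent_rank in nucleus {self.nucleus_id}")
        # ranks must be consistent with descending axis length
        by_rank = sorted(self.tracks, key=lambda t: t.bivalent_rank)
        lengths = [t.axis_length for t in by_rank]
        if any(lengths[i] < lengths[i + 1] - POSITION_TOL for i in range(len(lengths) - 1)):
            raise ValidationError(
                f"bivalent ranks inconsistent with descending axis_length "
                f"in nucleus {self.nucleus_id}"
            )

    @property
    def total_sc_length(self) -> float:
        return sum(t.sc_length for t in self.tracks)

    @property
    def total_focus_count(self) -> int:
        return sum(t.n_foci for t in self.tracks)

    @property
    def total_n_segments(self) -> int:
        return sum(t.n_segments for t in self.tracks)


@dataclass(frozen=True)
class Cohort:
    """All nuclei of one genotype, plus parsing provenance."""

    genotype: str
    nuclei: tuple[Nucleus, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        for nuc in self.nuclei:
            if nuc.genotype != self.genotype:
                raise ValidationError(
                    f"nucleus {nuc.nucleus_id} has genotype {nuc.genotype!r}, "
                    f"cohort is {self.genotype!r}"
                )

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    def tracks(self, ranks=None) -> list[FocusTrack]:
        """Flat list of tracks, optionally restricted to a set of bivalent ranks."""
        out = []
        for nuc in self.nuclei:
            for t in nuc.tracks:
                if ranks is None or t.bivalent_rank in ranks:
                    out.append(t)
        return out


def assign_ranks(lengths) -> list[int]:
    """Rank axis lengths 1..n, 1 = longest; ties broken by input order."""
    order = sorted(range(len(lengths)), key=lambda i: (-lengths[i], i))
    ranks = [0] * len(lengths)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks
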