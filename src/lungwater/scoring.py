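"""Semi-quantitative B-line scoring.

Per intercostal space the score is:

* A-pattern (horizontal reverberations only, aerated lung) → 0;
* discrete B lines → their count, 0–10;
* confluent B-line bands → the fraction of the rib-space width occupied
  by the bands × 10 (capped at 10).

Zone scores are the sum over the zone's seven spaces; the whole-animal
score is the sum over the four zones (0–280). Only the whole-animal
total is rounded (half away from zero); per-space confluent scores stay
fractional.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .layout import RatSite, Scheme, SiteId, build_layout

__all__ = [
    "Mode",
    "SpaceObservation",
    "BLineScoreResult",
    "score_space",
    "score_zone",
    "score_animal",
    "round_half_away",
]

logger = logging.getLogger(__name__)

MAX_SPACE_SCORE = 10.0


class Mode(str, Enum):
    A_PATTERN = "a_pattern"
    DISCRETE = "discrete"
    CONFLUENT = "confluent"


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 → 3, −2.5 → −3)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class SpaceObservation:
    """One intercostal space's reading.

    ``count`` is meaningful only in discrete mode; ``segments`` (B-line
    band widths, cm) and ``space_width`` (rib-space width, cm) only in
    confluent mode.
    """

    site: SiteId
    mode: Mode
    count: Optional[int] = None
    segments: tuple[float, ...] = ()
    space_width: Optional[float] = None

    def __post_init__(self) -> None:
        mode = Mode(self.mode)
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "segments", tuple(self.segments))
        if mode is Mode.A_PATTERN:
            if self.count not in (None, 0) or self.segments:
                raise ValueError(f"{self.site}: a_pattern carries no count or segments")
        elif mode is Mode.DISCRETE:
            if self.count is None or not (0 <= self.count <= 10):
                raise ValueError(
                    f"{self.site}: discrete count must be an integer in 0–10, got {self.count}"
                )
            if self.segments:
                raise ValueError(f"{self.site}: discrete observation carries no segments")
        else:  # confluent
            if self.space_width is None or self.space_width <= 0:
                raise ValueError(
                    f"{self.site}: confluent observation needs space_width > 0, "
                    f"got {self.space_width}"
                )
            if not self.segments or any(s <= 0 for s in self.segments):
                raise ValueError(f"{self.site}: confluent segment lengths must be > 0")
            total = sum(self.segments)
            if total > self.space_width * (1 + 1e-9):
                raise ValueError(
                    f"{self.site}: segments sum to {total:.4g} cm, exceeding the "
                    f"{self.space_width:.4g} cm rib space"
                )


@dataclass(frozen=True)
class BLineScoreResult:
    """Per-space, per-zone and whole-animal B-line scores."""

    per_space: Mapping[SiteId, float]
    per_zone: Mapping[int, float]
    total_raw: float
    total: int
    missing_sites: tuple[SiteId, ...] = field(default=())


def score_space(obs: SpaceObservation) -> float:
    """Score one intercostal space on the 0–10 scale."""
    if obs.mode is Mode.A_PATTERN:
        return 0.0
    if obs.mode is Mode.DISCRETE:
        return float(obs.count)
    occupied = sum(obs.segments) / obs.space_width
    return min(MAX_SPACE_SCORE, occupied * 10.0)


def score_zone(observations: Iterable[SpaceObservation], zone: int) -> float:
    """Sum of space scores within one scan zone; absent spaces contribute 0."""
    seen: set[SiteId] = set()
    total = 0.0
    for obs in observations:
        site = obs.site
        if not isinstance(site, RatSite) or site.zone != zone:
            raise ValueError(f"observation at {site} does not belong to zone {zone}")
        if site in seen:
            raise ValueError(f"duplicate observation at site {site.serialize()}")
        seen.add(site)
        total += score_space(obs)
    return total


def score_animal(observations: Sequence[SpaceObservation]) -> BLineScoreResult:
    """Aggregate one animal's 28-site reading into the whole-lung score.

    Sites absent from ``observations`` score 0 and are reported in
    ``missing_sites`` (and logged), matching a protocol that expects full
    28-site coverage.
    """
    layout = build_layout(Scheme.RAT_4X7)
    per_space: dict[SiteId, float] = {}
    for obs in observations:
        if obs.site not in layout:
            raise ValueError(
                f"site {obs.site!r} is not part of the rat 4-zone × 7-space layout"
            )
        if obs.site in per_space:
            raise ValueError(f"duplicate observation at site {obs.site.serialize()}")
        per_space[obs.site] = score_space(obs)

    missing = tuple(s for s in layout.sites if s not in per_space)
    if missing:
        logger.warning(
            "%d of 28 sites unobserved (scored 0): %s",
            len(missing),
            ", ".join(s.serialize() for s in missing),
        )

    per_zone = {
        z: sum(per_space.get(s, 0.0) for s in layout.sites if s.zone == z)
        for z in range(1, 5)
    }
    total_raw = sum(per_zone.values())
    return BLineScoreResult(
        per_space=per_space,
        per_zone=per_zone,
        total_raw=total_raw,
        total=round_half_away(total_raw),
        missing_sites=missing,
    )
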