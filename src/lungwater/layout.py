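"""Scanning-site coordinate systems for lung ultrasound B-line protocols.

Two schemes are supported:

* ``rat_4x7`` — the rat adaptation: each hemithorax is split into two
  dorsal scan zones (posterior-axillary→scapular and scapular→
  paravertebral), giving four zones, and each vertical scan shows seven
  intercostal spaces, so 4 × 7 = 28 sites per animal.
* ``human_28`` — the human 28-rib-space reference protocol: B lines are
  counted on four parasternal-to-mid-axillary lines, in intercostal
  spaces 2–4 on the left and 2–5 on the right (3·4 + 4·4 = 28).

Zone numbering convention (the protocol itself fixes none): zones 1–2 are
the right hemithorax, 3–4 the left; spaces are numbered 1–7
cranial→caudal. Scores are side-symmetric sums, so any fixed convention
yields identical totals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Union

__all__ = [
    "Scheme",
    "RatSite",
    "HumanSite",
    "SiteId",
    "SiteMap",
    "build_layout",
    "parse_site",
]

RAT_N_ZONES = 4
RAT_N_SPACES = 7

HUMAN_LINES = ("PS", "MC", "AA", "MA")  # parasternal, mid-clavicular, anterior-axillary, mid-axillary
HUMAN_SPACES = {"left": (2, 3, 4), "right": (2, 3, 4, 5)}


class Scheme(str, Enum):
    """Supported scanning-site layouts."""

    RAT_4X7 = "rat_4x7"
    HUMAN_28 = "human_28"


@dataclass(frozen=True, order=True)
class RatSite:
    """One rat intercostal site: scan zone 1–4, space 1–7 cranial→caudal."""

    zone: int
    space: int

    def __post_init__(self) -> None:
        if not (1 <= self.zone <= RAT_N_ZONES):
            raise ValueError(f"rat zone must be 1–{RAT_N_ZONES}, got {self.zone}")
        if not (1 <= self.space <= RAT_N_SPACES):
            raise ValueError(f"rat space must be 1–{RAT_N_SPACES}, got {self.space}")

    @property
    def side(self) -> str:
        # zones 1–2 right hemithorax, 3–4 left (fixed convention)
        return "right" if self.zone <= 2 else "left"

    def serialize(self) -> str:
        return f"Z{self.zone}S{self.space}"


@dataclass(frozen=True, order=True)
class HumanSite:
    """One human site: side, intercostal space, and anatomical scan line."""

    side: str
    space: int
    line: str

    def __post_init__(self) -> None:
        if self.side not in HUMAN_SPACES:
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.space not in HUMAN_SPACES[self.side]:
            raise ValueError(
                f"space {self.space} invalid for {self.side} hemithorax "
                f"(allowed: {HUMAN_SPACES[self.side]})"
            )
        if self.line not in HUMAN_LINES:
            raise ValueError(f"line must be one of {HUMAN_LINES}, got {self.line!r}")

    def serialize(self) -> str:
        return f"{self.side[0].upper()}S{self.space}{self.line}"


SiteId = Union[RatSite, HumanSite]


@dataclass(frozen=True)
class SiteMap:
    """Ordered, duplicate-free list of scanning sites for one scheme."""

    scheme: Scheme
    sites: tuple[SiteId, ...]

    def __post_init__(self) -> None:
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site identifiers must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, site: SiteId) -> bool:
        return site in self.sites

    def index(self, site: SiteId) -> int:
        return self.sites.index(site)


def build_layout(scheme: Union[Scheme, str]) -> SiteMap:
    """Enumerate the complete ordered site list for a scheme.

    The rat scheme walks zone 1→4 (the scan order), spaces cranial→caudal
    within a zone; the human scheme walks left then right, spaces outer,
    lines inner.
    """
    try:
        scheme = Scheme(scheme)
    except ValueError:
        supported = ", ".join(s.value for s in Scheme)
        raise ValueError(
            f"unknown scheme {scheme!r}; supported schemes: {supported}"
        ) from None

    sites: list[SiteId]
    if scheme is Scheme.RAT_4X7:
        sites = [
            RatSite(zone=z, space=s)
            for z in range(1, RAT_N_ZONES + 1)
            for s in range(1, RAT_N_SPACES + 1)
        ]
    else:
        sites = [
            HumanSite(side=side, space=sp, line=line)
            for side in ("left", "right")
            for sp in HUMAN_SPACES[side]
            for line in HUMAN_LINES
        ]
    return SiteMap(scheme=scheme, sites=tuple(sites))


_RAT_RE = re.compile(r"^Z(\d+)S(\d+)$")
_HUMAN_RE = re.compile(r"^([LR])S(\d+)([A-Z]{2})$")


def parse_site(text: str) -> SiteId:
    """Inverse of ``SiteId.serialize`` ("Z3S5", "LS2PS", ...)."""
    m = _RAT_RE.match(text)
    if m:
        return RatSite(zone=int(m.group(1)), space=int(m.group(2)))
    m = _HUMAN_RE.match(text)
    if m:
        side = "left" if m.group(1) == "L" else "right"
        return HumanSite(side=side, space=int(m.group(2)), line=m.group(3))
    raise ValueError(f"unparseable site identifier {text!r}")
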