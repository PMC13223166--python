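"""The 14-zone anatomical atlas of pelvic and para-aortic lymph-node regions.

Zones follow the numbering used in systematic lymphadenectomy for epithelial
ovarian cancer: paired common/external/internal iliac, obturator, superficial
inguinal and para-aortic stations, plus the presacral station and a catch-all
"distant" station (mesenteric, supraclavicular, mediastinal nodes).

The atlas also carries an explicit, editable list of anatomically plausible
connections between zones.  "Plausible" means the two stations are adjacent
along a lymphatic chain (iliac vessels, obturator fossa, para-aortic trunk)
or connected by a recognised drainage route (obturator to inguinal/presacral,
para-aortic cross-over, common iliac to para-aortic continuation).  Pathway
extraction uses this list to reject statistically strong edges between
anatomically distant stations.
"""

from __future__ import annotations

from dataclasses import dataclass, field


ZONE_NAMES: dict[int, str] = {
    1: "left common iliac",
    2: "right common iliac",
    3: "left external iliac",
    4: "right external iliac",
    5: "left internal iliac",
    6: "right internal iliac",
    7: "left obturator",
    8: "right obturator",
    9: "left superficial inguinal",
    10: "right superficial inguinal",
    11: "left para-aortic",
    12: "right para-aortic",
    13: "presacral",
    14: "distant",
}

ZONE_SIDES: dict[int, str] = {
    1: "left", 2: "right", 3: "left", 4: "right", 5: "left", 6: "right",
    7: "left", 8: "right", 9: "left", 10: "right", 11: "left", 12: "right",
    13: "midline", 14: "distant",
}

#: Default anatomical adjacency: unordered zone pairs deemed plausible
#: direct connections.  Chain neighbours along the iliac vessels, the
#: contralateral common-iliac and para-aortic pairs, obturator links to the
#: iliac chains and to inguinal/presacral stations, the common-iliac to
#: para-aortic continuation, and para-aortic/common-iliac access to the
#: distant station.
DEFAULT_ADJACENCY: frozenset[frozenset[int]] = frozenset(
    frozenset(p)
    for p in [
        (1, 2),              # contralateral common iliac
        (1, 3), (1, 5),      # left common iliac to left external/internal
        (2, 4), (2, 6),      # right common iliac to right external/internal
        (3, 5), (4, 6),      # ipsilateral external-internal iliac
        (3, 7), (5, 7),      # left obturator links
        (4, 8), (6, 8),      # right obturator links
        (7, 8),              # contralateral obturator
        (7, 9), (8, 10),     # obturator to ipsilateral inguinal
        (9, 10),             # contralateral inguinal
        (7, 13), (8, 13),    # obturator to presacral
        (11, 12),            # contralateral para-aortic
        (1, 11), (2, 12),    # common iliac to ipsilateral para-aortic
        (1, 14), (2, 14),    # common iliac to distant
        (11, 14), (12, 14),  # para-aortic to distant
    ]
)


@dataclass(frozen=True)
class Zone:
    """One anatomical lymph-node station."""

    id: int
    name: str
    side: str


@dataclass(frozen=True)
class ZoneAtlas:
    """The 14 nodal zones plus their anatomical adjacency structure.

    Parameters
    ----------
    zones
        The 14 zone descriptors, ids 1..14.
    adjacency
        Unordered pairs of zone ids considered anatomically plausible
        direct connections.
    """

    zones: tuple[Zone, ...] = field(
        default_factory=lambda: tuple(
            Zone(i, ZONE_NAMES[i], ZONE_SIDES[i]) for i in range(1, 15)
        )
    )
    adjacency: frozenset[frozenset[int]] = DEFAULT_ADJACENCY

    def __post_init__(self) -> None:
        ids = [z.id for z in self.zones]
        if sorted(ids) != list(range(1, 15)):
            raise ValueError(f"atlas must contain exactly zones 1..14, got ids {sorted(ids)}")
        valid = set(ids)
        for pair in self.adjacency:
            if len(pair) != 2 or not pair <= valid:
                raise ValueError(f"adjacency pair {set(pair)} references invalid zone ids")

    @property
    def zone_ids(self) -> tuple[int, ...]:
        return tuple(z.id for z in self.zones)

    def name_of(self, zone_id: int) -> str:
        return ZONE_NAMES[zone_id]

    def adjacent(self, a: int, b: int) -> bool:
        """True if zones ``a`` and ``b`` are anatomically plausible neighbours."""
        return frozenset((a, b)) in self.adjacency

    def with_extra_links(self, pairs) -> "ZoneAtlas":
        """Return a copy whose adjacency includes the given extra pairs."""
        extra = frozenset(frozenset(p) for p in pairs)
        return ZoneAtlas(self.zones, self.adjacency | extra)


def default_atlas() -> ZoneAtlas:
    """The standard 14-zone atlas with the default adjacency list."""
    return ZoneAtlas()
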