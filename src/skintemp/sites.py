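"""Skin sensor sites of the nine-sensor proximal/distal protocol.

Five proximal sites (abdomen, left/right infra-clavicular area, left/right
mid-thigh) and four distal sites (left/right hand at the thenar area,
left/right foot at the mid-metatarsal plantar area).  Every site except the
abdomen has a left/right homologue in the same group.
"""

from __future__ import annotations

from enum import Enum


class SiteGroup(str, Enum):
    """Sensor group: proximal (trunk/thigh) or distal (hands/feet)."""

    PROX = "PROX"
    DIST = "DIST"

    @property
    def sites(self) -> tuple["SiteCode", ...]:
        """Sites of this group, in the canonical (anatomical) order."""
        return GROUP_SITES[self]


class SiteCode(str, Enum):
    """One of the nine skin placement sites."""

    A = "A"      # abdomen
    LIA = "LIA"  # left infra-clavicular area
    RIA = "RIA"  # right infra-clavicular area
    LMT = "LMT"  # left mid-thigh
    RMT = "RMT"  # right mid-thigh
    LF = "LF"    # left foot
    RF = "RF"    # right foot
    LH = "LH"    # left hand
    RH = "RH"    # right hand

    @property
    def group(self) -> SiteGroup:
        return SiteGroup.PROX if self in GROUP_SITES[SiteGroup.PROX] else SiteGroup.DIST

    @property
    def homologue(self) -> "SiteCode | None":
        """The contralateral site of the same region; None for the abdomen."""
        return _HOMOLOGUES.get(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


GROUP_SITES: dict[SiteGroup, tuple[SiteCode, ...]] = {
    SiteGroup.PROX: (SiteCode.A, SiteCode.LIA, SiteCode.RIA, SiteCode.LMT, SiteCode.RMT),
    SiteGroup.DIST: (SiteCode.LF, SiteCode.RF, SiteCode.LH, SiteCode.RH),
}

ALL_SITES: tuple[SiteCode, ...] = GROUP_SITES[SiteGroup.PROX] + GROUP_SITES[SiteGroup.DIST]

_HOMOLOGUES: dict[SiteCode, SiteCode] = {
    SiteCode.LIA: SiteCode.RIA,
    SiteCode.RIA: SiteCode.LIA,
    SiteCode.LMT: SiteCode.RMT,
    SiteCode.RMT: SiteCode.LMT,
    SiteCode.LH: SiteCode.RH,
    SiteCode.RH: SiteCode.LH,
    SiteCode.LF: SiteCode.RF,
    SiteCode.RF: SiteCode.LF,
}

#: Homologous left/right pairs keyed by a stable pair label.
HOMOLOGOUS_PAIRS: dict[str, tuple[SiteCode, SiteCode]] = {
    "IA": (SiteCode.LIA, SiteCode.RIA),
    "MT": (SiteCode.LMT, SiteCode.RMT),
    "H": (SiteCode.LH, SiteCode.RH),
    "F": (SiteCode.LF, SiteCode.RF),
}


def parse_site(token: str) -> SiteCode:
    """Parse a site token such as ``"LIA"`` (case-insensitive).

    Raises
    ------
    ValueError
        If the token is not one of the nine site codes.
    """
    try:
        return SiteCode(token.strip().upper())
    except ValueError:
        valid = ", ".join(s.value for s in ALL_SITES)
        raise ValueError(f"unknown site token {token!r}; expected one of: {valid}") from None


def parse_group(token: str) -> SiteGroup:
    """Parse ``"prox"``/``"dist"`` (case-insensitive) into a :class:`SiteGroup`."""
    try:
        return SiteGroup(token.strip().upper())
    except ValueError:
        raise ValueError(f"unknown group {token!r}; expected 'PROX' or 'DIST'") from None
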