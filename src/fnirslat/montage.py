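"""Headband probe geometry.

The prototype headband spans the sensorimotor strip with five detectors
(one at the vertex, two per hemisphere) and nine long-path LED sources at
30 mm separation, giving an 8 x 2 grid of 16 long-path measurement
locations (8 homotopic medial->lateral pairs, one member per hemisphere).
Each detector additionally carries a short-path source at 8 mm whose
channel samples scalp/systemic physiology for that detector's long
channels.

Long-path channels use the 745/850 nm wavelength pair, short-path
channels 735/850 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LONG_WAVELENGTHS = (745.0, 850.0)
SHORT_WAVELENGTHS = (735.0, 850.0)
LONG_SEPARATION_CM = 3.0
SHORT_SEPARATION_CM = 0.8


@dataclass(frozen=True)
class Channel:
    """One source-detector measurement location."""

    id: str
    path_type: str  # "long" | "short"
    source: str
    detector: str
    wavelengths: tuple[float, float]
    hemisphere: str  # "left" | "right" | "midline" (short channel at vertex)
    pair_index: int | None = None  # 1 (most medial) .. 8 (most lateral); long only
    short_channel: str | None = None  # associated short channel; long only

    @property
    def separation_cm(self) -> float:
        return LONG_SEPARATION_CM if self.path_type == "long" else SHORT_SEPARATION_CM


@dataclass(frozen=True)
class Montage:
    detectors: list[str]
    long_sources: list[str]
    short_sources: list[str]
    channels: list[Channel] = field(default_factory=list)
    homotopic_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.path_type == "long"]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.path_type == "short"]

    def channel(self, channel_id: str) -> Channel:
        for c in self.channels:
            if c.id == channel_id:
                return c
        raise KeyError(f"unknown channel {channel_id!r}")

    def validate(self) -> None:
        long = self.long_channels
        if len(long) != 16:
            raise ValueError(f"expected 16 long-path locations, got {len(long)}")
        if len(self.homotopic_pairs) != 8:
            raise ValueError(
                f"expected 8 homotopic pairs, got {len(self.homotopic_pairs)}"
            )
        seen: set[str] = set()
        for k, (lid, rid) in enumerate(self.homotopic_pairs, start=1):
            lch, rch = self.channel(lid), self.channel(rid)
            if lch.hemisphere != "left" or rch.hemisphere != "right":
                raise ValueError(f"pair {k} is not (left, right): {lid}, {rid}")
            if lch.pair_index != rch.pair_index:
                raise ValueError(f"pair {k} members disagree on pair_index")
            seen.update((lid, rid))
        if seen != {c.id for c in long}:
            raise ValueError("every long channel must belong to exactly one pair")
        for c in long:
            if c.short_channel is None:
                raise ValueError(f"long channel {c.id} has no local short channel")


# detector name -> (hemisphere, channels it hosts as (hemisphere, pair_index, source))
# Vertex detector hosts the two most medial locations of each hemisphere; the
# intermediate detectors host four locations each; the lateral end detectors two.
_LAYOUT: dict[str, list[tuple[str, int, str]]] = {
    "D14": [("left", 8, "E1"), ("left", 7, "E2")],
    "D15": [("left", 6, "E2"), ("left", 5, "E3"), ("left", 4, "E4"), ("left", 3, "E5")],
    "D16": [("left", 2, "E4"), ("left", 1, "E5"), ("right", 1, "E6"), ("right", 2, "E7")],
    "D17": [("right", 3, "E6"), ("right", 4, "E7"), ("right", 5, "E8"), ("right", 6, "E9")],
    "D18": [("right", 7, "E8"), ("right", 8, "E9")],
}

_DETECTOR_HEMI = {
    "D14": "left",
    "D15": "left",
    "D16": "midline",
    "D17": "right",
    "D18": "right",
}


def build_montage() -> Montage:
    """Construct the headband montage: 16 long + 5 short channels, 8 pairs."""
    detectors = list(_LAYOUT)
    channels: list[Channel] = []
    pairs: dict[int, dict[str, str]] = {k: {} for k in range(1, 9)}
    for det, locs in _LAYOUT.items():
        short_id = f"S{det[1:]}"
        channels.append(
            Channel(
                id=short_id,
                path_type="short",
                source=f"E{det}",
                detector=det,
                wavelengths=SHORT_WAVELENGTHS,
                hemisphere=_DETECTOR_HEMI[det],
            )
        )
        for hemi, pair_index, source in locs:
            cid = f"{'L' if hemi == 'left' else 'R'}{pair_index}"
            channels.append(
                Channel(
                    id=cid,
                    path_type="long",
                    source=source,
                    detector=det,
                    wavelengths=LONG_WAVELENGTHS,
                    hemisphere=hemi,
                    pair_index=pair_index,
                    short_channel=short_id,
                )
            )
            pairs[pair_index][hemi] = cid
    homotopic = [(pairs[k]["left"], pairs[k]["right"]) for k in range(1, 9)]
    montage = Montage(
        detectors=detectors,
        long_sources=[f"E{i}" for i in range(1, 10)],
        short_sources=[f"ED{i}" for i in (14, 15, 16, 17, 18)],
        channels=channels,
        homotopic_pairs=homotopic,
    )
    montage.validate()
    return montage
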