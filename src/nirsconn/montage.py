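"""Optode montage: 48 measurement channels from 24 sources and 16 detectors.

A *channel* is a source–detector pair at a nominal 3 cm separation sampling one
cortical patch.  Channel numbering is 1-based and fixed, so that pair labels
such as "10–46" are stable across runs and tables.  The built-in
``whole_head_48`` layout covers the frontal, parietal, occipital and temporal
lobes and carries named-area labels (DLPFC, Broca's pars triangularis /
opercularis, Wernicke's area, V1, V2) on the channels used in the longitudinal
edge analyses.  Optode coordinates are illustrative: they place the montage on
a plausible whole-head grid but are not registered to any template brain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

N_CHANNELS = 48
N_SOURCES = 24
N_DETECTORS = 16


class ChannelDef(NamedTuple):
    """One measurement channel: a source–detector pair with a region label."""

    source: int
    detector: int
    region_label: str


# Coarse lobe bands (1-based channel numbers) used both for labelling and for
# the block structure of the synthetic group networks.
_LOBE_BANDS = (
    (range(1, 9), "occipital"),
    (range(9, 17), "temporal"),
    (range(17, 29), "parietal"),
    (range(29, 49), "frontal"),
)

# Named cortical areas on specific channels.  The longitudinal analyses report
# pairs 10-46, 10-34, 7-48 and 4-47; their endpoints must carry these labels.
_NAMED_AREAS = {
    4: "visual association cortex (V2)",
    7: "primary visual cortex (V1)",
    10: "supramarginal gyrus / Wernicke's area",
    34: "dorsolateral prefrontal cortex (DLPFC)",
    44: "Broca's area (pars opercularis)",
    45: "dorsolateral prefrontal cortex (DLPFC)",
    46: "dorsolateral prefrontal cortex (DLPFC)",
    47: "Broca's area (pars triangularis)",
    48: "Broca's area (pars triangularis)",
}


def channel_lobe(channel_1based: int) -> str:
    """Coarse lobe of a channel (named areas keep their lobe membership)."""
    for band, lobe in _LOBE_BANDS:
        if channel_1based in band:
            return lobe
    raise ValueError(f"channel {channel_1based} outside 1..{N_CHANNELS}")


@dataclass(frozen=True)
class MontageSpec:
    """Source/detector layout defining the 48 measurement channels.

    ``channels`` is an ordered tuple; position ``i`` is channel ``i + 1`` in
    the 1-based numbering used in all tables and pair labels.
    """

    n_sources: int
    n_detectors: int
    channels: tuple[ChannelDef, ...]
    separation_cm: float = 3.0
    sampling_rate: float = 11.0
    wavelengths: tuple[float, float] = (730.0, 850.0)
    name: str = "whole_head_48"
    source_pos: tuple[tuple[float, float], ...] = field(default=(), repr=False)
    detector_pos: tuple[tuple[float, float], ...] = field(default=(), repr=False)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def __post_init__(self) -> None:
        if len(self.channels) != N_CHANNELS:
            raise ValueError(
                f"montage must define exactly {N_CHANNELS} channels, "
                f"got {len(self.channels)}"
            )
        seen: set[tuple[int, int]] = set()
        for ch in self.channels:
            if not (1 <= ch.source <= self.n_sources):
                raise ValueError(f"channel references invalid source {ch.source}")
            if not (1 <= ch.detector <= self.n_detectors):
                raise ValueError(f"channel references invalid detector {ch.detector}")
            if (ch.source, ch.detector) in seen:
                raise ValueError(
                    f"duplicate source-detector pair {ch.source}-{ch.detector}"
                )
            seen.add((ch.source, ch.detector))
        if len(self.wavelengths) != 2:
            raise ValueError("exactly two wavelengths required")

    def pair_label(self, i: int, j: int) -> str:
        """1-based "i-j" label for a channel pair (i < j)."""
        a, b = sorted((i, j))
        return f"{a}-{b}"

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "n_sources": self.n_sources,
            "n_detectors": self.n_detectors,
            "separation_cm": self.separation_cm,
            "sampling_rate": self.sampling_rate,
            "wavelengths": list(self.wavelengths),
            "channels": [
                {"index": i + 1, "source": c.source, "detector": c.detector,
                 "region_label": c.region_label}
                for i, c in enumerate(self.channels)
            ],
        }
        return json.dumps(payload, indent=2)


def _builtin_whole_head_48() -> MontageSpec:
    channels = []
    for i in range(N_CHANNELS):
        src = i // 2 + 1
        det = ((i // 2) + (i % 2) * 8) % N_DETECTORS + 1
        num = i + 1
        label = _NAMED_AREAS.get(num, channel_lobe(num))
        channels.append(ChannelDef(src, det, label))
    # Illustrative planar optode coordinates (cm) on a head-sized grid.
    src_pos = tuple((float((s % 6) * 3.0), float((s // 6) * 4.0)) for s in range(N_SOURCES))
    det_pos = tuple(
        (float((d % 4) * 4.5 + 1.5), float((d // 4) * 4.0 + 2.0)) for d in range(N_DETECTORS)
    )
    return MontageSpec(
        n_sources=N_SOURCES,
        n_detectors=N_DETECTORS,
        channels=tuple(channels),
        source_pos=src_pos,
        detector_pos=det_pos,
    )


def montage_from_json(text: str) -> MontageSpec:
    payload = json.loads(text)
    indices = [c["index"] for c in payload["channels"]]
    if len(set(indices)) != len(indices):
        raise ValueError("montage file contains duplicate channel indices")
    order = sorted(payload["channels"], key=lambda c: c["index"])
    channels = tuple(
        ChannelDef(int(c["source"]), int(c["detector"]), str(c["region_label"]))
        for c in order
    )
    return MontageSpec(
        n_sources=int(payload["n_sources"]),
        n_detectors=int(payload["n_detectors"]),
        channels=channels,
        separation_cm=float(payload.get("separation_cm", 3.0)),
        sampling_rate=float(payload.get("sampling_rate", 11.0)),
        wavelengths=tuple(payload.get("wavelengths", (730.0, 850.0))),
        name=str(payload.get("name", "custom")),
    )


def build_montage(layout_name: str = "whole_head_48") -> MontageSpec:
    """Return a built-in montage by name, or load one from a JSON file path.

    Raises ``ValueError`` for an unknown layout name and for montage files
    with duplicate channel indices.
    """
    if layout_name == "whole_head_48":
        return _builtin_whole_head_48()
    if layout_name.endswith(".json"):
        with open(layout_name, "r", encoding="utf-8") as fh:
            return montage_from_json(fh.read())
    raise ValueError(f"unknown layout {layout_name!r}")
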