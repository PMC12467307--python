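"""Canonical FACS action-unit inventory, emotion categories, and the AU-to-rig map.

The default inventory holds the 12 action units the facial rig exposes
(AU1 inner brow raiser ... AU23 lip tightener). Everything downstream —
synthetic corpora, co-occurrence graphs, curve mapping — is parameterised by
an ordered AU id tuple so alternative inventories (e.g. the larger CASME II
annotation set) can be swapped in.
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = [
    "AU_INVENTORY",
    "EMOTIONS",
    "load_rig_map",
    "RigMap",
]

#: Ordered canonical inventory: the 12 AUs with rig-control bindings.
AU_INVENTORY: tuple[str, ...] = (
    "AU1", "AU2", "AU4", "AU5", "AU6", "AU7",
    "AU9", "AU10", "AU12", "AU15", "AU20", "AU23",
)

#: Six Ekman emotion categories plus neutral (index order is the
#: categorical-label order used by every classifier head).
EMOTIONS: tuple[str, ...] = (
    "anger", "disgust", "fear", "happiness", "sadness", "surprise", "neutral",
)


class RigMap:
    """Mapping from AU id to an ordered list of rig control channel names."""

    def __init__(self, mapping: dict[str, list[str]], descriptions: dict[str, str] | None = None):
        for au, channels in mapping.items():
            if not channels:
                raise ValueError(f"rig map entry for {au} has no channels")
            if len(set(channels)) != len(channels):
                raise ValueError(f"duplicate channel names for {au}")
        self.mapping = dict(mapping)
        self.descriptions = dict(descriptions or {})

    def channels(self, au_id: str) -> list[str]:
        try:
            return list(self.mapping[au_id])
        except KeyError:
            raise KeyError(f"AU id {au_id!r} has no rig mapping") from None

    def __contains__(self, au_id: str) -> bool:
        return au_id in self.mapping

    def __iter__(self):
        return iter(self.mapping)

    @classmethod
    def from_csv(cls, path) -> "RigMap":
        mapping: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["au_id"]] = row["channels"].split(";")
                desc[row["au_id"]] = row["facs_description"]
        return cls(mapping, desc)


def load_rig_map() -> RigMap:
    """Load the bundled default AU-to-rig control table."""
    ref = resources.files("aucurve.data").joinpath("rig_map.csv")
    with resources.as_file(ref) as path:
        return RigMap.from_csv(path)
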