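"""Brodmann-area region-of-interest atlas.

The network nodes are the 42 Brodmann areas per hemisphere that standard
EEG source-localization software can resolve: BA 1-47 excluding areas 12,
14, 15, 16 and 26 (not implemented as cortical parcels), giving 84 ROIs.
Ordering is fixed: left hemisphere in ascending BA number, then right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Brodmann areas without a resolvable cortical parcel.
EXCLUDED_BRODMANN_AREAS = frozenset({12, 14, 15, 16, 26})

#: Brodmann numbers used as nodes, ascending.
BRODMANN_NUMBERS = tuple(
    ba for ba in range(1, 48) if ba not in EXCLUDED_BRODMANN_AREAS
)

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered 84-node Brodmann-area atlas with hemisphere tags.

    Attributes
    ----------
    rois : tuple of (int, str)
        ``(brodmann_number, hemisphere)`` pairs in canonical order:
        left hemisphere ascending by BA number, then right.
    """

    rois: tuple[tuple[int, str], ...]
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", tuple(f"BA{ba} {h}" for ba, h in self.rois)
        )

    def __len__(self) -> int:
        return len(self.rois)

    def index(self, label: str) -> int:
        """Position of an ROI label (e.g. ``"BA20 R"``) in the atlas order."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label: {label!r}") from None


def build_roi_atlas() -> ROIAtlas:
    """Return the canonical 84-node atlas (42 BAs per hemisphere)."""
    rois = [(ba, h) for h in HEMISPHERES for ba in BRODMANN_NUMBERS]
    return ROIAtlas(rois=tuple(rois))
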