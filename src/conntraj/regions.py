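"""Region labels for the motor + subcortical parcel set.

Analyses are restricted to a motor-network / subcortical node set. The exact
parcel list used clinically is site configuration; this module provides a
documented default of 45 labels (13 motor-network cortical parcels per
hemisphere, 9 subcortical structures per hemisphere, plus the midline
brainstem) and the ``hemi:class:name`` label syntax used by all file formats.
"""

from __future__ import annotations

from dataclasses import dataclass

HEMISPHERES = ("L", "R", "M")  # left, right, midline
REGION_CLASSES = ("cortical", "subcortical")

_CORTICAL_MOTOR = [
    "M1", "S1", "SMA", "preSMA", "SCEF", "PMd", "PMv",
    "CingulateMotor", "Area24dd", "Area55b", "FEF", "OP4", "Area43",
]

_SUBCORTICAL = [
    "Thalamus", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens", "VentralDC", "Cerebellum",
]


@dataclass(frozen=True)
class RegionLabel:
    """One parcel: name, hemisphere tag and cortical/subcortical class."""

    name: str
    hemi: str
    region_class: str

    def __post_init__(self) -> None:
        if self.hemi not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere tag {self.hemi!r} for region {self.name!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r} for region {self.name!r}")

    def __str__(self) -> str:
        return f"{self.hemi}:{self.region_class}:{self.name}"

    @classmethod
    def parse(cls, text: str) -> "RegionLabel":
        parts = text.strip().split(":")
        if len(parts) != 3:
            raise ValueError(f"region label {text!r} is not of the form hemi:class:name")
        hemi, region_class, name = parts
        return cls(name=name, hemi=hemi, region_class=region_class)


def default_motor_labels(n_regions: int = 45) -> list[RegionLabel]:
    """Default motor + subcortical label set.

    The full set has 45 entries: 26 cortical (13 per hemisphere), 18
    subcortical (9 per hemisphere) and the midline brainstem. Smaller
    ``n_regions`` take a prefix that alternates hemispheres so both stay
    represented.
    """
    full: list[RegionLabel] = []
    for name in _CORTICAL_MOTOR:
        full.append(RegionLabel(name, "L", "cortical"))
        full.append(RegionLabel(name, "R", "cortical"))
    for name in _SUBCORTICAL:
        full.append(RegionLabel(name, "L", "subcortical"))
        full.append(RegionLabel(name, "R", "subcortical"))
    full.append(RegionLabel("Brainstem", "M", "subcortical"))
    if not 2 <= n_regions <= len(full):
        raise ValueError(f"n_regions must be in [2, {len(full)}], got {n_regions}")
    return full[:n_regions]
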