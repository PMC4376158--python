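"""The standardized UKA periprosthetic localization scheme.

Tracer activity around a unicondylar knee arthroplasty is scored in 24
anatomically fixed regions spanning the distal femur (8), the patella (4)
and the proximal tibia (12).  Each region is addressed by a short code:

* bone letter — ``F`` femur, ``T`` tibia, ``P`` patella;
* zone digit — ``1`` medial, ``2`` lateral, ``3`` central around the tibial
  stem (tibia only);
* axial letter — ``s`` superior, ``i`` inferior;
* sagittal letter — ``a`` anterior, ``p`` posterior (absent for the
  patella, which is split only medial/lateral and superior/inferior).

Three auxiliary landmark regions — the proximal femoral mid-shaft
(background reference), the tibial stem tip and the tibial tubercle — exist
alongside the scored grid; only the femoral shaft serves as the denominator
of uptake ratios and none of them appears in the scored enumeration.

Each scored region carries a default summary statistic (``max`` or
``mean``); four femoral regions (F2ip, F1ip, F2ia, F1sp) default to the
mean, all others to the maximum.  A global override to all-max or all-mean
is available for users who prefer a single statistic throughout.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Literal, Optional

import pandas as pd

from .errors import SchemeError

__all__ = [
    "Bone",
    "Zone",
    "Axial",
    "Sagittal",
    "Statistic",
    "RegionCode",
    "AuxiliaryRegion",
    "enumerate_scored_regions",
    "parse_region_label",
    "default_statistic",
    "statistic_map",
    "scheme_table",
]


class Bone(str, enum.Enum):
    FEMUR = "F"
    TIBIA = "T"
    PATELLA = "P"


class Zone(int, enum.Enum):
    MEDIAL = 1
    LATERAL = 2
    CENTRAL = 3  # around the tibial stem; tibia only


class Axial(str, enum.Enum):
    SUPERIOR = "s"
    INFERIOR = "i"


class Sagittal(str, enum.Enum):
    ANTERIOR = "a"
    POSTERIOR = "p"


class Statistic(str, enum.Enum):
    MAX = "max"
    MEAN = "mean"


_LABEL_RE = re.compile(r"^(?P<bone>[FTP])(?P<zone>[123])(?P<axial>[si])(?P<sagittal>[ap])?$")


@dataclass(frozen=True, order=False)
class RegionCode:
    """One cell of the scored localization grid.

    Invariants: zone 3 occurs only on the tibia; the sagittal letter is
    absent exactly when the bone is the patella.  ``label`` round-trips
    bit-exactly through :func:`parse_region_label`.
    """

    bone: Bone
    zone: Zone
    axial: Axial
    sagittal: Optional[Sagittal]

    def __post_init__(self) -> None:
        if self.zone is Zone.CENTRAL and self.bone is not Bone.TIBIA:
            raise SchemeError(
                f"zone: central-around-stem (3) is tibial only, got bone {self.bone.value!r}"
            )
        if self.bone is Bone.PATELLA and self.sagittal is not None:
            raise SchemeError("sagittal: patellar regions carry no anterior/posterior letter")
        if self.bone is not Bone.PATELLA and self.sagittal is None:
            raise SchemeError(f"sagittal: required for bone {self.bone.value!r}")

    @property
    def label(self) -> str:
        """Canonical code, e.g. ``F2ip`` or ``P1s``."""
        tail = self.sagittal.value if self.sagittal is not None else ""
        return f"{self.bone.value}{self.zone.value}{self.axial.value}{tail}"

    def __str__(self) -> str:
        return self.label


class AuxiliaryRegion(str, enum.Enum):
    """Landmark regions outside the scored grid.

    ``FEMORAL_SHAFT_BACKGROUND`` (proximal femoral mid-shaft) is the only
    permitted denominator for uptake ratios.
    """

    FEMORAL_SHAFT_BACKGROUND = "femoral_shaft_background"
    STEM_TIP = "stem_tip"
    TIBIAL_TUBERCLE = "tibial_tubercle"


# Scored grid in its canonical row order (femur, patella, tibia), together
# with each region's default statistic.
_SCHEME_ROWS: tuple[tuple[str, Statistic], ...] = (
    ("F2ip", Statistic.MEAN),
    ("F1ip", Statistic.MEAN),
    ("F2ia", Statistic.MEAN),
    ("F1ia", Statistic.MAX),
    ("F2sa", Statistic.MAX),
    ("F1sa", Statistic.MAX),
    ("F1sp", Statistic.MEAN),
    ("F2sp", Statistic.MAX),
    ("P2s", Statistic.MAX),
    ("P2i", Statistic.MAX),
    ("P1i", Statistic.MAX),
    ("P1s", Statistic.MAX),
    ("T2sp", Statistic.MAX),
    ("T3sp", Statistic.MAX),
    ("T1sp", Statistic.MAX),
    ("T2sa", Statistic.MAX),
    ("T3sa", Statistic.MAX),
    ("T1sa", Statistic.MAX),
    ("T2ia", Statistic.MAX),
    ("T3ia", Statistic.MAX),
    ("T1ia", Statistic.MAX),
    ("T2ip", Statistic.MAX),
    ("T3ip", Statistic.MAX),
    ("T1ip", Statistic.MAX),
)


def parse_region_label(label: str) -> RegionCode:
    """Decode a scored-region code such as ``"T3sp"`` into a :class:`RegionCode`.

    Parsing is case-sensitive (bone uppercase, modifiers lowercase) and
    rejects anything outside the scored grammar, naming the offending field.
    """
    if not isinstance(label, str) or not label:
        raise SchemeError("label: expected a non-empty string")
    m = _LABEL_RE.match(label)
    if m is None:
        _diagnose(label)
        raise SchemeError(f"label: {label!r} does not match the scheme grammar")
    bone = Bone(m.group("bone"))
    zone = Zone(int(m.group("zone")))
    axial = Axial(m.group("axial"))
    sag = Sagittal(m.group("sagittal")) if m.group("sagittal") else None
    if bone is Bone.PATELLA and sag is not None:
        raise SchemeError(f"sagittal: patellar label {label!r} must not carry an a/p letter")
    if bone is not Bone.PATELLA and sag is None:
        raise SchemeError(f"sagittal: label {label!r} is missing the anterior/posterior letter")
    if zone is Zone.CENTRAL and bone is not Bone.TIBIA:
        raise SchemeError(f"zone: central-around-stem in {label!r} is valid for the tibia only")
    return RegionCode(bone=bone, zone=zone, axial=axial, sagittal=sag)


def _diagnose(label: str) -> None:
    """Raise a field-specific error for common malformations."""
    if label[0] not in "FTP":
        raise SchemeError(f"bone: unknown bone letter {label[0]!r} in {label!r} (expected F, T or P)")
    if len(label) < 2 or not label[1].isdigit():
        raise SchemeError(f"zone: missing zone digit in {label!r}")
    if label[1] not in "123":
        raise SchemeError(f"zone: zone {label[1]!r} out of range in {label!r} (expected 1, 2 or 3)")
    if len(label) < 3 or label[2] not in "si":
        raise SchemeError(f"axial: missing or invalid axial letter in {label!r} (expected s or i)")


def enumerate_scored_regions() -> list[RegionCode]:
    """All 24 scored regions in canonical order (femur 8, patella 4, tibia 12)."""
    return [parse_region_label(lbl) for lbl, _ in _SCHEME_ROWS]


_DEFAULT_STATISTIC: dict[str, Statistic] = {lbl: stat for lbl, stat in _SCHEME_ROWS}


def default_statistic(
    region: RegionCode,
    override: Optional[Literal["max", "mean"]] = None,
) -> Statistic:
    """Default summary statistic for a scored region.

    ``override`` forces a single statistic for the whole scheme ("max" or
    "mean"), for users who record one statistic uniformly.
    """
    if isinstance(region, AuxiliaryRegion):
        raise SchemeError(f"auxiliary region {region.value!r} has no scored statistic")
    if override is not None:
        return Statistic(override)
    try:
        return _DEFAULT_STATISTIC[region.label]
    except KeyError:  # pragma: no cover - RegionCode invariants make this unreachable
        raise SchemeError(f"region {region.label!r} is not part of the scored scheme")


def statistic_map(override: Optional[Literal["max", "mean"]] = None) -> dict[str, Statistic]:
    """Label → statistic for every scored region, honouring a global override."""
    return {r.label: default_statistic(r, override) for r in enumerate_scored_regions()}


def scheme_table() -> pd.DataFrame:
    """The scheme as a DataFrame (columns label, bone, zone, axial, sagittal, statistic).

    Loaded from the CSV shipped as package data; the CSV is the serialized
    form of :func:`enumerate_scored_regions` and the default statistics.
    """
    with resources.files("ukaspect.data").joinpath("scheme.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype={"label": str, "bone": str, "axial": str}, keep_default_na=False)
    return df


def _iter_scheme_rows() -> Iterator[dict]:
    for region in enumerate_scored_regions():
        yield {
            "label": region.label,
            "bone": region.bone.value,
            "zone": region.zone.value,
            "axial": region.axial.value,
            "sagittal": region.sagittal.value if region.sagittal else "",
            "statistic": default_statistic(region).value,
        }
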