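"""Registry of the 32 facial soft-tissue landmarks.

Single source of truth for landmark names, abbreviations, organ assignment,
left-right pairing and the per-organ output sizes of the prediction networks.
Naming scheme: paired points are ``<FullName>_<left|right>``, midline points
use the bare full name (spaces replaced by underscores). Within each organ the
canonical ordering is anatomical-table row order with right before left for
paired points; this ordering fixes the layout of every network output vector.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterator


class Organ(str, Enum):
    """The six face regions, each with its own prediction network."""

    EYES = "eyes"
    NOSE = "nose"
    LIPS = "lips"
    CHIN = "chin"
    RIGHT_FACE = "right_face"
    LEFT_FACE = "left_face"


#: Fixed organ ordering used for the detection output (6 x 6 vector).
ORGAN_ORDER: tuple[Organ, ...] = (
    Organ.EYES,
    Organ.NOSE,
    Organ.LIPS,
    Organ.CHIN,
    Organ.RIGHT_FACE,
    Organ.LEFT_FACE,
)


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


@dataclass(frozen=True)
class LandmarkDef:
    name: str
    abbreviation: str
    organ: Organ
    laterality: Laterality
    definition_text: str


@dataclass(frozen=True)
class OrganSpec:
    organ: Organ
    landmark_names: tuple[str, ...]
    n_landmarks: int


# (abbreviation, base name, organ, paired?, definition)
_TABLE: tuple[tuple[str, str, Organ, bool, str], ...] = (
    ("En", "Endocanthion", Organ.EYES, True,
     "The soft tissue point located at the inner commissure of the eye fissure"),
    ("Ex", "Exocanthion", Organ.EYES, True,
     "The soft tissue point located at the outer commissure of the eye fissure"),
    ("Ps", "Palpebrale_superius", Organ.EYES, True,
     "Most superior point on the margin of the upper eyelid"),
    ("Pi", "Palpebrale_inferius", Organ.EYES, True,
     "Most inferior point on the margin of the lower eyelid"),
    ("G", "Glabella", Organ.NOSE, False,
     "Most anterior midpoint on the fronto-orbital soft tissue contour"),
    ("Na", "Nasion", Organ.NOSE, False,
     "Point directly anterior to the nasofrontal suture, in the midline"),
    ("Pn", "Pronasale", Organ.NOSE, False,
     "The most anteriorly protruded point of the apex nasi"),
    ("Sn", "Subnasale", Organ.NOSE, False,
     "Median point at the junction between the lower border of the nasal "
     "septum and the philtrum area"),
    ("A", "Subspinale", Organ.NOSE, False,
     "The deepest point seen in the profile view below the anterior nasal spine"),
    ("Al", "Alare", Organ.NOSE, True,
     "The most lateral point on the nasal ala"),
    ("Ls", "Labiale_superius", Organ.LIPS, False,
     "Midpoint of the vermilion border of the upper lip"),
    ("Sto", "Stomion", Organ.LIPS, False,
     "Midline point of the labial fissure when the lips are naturally closed"),
    ("Li", "Labiale_inferius", Organ.LIPS, False,
     "Midpoint of the vermilion border of the lower lip"),
    ("Cph", "Christa_philtra", Organ.LIPS, True,
     "Point on each elevated margin of the philtrum just before projection "
     "to the vermilion line"),
    ("Ch", "Cheilion", Organ.LIPS, True,
     "Outer corner of the mouth where the outer edges of the upper and lower "
     "vermilions meet"),
    ("B", "Sublabiale", Organ.CHIN, False,
     "Most posterior midpoint of the philtrum of the lower lip"),
    ("Pg", "Pogonion", Organ.CHIN, False,
     "Most anterior median point on the mental eminence of the mandible"),
    ("Gn", "Gnathion", Organ.CHIN, False,
     "Median point halfway between pogonion and menton"),
    ("Me", "Menton", Organ.CHIN, False,
     "Most inferior median point of the mental symphysis"),
    ("Tra", "Tragus", Organ.RIGHT_FACE, True,
     "The most convex point of the tragus at the external ear canal"),
    ("Zy", "Zygion", Organ.RIGHT_FACE, True,
     "The most lateral point on the zygomatic arch"),
    ("Go", "Gonion", Organ.RIGHT_FACE, True,
     "Point on the rounded margin of the angle of the mandible"),
)


def _expand() -> Iterator[LandmarkDef]:
    for abbr, base, organ, paired, definition in _TABLE:
        if organ in (Organ.RIGHT_FACE, Organ.LEFT_FACE):
            # lateral face landmarks belong to side-specific organs
            yield LandmarkDef(f"{base}_right", abbr, Organ.RIGHT_FACE,
                              Laterality.RIGHT, definition)
        elif paired:
            yield LandmarkDef(f"{base}_right", abbr, organ,
                              Laterality.RIGHT, definition)
            yield LandmarkDef(f"{base}_left", abbr, organ,
                              Laterality.LEFT, definition)
        else:
            yield LandmarkDef(base, abbr, organ, Laterality.MIDLINE, definition)
    # left-face mirrors of the right-face landmarks
    for abbr, base, organ, paired, definition in _TABLE:
        if organ is Organ.RIGHT_FACE:
            yield LandmarkDef(f"{base}_left", abbr, Organ.LEFT_FACE,
                              Laterality.LEFT, definition)


@lru_cache(maxsize=1)
def build_registry() -> tuple[LandmarkDef, ...]:
    """Return the 32 landmark definitions in canonical order."""
    defs = tuple(_expand())
    assert len(defs) == 32
    return defs


@lru_cache(maxsize=1)
def landmark_names() -> tuple[str, ...]:
    """All 32 names, ordered by organ (ORGAN_ORDER) then canonical order."""
    names: list[str] = []
    for organ in ORGAN_ORDER:
        names.extend(organ_spec(organ).landmark_names)
    return tuple(names)


def organ_spec(organ: Organ | str) -> OrganSpec:
    """Spec of one organ: its ordered landmark names and output count N."""
    try:
        organ = Organ(organ)
    except ValueError:
        valid = ", ".join(o.value for o in Organ)
        raise ValueError(f"unknown organ {organ!r}; valid organs: {valid}") from None
    names = tuple(d.name for d in build_registry() if d.organ is organ)
    return OrganSpec(organ=organ, landmark_names=names, n_landmarks=len(names))


@lru_cache(maxsize=1)
def symmetric_pairs() -> tuple[tuple[str, str], ...]:
    """The 10 left-right symmetric pairs as (name_left, name_right)."""
    reg = build_registry()
    rights = {d.abbreviation: d for d in reg if d.laterality is Laterality.RIGHT}
    pairs = []
    for d in reg:
        if d.laterality is Laterality.LEFT:
            pairs.append((d.name, rights[d.abbreviation].name))
    return tuple(pairs)


def registry_to_json() -> str:
    """Serialize the registry for downstream tools."""
    return json.dumps([asdict(d) for d in build_registry()], indent=2)
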