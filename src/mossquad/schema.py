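"""Fixed class schema shared by every pipeline stage.

The classifier assigns ground-cover objects to a closed set of classes:
three moss health states (healthy, stressed, moribund), plus lichen, rock,
snow, water, wet moss, shadow, and an explicit ``unclassified`` terminal
class.  Pixels outside the physical quadrat are ``outside_quadrat`` and are
excluded from cover denominators.
"""

from __future__ import annotations

# Integer codes used in class rasters. 0 is reserved for outside-quadrat so
# that paletted exports render the analysis extent naturally.
OUTSIDE_QUADRAT = "outside_quadrat"

CLASS_NAMES: tuple[str, ...] = (
    OUTSIDE_QUADRAT,   # 0
    "healthy_moss",    # 1
    "stressed_moss",   # 2
    "moribund_moss",   # 3
    "lichen",          # 4
    "rock",            # 5
    "snow",            # 6
    "water",           # 7
    "wet_moss",        # 8
    "shadow",          # 9
    "unclassified",    # 10
)

CLASS_CODE: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}
N_CLASSES = len(CLASS_NAMES)

#: Cover classes reported in percent-cover tables (everything but outside).
COVER_CLASSES: tuple[str, ...] = CLASS_NAMES[1:]

# Manually digitized mask layers.  Precedence when polygons overlap is the
# order below (earlier wins): the frame is absolute, then water, snow,
# wet moss, the two lichen layers, and rock.
MASK_LAYERS: tuple[str, ...] = (
    "quadrat_frame",
    "water",
    "snow",
    "wet_moss",
    "macrolichen",
    "crustose_lichen",
    "rock",
)

#: Class each mask layer maps to in the final class raster.
MASK_LAYER_CLASS: dict[str, str] = {
    "quadrat_frame": OUTSIDE_QUADRAT,
    "water": "water",
    "snow": "snow",
    "wet_moss": "wet_moss",
    "macrolichen": "lichen",
    "crustose_lichen": "lichen",
    "rock": "rock",
}

# Provenance codes for ClassMap pixels.
PROVENANCE_NAMES: tuple[str, ...] = ("none", "mask", "rule", "context_rule", "manual_correction")
PROVENANCE_CODE: dict[str, int] = {name: i for i, name in enumerate(PROVENANCE_NAMES)}


class SchemaError(ValueError):
    """Raised for names outside the fixed class/mask schema."""


def class_code(name: str) -> int:
    try:
        return CLASS_CODE[name]
    except KeyError:
        raise SchemaError(f"unknown class {name!r}; valid classes: {', '.join(CLASS_NAMES)}") from None
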