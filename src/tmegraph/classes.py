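"""Histology class registry.

Sixteen tissue classes plus a background class, coded 0-16. The integer
codes double as grid values in histology maps and as confusion-matrix
indices, so they must stay dense and stable.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HistologyClass:
    """A histology class: integer code, canonical name, render color."""

    id: int
    name: str
    color: tuple[int, int, int]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.id}:{self.name}"


# Code order follows the tile-level confusion-matrix convention
# (0 stroma ... 15 mucinous change, 16 background).
_CLASS_DEFS: list[tuple[int, str, tuple[int, int, int]]] = [
    (0, "stroma", (0, 160, 0)),
    (1, "tumor", (200, 0, 0)),
    (2, "tertiaryTIL", (130, 0, 200)),
    (3, "stromaTIL", (255, 140, 0)),
    (4, "normal tissue", (90, 200, 250)),
    (5, "PGCC", (150, 75, 0)),
    (6, "blood vessels", (255, 0, 120)),
    (7, "necrosis", (60, 60, 60)),
    (8, "microvessel (MVD)", (0, 0, 200)),
    (9, "benign tumor", (0, 120, 255)),
    (10, "tumorTIL", (170, 0, 255)),
    (11, "in situ carcinoma", (255, 200, 0)),
    (12, "hemorrhage", (140, 0, 30)),
    (13, "adipocytes", (255, 255, 150)),
    (14, "apocrine change", (0, 200, 170)),
    (15, "mucinous change", (180, 220, 255)),
    (16, "background", (245, 245, 245)),
]

CLASSES: tuple[HistologyClass, ...] = tuple(
    HistologyClass(i, n, c) for i, n, c in _CLASS_DEFS
)

#: The 16 tissue classes (background excluded).
TISSUE_CLASSES: tuple[HistologyClass, ...] = CLASSES[:-1]

BACKGROUND: HistologyClass = CLASSES[-1]

#: Sentinel grid value for cells with no retained tile.
EMPTY_CELL: int = -1

_BY_NAME = {c.name: c for c in CLASSES}
_BY_ID = {c.id: c for c in CLASSES}

# Common aliases seen in annotation exports.
_ALIASES = {
    "tTIL": "tumorTIL",
    "sTIL": "stromaTIL",
    "teTIL": "tertiaryTIL",
    "microvessel": "microvessel (MVD)",
    "MVD": "microvessel (MVD)",
    "normal": "normal tissue",
}


def class_by_name(name: str) -> HistologyClass:
    """Look up a class by name (aliases allowed). Raises KeyError with the
    list of valid names on an unknown label."""
    key = _ALIASES.get(name, name)
    try:
        return _BY_NAME[key]
    except KeyError:
        valid = ", ".join(sorted(_BY_NAME))
        raise KeyError(f"unknown histology class {name!r}; valid names: {valid}") from None


def class_by_id(class_id: int) -> HistologyClass:
    return _BY_ID[class_id]


def default_palette() -> dict[int, tuple[int, int, int]]:
    """class id -> RGB. Bijective by construction (asserted)."""
    palette = {c.id: c.color for c in CLASSES}
    assert len(set(palette.values())) == len(palette), "palette must be a bijection"
    return palette
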