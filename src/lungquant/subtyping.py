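"""Area-based LUAD-vs-LUSC subtyping from paired tissue masks.

The subtype mask carries glandular/squamous labels (plus tumor stroma,
necrosis and mucin) over the same raster geometry as the main tissue
mask, but is only interpreted where the main mask recognized epithelial
tumor: subtype pixels falling elsewhere are ignored, never reassigned.
The slide call is the argmax of the LUAD/LUSC area percentages over that
epithelial support; a winning percentage in the closed 40-60% band flags
the slide as borderline (typically a poorly differentiated solid tumor
needing immunohistochemistry).  Case-level calls pool raw pixel counts
across slides (area weighting), so they are invariant to how tumor is
split across blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ShapeError
from .masks import ClassLegend, LegendEntry, TissueMask, profile_areas

logger = logging.getLogger(__name__)

#: Closed interval of winning percentages flagged as borderline.
BORDERLINE_LOW = 40.0
BORDERLINE_HIGH = 60.0

_SUBTYPE_ENTRIES = (
    ("BACK", "background", (255, 255, 255)),
    ("TUMOR_LUAD", "tumor_region", (60, 120, 220)),
    ("TUMOR_LUSC", "tumor_region", (220, 80, 60)),
    ("TU_STROMA", "tumor_region", (255, 160, 120)),
    ("NECROSIS", "tumor_region", (30, 30, 120)),
    ("MUCIN", "tumor_region", (140, 210, 240)),
)


def subtype_legend(mpp: float = 1.0) -> ClassLegend:
    """Six-class legend of the subtype mask (LUAD/LUSC + context classes)."""
    return ClassLegend(
        entries=tuple(
            LegendEntry(i, name, group, color)
            for i, (name, group, color) in enumerate(_SUBTYPE_ENTRIES)
        ),
        mpp=mpp,
    )


@dataclass
class SubtypeCall:
    """Slide- or case-level subtype decision with its area evidence.

    ``pct_luad + pct_lusc == 100`` whenever evaluable tumor exists; the
    evaluated pixels are exactly the epithelial-tumor pixels that received
    a LUAD or LUSC label.  ``call == "NO_TUMOR"`` marks a slide/case with
    no evaluable tumor (explicit outcome, not an error).  Raw pixel
    tallies are retained for case-level pooling.
    """

    call: str  # "LUAD" | "LUSC" | "NO_TUMOR"
    pct_luad: float
    pct_lusc: float
    borderline: bool
    mucin_pct: float
    level: str  # "slide" | "case"
    luad_px: int = 0
    lusc_px: int = 0
    mucin_px: int = 0
    tu_stroma_px: int = 0
    origin: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.call != "NO_TUMOR"


def restrict_to_tumor(main: TissueMask, subtype: TissueMask) -> np.ndarray:
    """Binary support of pixels the main mask calls epithelial tumor.

    This is the only support over which subtype labels are tallied.
    """
    if main.shape != subtype.shape:
        raise ShapeError(
            f"main mask shape {main.shape} != subtype mask shape {subtype.shape}"
        )
    return main.class_support("TUMOR")


def _tally(main: TissueMask, subtype: TissueMask) -> dict[str, int]:
    support = restrict_to_tumor(main, subtype)
    prof = profile_areas(subtype, restrict_to=support)
    return prof.pixel_counts


def _call_from_counts(
    luad: int,
    lusc: int,
    mucin: int,
    tu_stroma: int,
    level: str,
    origin: str | None = None,
) -> SubtypeCall:
    evaluated = luad + lusc
    if evaluated == 0:
        return SubtypeCall(
            call="NO_TUMOR",
            pct_luad=float("nan"),
            pct_lusc=float("nan"),
            borderline=False,
            mucin_pct=float("nan"),
            level=level,
            origin=origin,
        )
    pct_luad = 100.0 * luad / evaluated
    pct_lusc = 100.0 - pct_luad
    if luad == lusc:
        # exact tie: deterministic rule, routed to review via borderline flag
        call = "LUAD"
        logger.warning(
            "exact 50/50 LUAD/LUSC tie (%s %s): calling LUAD, borderline",
            level, origin or "",
        )
    else:
        call = "LUAD" if luad > lusc else "LUSC"
    winning = max(pct_luad, pct_lusc)
    borderline = BORDERLINE_LOW <= winning <= BORDERLINE_HIGH
    mucin_denom = mucin + evaluated + tu_stroma
    mucin_pct = 100.0 * mucin / mucin_denom if mucin_denom else 0.0
    return SubtypeCall(
        call=call,
        pct_luad=pct_luad,
        pct_lusc=pct_lusc,
        borderline=borderline,
        mucin_pct=mucin_pct,
        level=level,
        luad_px=luad,
        lusc_px=lusc,
        mucin_px=mucin,
        tu_stroma_px=tu_stroma,
        origin=origin,
    )


def classify_slide(main: TissueMask, subtype: TissueMask) -> SubtypeCall:
    """Classify one slide from its main and subtype masks.

    ``pct_luad = 100 * |LUAD px| / (|LUAD px| + |LUSC px|)`` over the
    epithelial-tumor support.  An exact 50/50 tie is called LUAD with
    ``borderline=True`` and a logged warning; the flag routes such slides
    to human review either way.
    """
    counts = _tally(main, subtype)
    return _call_from_counts(
        counts["TUMOR_LUAD"],
        counts["TUMOR_LUSC"],
        counts["MUCIN"],
        counts["TU_STROMA"],
        level="slide",
        origin=main.origin_slide,
    )


def mucin_fraction(subtype: TissueMask, main: TissueMask) -> float | None:
    """Percent mucin area: ``100 * mucin / (mucin + tumor + tumor stroma)``.

    Tumor counts both subtype labels (LUAD + LUSC); all tallies are taken
    over the epithelial-tumor support of the main mask.  Returns ``None``
    when the denominator is zero (no evaluable tumor).
    """
    counts = _tally(main, subtype)
    denom = (
        counts["MUCIN"]
        + counts["TUMOR_LUAD"]
        + counts["TUMOR_LUSC"]
        + counts["TU_STROMA"]
    )
    if denom == 0:
        return None
    return 100.0 * counts["MUCIN"] / denom


def aggregate_case(slide_calls: Sequence[SubtypeCall], origin: str | None = None) -> SubtypeCall:
    """Pool slide calls into one case-level call.

    Raw LUAD/LUSC pixel counts are pooled across evaluable slides (area
    weighting) and the case is classified exactly like a slide.  Slides
    without evaluable tumor contribute nothing; if no slide is evaluable
    the case call is ``NO_TUMOR``.  Pooling is order-invariant and, for a
    single slide, reduces to the slide call.
    """
    if not slide_calls:
        raise ValueError("aggregate_case requires at least one slide call")
    luad = sum(c.luad_px for c in slide_calls if c.evaluable)
    lusc = sum(c.lusc_px for c in slide_calls if c.evaluable)
    mucin = sum(c.mucin_px for c in slide_calls if c.evaluable)
    stroma = sum(c.tu_stroma_px for c in slide_calls if c.evaluable)
    return _call_from_counts(luad, lusc, mucin, stroma, level="case", origin=origin)
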