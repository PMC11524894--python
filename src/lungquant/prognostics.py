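"""Explainable prognostic parameters from a tissue mask.

Four quantities are computed from the segmentation mask of a slide:

* ``TLS-TD``  — qualified TLS area / (epithelial tumor + tumor stroma area);
* ``NECR-TD`` — tumor-associated necrosis area / the same denominator;
* ``T/NR``   — qualified TLS area / tumor-associated necrosis area
  (undefined when there is no qualified necrosis — no normalization by
  tumor area is applied);
* ``T+NR``   — a three-level prognostic group (PG1-PG3) built from the
  dichotomized densities.

Objects (connected components of TLS or necrosis) are extracted with no
size filtering of any kind — single-pixel components count.  An object
qualifies for the densities when it is intratumoral (touches the tumor
region: epithelial tumor, tumor stroma, necrosis or mucin) or immediately
peritumoral (within a configurable distance of the tumor region boundary,
250 um by default).  Components far from any tumor — e.g. lymphoid
aggregates or autolytic debris out in benign parenchyma — are excluded.

Dichotomization uses the optimal-cutoff principle: candidate cutoffs on a
percentile grid are scored with the two-group log-rank statistic and the
maximizer (subject to a minimum group size) is retained, along with the
full statistic trace for audit.  The same cutoff is intended to be reused
across survival endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import LegendError, StratificationError
from .masks import TissueMask
from .survival import logrank_statistic

Qualification = Literal["intratumoral", "peritumoral", "non_tumor_associated"]

#: Default "immediate peritumoral" distance in microns.
DEFAULT_PERITUMORAL_UM = 250.0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass
class TissueObject:
    """One connected component of a tissue class."""

    class_name: str
    pixels: np.ndarray  # (n, 2) array of (row, col) coordinates
    area_px: int
    area_um2: float
    qualification: Qualification | None = None
    min_distance_um: float | None = None  # to the tumor-region reference


@dataclass
class PrognosticScores:
    """Per-slide (or pooled per-case) prognostic parameters.

    ``t_nr`` is ``None`` when no qualified necrosis exists (ratio
    undefined; such cases are excluded from T/NR stratification but keep
    their TLS-TD/NECR-TD and prognostic group).  All stored densities are
    raw ratios — any display upscaling (x1,000 etc.) is presentation
    only.
    """

    tls_td: float
    necr_td: float
    t_nr: float | None
    tls_area_px: int
    necr_area_px: int
    denominator_px: int
    peritumoral_dist_um: float
    n_tls_objects: int = 0
    n_necr_objects: int = 0
    tls_group: str | None = None
    necr_group: str | None = None
    t_nr_group: str | None = None
    pg: str | None = None


@dataclass
class CutoffResult:
    """Optimal-cutoff search result with its full audit trace."""

    parameter: str
    cutoff: float
    grid: np.ndarray  # candidate cutoff values searched
    statistics: np.ndarray  # log-rank chi-square per candidate (NaN = inadmissible)
    p_value: float
    n_low: int
    n_high: int
    min_group_size: int


def extract_objects(
    mask: TissueMask, class_name: str, connectivity: int = 8
) -> list[TissueObject]:
    """Connected components of one class; no size filtering whatsoever."""
    if not mask.legend.has_class(class_name):
        raise LegendError(f"class {class_name!r} not in legend")
    support = mask.class_support(class_name)
    labeled, n = ndimage.label(support, structure=_structure(connectivity))
    objects: list[TissueObject] = []
    mpp2 = mask.mpp**2
    for i in range(1, n + 1):
        coords = np.argwhere(labeled == i)
        objects.append(
            TissueObject(
                class_name=class_name,
                pixels=coords,
                area_px=len(coords),
                area_um2=len(coords) * mpp2,
            )
        )
    return objects


def tumor_region_support(
    mask: TissueMask, exclude_class: str | None = None
) -> np.ndarray:
    """Boolean raster of the tumor region (TUMOR, TU_STROMA, NECROSIS, MUCIN).

    ``exclude_class`` drops one class from the union — used when
    qualifying objects of a class that is itself part of the tumor region
    (necrosis), so an object never qualifies against its own pixels.
    """
    ids = [
        i for i in mask.legend.tumor_region_ids()
        if exclude_class is None or i != mask.legend.id_of(exclude_class)
    ]
    return np.isin(mask.labels, ids)


def qualify_objects(
    objects: Sequence[TissueObject],
    mask: TissueMask,
    peritumoral_dist_um: float = DEFAULT_PERITUMORAL_UM,
) -> list[TissueObject]:
    """Label each object intratumoral / peritumoral / non-tumor-associated.

    The reference region is the tumor region minus the object's own
    class.  An object is intratumoral when some pixel touches the
    reference under 8-neighborhood adjacency (center-to-center distance
    <= sqrt(2) px), peritumoral when its minimum Euclidean distance to the
    reference is within ``peritumoral_dist_um`` microns, and
    non-tumor-associated otherwise (excluded from every density).
    Qualification is filled in place and the list returned.
    """
    if peritumoral_dist_um < 0:
        raise ValueError("peritumoral_dist_um must be >= 0")
    if not objects:
        return list(objects)
    mpp = mask.mpp
    touch_um = math.sqrt(2.0) * mpp * (1 + 1e-9)
    by_class: dict[str, np.ndarray] = {}
    for obj in objects:
        ref = by_class.get(obj.class_name)
        if ref is None:
            reference = tumor_region_support(mask, exclude_class=obj.class_name)
            if reference.any():
                # distance (um) from every pixel to the nearest reference pixel
                ref = ndimage.distance_transform_edt(~reference, sampling=mpp)
            else:
                ref = np.full(mask.shape, np.inf)
            by_class[obj.class_name] = ref
        d = float(ref[obj.pixels[:, 0], obj.pixels[:, 1]].min())
        obj.min_distance_um = d
        if d <= touch_um:
            obj.qualification = "intratumoral"
        elif d <= peritumoral_dist_um:
            obj.qualification = "peritumoral"
        else:
            obj.qualification = "non_tumor_associated"
    return list(objects)


def _qualified_area_px(
    mask: TissueMask,
    class_name: str,
    peritumoral_dist_um: float,
    connectivity: int,
) -> tuple[int, int]:
    """(qualified pixel area, number of objects of the class)."""
    objs = qualify_objects(
        extract_objects(mask, class_name, connectivity=connectivity),
        mask,
        peritumoral_dist_um=peritumoral_dist_um,
    )
    area = sum(o.area_px for o in objs if o.qualification != "non_tumor_associated")
    return area, len(objs)


def _denominator_px(mask: TissueMask) -> int:
    """Pixel area of epithelial tumor + tumor stroma."""
    legend = mask.legend
    counts = np.bincount(mask.labels.ravel(), minlength=legend.n_classes)
    return int(counts[legend.id_of("TUMOR")] + counts[legend.id_of("TU_STROMA")])


def compute_tls_td(
    mask: TissueMask,
    peritumoral_dist_um: float = DEFAULT_PERITUMORAL_UM,
    connectivity: int = 8,
) -> float | None:
    """TLS tumor density, or ``None`` when the slide has no tumor."""
    denom = _denominator_px(mask)
    if denom == 0:
        return None
    area, _ = _qualified_area_px(mask, "TLS", peritumoral_dist_um, connectivity)
    return area / denom


def compute_necr_td(
    mask: TissueMask,
    peritumoral_dist_um: float = DEFAULT_PERITUMORAL_UM,
    connectivity: int = 8,
) -> float | None:
    """Necrosis tumor density (tumor-associated necrosis only)."""
    denom = _denominator_px(mask)
    if denom == 0:
        return None
    area, _ = _qualified_area_px(mask, "NECROSIS", peritumoral_dist_um, connectivity)
    return area / denom


def compute_t_nr(
    mask: TissueMask,
    peritumoral_dist_um: float = DEFAULT_PERITUMORAL_UM,
    connectivity: int = 8,
) -> float | None:
    """TLS / necrosis area ratio; ``None`` when qualified necrosis is zero."""
    tls, _ = _qualified_area_px(mask, "TLS", peritumoral_dist_um, connectivity)
    necr, _ = _qualified_area_px(mask, "NECROSIS", peritumoral_dist_um, connectivity)
    if necr == 0:
        return None
    return tls / necr


def compute_scores(
    mask: TissueMask,
    peritumoral_dist_um: float = DEFAULT_PERITUMORAL_UM,
    connectivity: int = 8,
) -> PrognosticScores | None:
    """All prognostic parameters of one mask; ``None`` when no tumor."""
    denom = _denominator_px(mask)
    if denom == 0:
        return None
    tls, n_tls = _qualified_area_px(mask, "TLS", peritumoral_dist_um, connectivity)
    necr, n_necr = _qualified_area_px(
        mask, "NECROSIS", peritumoral_dist_um, connectivity
    )
    return PrognosticScores(
        tls_td=tls / denom,
        necr_td=necr / denom,
        t_nr=(tls / necr) if necr > 0 else None,
        tls_area_px=tls,
        necr_area_px=necr,
        denominator_px=denom,
        peritumoral_dist_um=peritumoral_dist_um,
        n_tls_objects=n_tls,
        n_necr_objects=n_necr,
    )


# -- cohort-level dichotomization ---------------------------------------

#: Percentile grid searched for the optimal cutoff.
CUTOFF_PERCENTILES = np.arange(10.0, 90.0 + 1e-9, 2.5)
#: Minimum size of each dichotomized group, as a fraction of the cohort.
MIN_GROUP_FRACTION = 0.10


def find_optimal_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    parameter: str = "value",
    percentiles: np.ndarray = CUTOFF_PERCENTILES,
    min_group_fraction: float = MIN_GROUP_FRACTION,
) -> CutoffResult:
    """Optimal-cutoff dichotomization by maximally selected log-rank statistic.

    Candidate cutoffs are the cohort percentiles of ``values``; at each
    candidate the cohort splits into low (<= cutoff) and high (> cutoff)
    and the two-group log-rank chi-square is computed.  The cutoff with
    the largest statistic among candidates leaving at least
    ``min_group_fraction`` of cases in each group wins (ties broken
    toward the smaller cutoff).  The full trace is returned so users can
    audit the scan or apply multiplicity corrections; none is applied
    here.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (len(values) == len(times) == len(events)):
        raise ValueError("values, times and events must have equal length")
    n = len(values)
    if events.sum() < 1:
        raise StratificationError("no events in cohort; cannot stratify")
    min_size = max(2, math.ceil(min_group_fraction * n))
    grid = np.unique(np.percentile(values, percentiles))
    stats = np.full(len(grid), np.nan)
    for i, c in enumerate(grid):
        low = values <= c
        n_low = int(low.sum())
        n_high = n - n_low
        if n_low < min_size or n_high < min_size:
            continue
        try:
            chi2, _ = logrank_statistic(
                times[low], events[low], times[~low], events[~low]
            )
        except Exception:
            continue
        stats[i] = chi2
    if np.all(np.isnan(stats)):
        raise StratificationError(
            f"no admissible cutoff for {parameter!r}: every candidate violates "
            f"the minimum group size ({min_size}) or yields no testable split"
        )
    best = int(np.nanargmax(stats))
    cutoff = float(grid[best])
    low = values <= cutoff
    _, p = logrank_statistic(times[low], events[low], times[~low], events[~low])
    return CutoffResult(
        parameter=parameter,
        cutoff=cutoff,
        grid=grid,
        statistics=stats,
        p_value=float(p),
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
        min_group_size=min_size,
    )


def dichotomize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """Map values to 'low' (<= cutoff) / 'high' (> cutoff) labels."""
    values = np.asarray(values, dtype=float)
    return np.where(values > cutoff, "high", "low")


def assign_prognostic_group(tls_group: str, necr_group: str) -> str:
    """Cumulative T+NR prognostic group from the two dichotomized densities.

    PG1 (best): TLS high and necrosis low.  PG3 (worst): TLS low and
    necrosis high.  PG2: the two discordant-favorability combinations
    (both high or both low).  The four input combinations map onto
    exactly three groups.
    """
    for name, g in (("tls_group", tls_group), ("necr_group", necr_group)):
        if g not in ("low", "high"):
            raise ValueError(f"{name} must be 'low' or 'high', got {g!r}")
    if tls_group == "high" and necr_group == "low":
        return "PG1"
    if tls_group == "low" and necr_group == "high":
        return "PG3"
    return "PG2"
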