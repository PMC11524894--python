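"""Class legend, label-raster data model and exact per-class area profiles.

The universal substrate of the package is a single-channel integer label
raster (a "tissue mask") in which every pixel carries the id of one tissue
class.  A :class:`ClassLegend` declares the id -> name -> group mapping and
the raster resolution in microns per pixel (MPP); a :class:`TissueMask`
couples a raster to its legend; :func:`profile_areas` turns a mask into
exact per-class pixel and area tallies.

The default legend is the 12-entry scheme used throughout the package:
11 tissue classes (epithelial tumor, tumor stroma, necrosis, mucin, TLS,
benign lung, non-tumor stroma, bronchial mucosa, blood, peribronchial
glands, cartilage) plus slide background.  The pre-merge 15-entry
annotation scheme (14 tissue classes + background), in which non-tumor
stroma is still split into connective tissue, fat, muscle and vessels, is
available via :func:`annotation_legend`; :func:`merge_classes` collapses it
to the working scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, LegendError, ShapeError

GROUPS = ("tumor_region", "benign", "background")

#: Classes whose union constitutes the "tumor region" of a slide.
TUMOR_REGION_CLASSES = ("TUMOR", "TU_STROMA", "NECROSIS", "MUCIN")

# (name, group, display color) in id order; BACK deliberately takes id 0 so
# that zero-initialized rasters are background.
_DEFAULT_ENTRIES = (
    ("BACK", "background", (255, 255, 255)),
    ("TUMOR", "tumor_region", (200, 0, 0)),
    ("TU_STROMA", "tumor_region", (255, 160, 120)),
    ("NECROSIS", "tumor_region", (30, 30, 120)),
    ("MUCIN", "tumor_region", (140, 210, 240)),
    ("TLS", "benign", (250, 220, 0)),
    ("LUNG_BENIGN", "benign", (150, 220, 150)),
    ("STROMA", "benign", (190, 190, 190)),
    ("BRONCH", "benign", (150, 90, 40)),
    ("BLOOD", "benign", (255, 60, 60)),
    ("GLAND_PERIBR", "benign", (90, 160, 200)),
    ("CARTIL", "benign", (120, 120, 200)),
)

# Pre-merge annotation scheme: STROMA is still split into its four
# connective-tissue constituents.
_CONNECTIVE_CLASSES = ("CONN_STROMA", "FAT", "MUSCLE", "VESSEL")

_ANNOTATION_ENTRIES = tuple(
    e for e in _DEFAULT_ENTRIES if e[0] != "STROMA"
) + tuple((n, "benign", (190, 190, 190)) for n in _CONNECTIVE_CLASSES)


@dataclass(frozen=True)
class LegendEntry:
    class_id: int
    class_name: str
    group: str
    color: tuple[int, int, int] | None = None


@dataclass(frozen=True)
class ClassLegend:
    """Ordered id -> class mapping plus raster resolution.

    Parameters
    ----------
    entries
        One :class:`LegendEntry` per class.  Ids must be unique and
        contiguous from 0; names unique; exactly one entry must have
        ``group == "background"``.
    mpp
        Microns per pixel of rasters interpreted under this legend.
    """

    entries: tuple[LegendEntry, ...]
    mpp: float = 1.0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ConfigError(f"mpp must be positive, got {self.mpp}")
        ids = [e.class_id for e in self.entries]
        names = [e.class_name for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigError(f"duplicate class ids: {dup}")
        if sorted(ids) != list(range(len(ids))):
            raise ConfigError(
                f"class ids must be contiguous from 0, got {sorted(ids)}"
            )
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate class names: {dup}")
        for e in self.entries:
            if e.group not in GROUPS:
                raise ConfigError(
                    f"entry {e.class_name!r}: unknown group {e.group!r}"
                )
        n_back = sum(e.group == "background" for e in self.entries)
        if n_back != 1:
            raise ConfigError(
                f"exactly one background class required, found {n_back}"
            )

    # -- lookups ---------------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(e.class_name for e in sorted(self.entries, key=lambda e: e.class_id))

    @property
    def background_id(self) -> int:
        return next(e.class_id for e in self.entries if e.group == "background")

    def id_of(self, class_name: str) -> int:
        for e in self.entries:
            if e.class_name == class_name:
                return e.class_id
        raise LegendError(f"unknown class name {class_name!r}")

    def name_of(self, class_id: int) -> str:
        for e in self.entries:
            if e.class_id == class_id:
                return e.class_name
        raise LegendError(f"unknown class id {class_id}")

    def has_class(self, class_name: str) -> bool:
        return any(e.class_name == class_name for e in self.entries)

    def ids_of_group(self, group: str) -> tuple[int, ...]:
        return tuple(e.class_id for e in self.entries if e.group == group)

    def tumor_region_ids(self) -> tuple[int, ...]:
        """Ids of the classes constituting the tumor region."""
        return tuple(
            self.id_of(n) for n in TUMOR_REGION_CLASSES if self.has_class(n)
        )

    def tissue_class_names(self) -> tuple[str, ...]:
        """All class names except background."""
        return tuple(
            e.class_name for e in sorted(self.entries, key=lambda e: e.class_id)
            if e.group != "background"
        )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mpp": self.mpp,
            "classes": [
                {
                    "id": e.class_id,
                    "name": e.class_name,
                    "group": e.group,
                    "color": list(e.color) if e.color else None,
                }
                for e in sorted(self.entries, key=lambda e: e.class_id)
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassLegend":
        try:
            classes = d["classes"]
        except (KeyError, TypeError):
            raise ConfigError("legend config must contain a 'classes' list")
        entries = []
        for c in classes:
            try:
                entries.append(
                    LegendEntry(
                        class_id=int(c["id"]),
                        class_name=str(c["name"]),
                        group=str(c["group"]),
                        color=tuple(c["color"]) if c.get("color") else None,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"malformed legend entry {c!r}: {exc}") from exc
        return cls(entries=tuple(entries), mpp=float(d.get("mpp", 1.0)))


def default_legend(mpp: float = 1.0) -> ClassLegend:
    """The working 12-entry legend: 11 tissue classes + background."""
    return ClassLegend(
        entries=tuple(
            LegendEntry(i, name, group, color)
            for i, (name, group, color) in enumerate(_DEFAULT_ENTRIES)
        ),
        mpp=mpp,
    )


def annotation_legend(mpp: float = 1.0) -> ClassLegend:
    """The pre-merge annotation scheme: 14 tissue classes + background.

    Non-tumor stroma appears as four separate connective-tissue classes
    (CONN_STROMA, FAT, MUSCLE, VESSEL) instead of the single STROMA class
    of the working legend.
    """
    return ClassLegend(
        entries=tuple(
            LegendEntry(i, name, group, color)
            for i, (name, group, color) in enumerate(_ANNOTATION_ENTRIES)
        ),
        mpp=mpp,
    )


def connective_tissue_classes() -> tuple[str, ...]:
    """The four connective-tissue classes merged into STROMA."""
    return _CONNECTIVE_CLASSES


def merge_classes(
    legend: ClassLegend,
    merge_names: Sequence[str],
    new_name: str,
    new_group: str = "benign",
) -> tuple[ClassLegend, np.ndarray]:
    """Merge several classes of a legend into one.

    Returns the merged legend (ids re-packed to stay contiguous) and an
    ``id_map`` array such that ``id_map[old_labels]`` converts a raster
    from the old to the new scheme.  The merged class takes the position
    of the first merged entry in id order.
    """
    merge_set = set(merge_names)
    unknown = merge_set - set(legend.class_names)
    if unknown:
        raise LegendError(f"cannot merge unknown classes: {sorted(unknown)}")
    if len(merge_set) < 2:
        raise LegendError("merging requires at least two classes")

    old_sorted = sorted(legend.entries, key=lambda e: e.class_id)
    id_map = np.zeros(len(old_sorted), dtype=np.int64)
    new_entries: list[LegendEntry] = []
    merged_id: int | None = None
    for e in old_sorted:
        if e.class_name in merge_set:
            if merged_id is None:
                merged_id = len(new_entries)
                new_entries.append(
                    LegendEntry(merged_id, new_name, new_group, e.color)
                )
            id_map[e.class_id] = merged_id
        else:
            nid = len(new_entries)
            new_entries.append(LegendEntry(nid, e.class_name, e.group, e.color))
            id_map[e.class_id] = nid
    return ClassLegend(entries=tuple(new_entries), mpp=legend.mpp), id_map


def default_legend_path() -> Path:
    """Path of the shipped default legend config (YAML)."""
    return Path(__file__).parent / "data" / "default_legend.yaml"


def load_legend(config_path: str | Path) -> ClassLegend:
    """Load and validate a legend from a YAML or JSON config file."""
    path = Path(config_path)
    if not path.exists():
        raise ConfigError(f"legend config not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse legend config {path}: {exc}") from exc
    return ClassLegend.from_dict(data)


def save_legend(legend: ClassLegend, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(legend.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(legend.to_dict(), sort_keys=False))


@dataclass
class TissueMask:
    """A 2-D class-id raster bound to its legend.

    Pixel coordinates are 0-based, row-major ``(row, col)``.
    """

    labels: np.ndarray
    legend: ClassLegend
    origin_slide: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or min(self.labels.shape) < 1:
            raise ShapeError(
                f"labels must be a non-empty 2-D raster, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LegendError("labels must be an integer raster")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 0 or hi >= self.legend.n_classes:
            raise LegendError(
                f"raster values span [{lo}, {hi}] but legend defines ids "
                f"0..{self.legend.n_classes - 1}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def mpp(self) -> float:
        return self.legend.mpp

    def class_support(self, class_name: str) -> np.ndarray:
        """Boolean raster of pixels carrying ``class_name``."""
        return self.labels == self.legend.id_of(class_name)


def mask_from_rgb(rgb: np.ndarray, legend: ClassLegend, **kw) -> TissueMask:
    """Ingest an RGB color-coded mask via the legend's color table."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ShapeError(f"expected HxWx3 RGB raster, got shape {rgb.shape}")
    labels = np.full(rgb.shape[:2], -1, dtype=np.int64)
    for e in legend.entries:
        if e.color is None:
            raise LegendError(
                f"class {e.class_name!r} has no color; cannot ingest RGB mask"
            )
        hit = np.all(rgb[:, :, :3] == np.array(e.color), axis=2)
        labels[hit] = e.class_id
    if (labels < 0).any():
        n = int((labels < 0).sum())
        raise LegendError(f"{n} pixels have colors absent from the legend")
    return TissueMask(labels=labels, legend=legend, **kw)


@dataclass
class ClassAreaProfile:
    """Per-class pixel and area tallies for a mask or region."""

    pixel_counts: dict[str, int]
    mpp: float
    origin_slide: str | None = None
    area_um2: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.area_um2 = {
            name: count * self.mpp**2 for name, count in self.pixel_counts.items()
        }

    @property
    def total_pixels(self) -> int:
        return sum(self.pixel_counts.values())

    def count(self, *class_names: str) -> int:
        return sum(self.pixel_counts[n] for n in class_names)

    def area(self, *class_names: str) -> float:
        return sum(self.area_um2[n] for n in class_names)


def profile_areas(
    mask: TissueMask, restrict_to: np.ndarray | None = None
) -> ClassAreaProfile:
    """Count pixels of each class, optionally inside a binary region.

    ``restrict_to`` must match the mask's dimensions; pixels where it is
    falsy are excluded from every tally.
    """
    labels = mask.labels
    if restrict_to is not None:
        restrict_to = np.asarray(restrict_to)
        if restrict_to.shape != labels.shape:
            raise ShapeError(
                f"restrict_to shape {restrict_to.shape} != mask shape {labels.shape}"
            )
        labels = labels[restrict_to.astype(bool)]
    counts = np.bincount(labels.ravel(), minlength=mask.legend.n_classes)
    pixel_counts = {
        name: int(counts[mask.legend.id_of(name)]) for name in mask.legend.class_names
    }
    return ClassAreaProfile(
        pixel_counts=pixel_counts, mpp=mask.mpp, origin_slide=mask.origin_slide
    )
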