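"""Synthetic tissue masks and survival cohorts with known ground truth.

The generator emulates the geometry the analysis layer cares about — not
histology.  A mask consists of smooth tumor blobs (epithelial tumor +
tumor stroma textured by a smoothed random field), necrosis and mucin
components carved inside the tumor, TLS components placed intratumorally,
immediately peritumorally or distantly per a placement mix, and a benign
surround (lung parenchyma, non-tumor stroma, slide-background margin).
Planted class fractions are expressed relative to the final epithelial
tumor + tumor stroma area, i.e. on the same scale as the TLS-TD/NECR-TD
densities, so planted-parameter recovery is direct.

Survival cohorts draw times from a proportional-hazards model whose
log-hazard is linear in the planted densities (TLS protective, necrosis
adverse), with independent censoring and pT/pN stage covariates
positively associated with necrosis density.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SpecError
from .masks import ClassLegend, TissueMask, default_legend
from .subtyping import subtype_legend

# ---------------------------------------------------------------------
# mask generation
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMaskSpec:
    """Geometry and composition of one synthetic slide mask.

    Fractions are targets relative to the realized epithelial tumor +
    tumor stroma area (the density denominator).  ``tls_placement`` is
    the (intratumoral, peritumoral, distant) mix of planted TLS area;
    distant TLS is planted beyond the association distance and must not
    enter any density.
    """

    height: int = 1024
    width: int = 1024
    mpp: float = 1.0
    tumor_fraction: float = 0.35  # of the interior canvas
    tumor_blob_count: int = 4
    stroma_share: float = 0.40  # share of tumor region that is TU_STROMA
    texture_sigma: float = 12.0
    f_necrosis: float = 0.05
    f_tls: float = 0.03
    f_mucin: float = 0.0
    tls_placement: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tls_radius_px: tuple[int, int] = (5, 12)
    necrosis_radius_px: tuple[int, int] = (8, 24)
    mucin_radius_px: tuple[int, int] = (6, 14)
    peritumoral_band_um: float = 200.0  # placement band for peritumoral TLS
    distant_min_um: float = 300.0  # minimum clearance for distant TLS
    back_margin_px: int = 8
    benign_stroma_share: float = 0.15  # of benign surround

    def validate(self) -> None:
        for name in ("f_necrosis", "f_tls", "f_mucin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {v}")
        if self.f_necrosis + self.f_tls + self.f_mucin > 0.8:
            raise SpecError("within-tumor fractions sum above 0.8; infeasible")
        if any(p < 0 for p in self.tls_placement) or sum(self.tls_placement) <= 0:
            raise SpecError("tls_placement must be non-negative with positive sum")
        if not 0 < self.tumor_fraction < 0.9:
            raise SpecError("tumor_fraction must lie in (0, 0.9)")
        if self.height < 64 or self.width < 64:
            raise SpecError("canvas must be at least 64x64")


def _disk_coords(
    cr: int, cc: int, r: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a disk, ordered by distance from the center.

    The distance ordering makes area trimming keep a connected, roughly
    round shape (any radius prefix of a disk is itself a disk).
    """
    r0 = max(0, cr - r)
    r1 = min(shape[0], cr + r + 1)
    c0 = max(0, cc - r)
    c1 = min(shape[1], cc + r + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    inside = d2 <= r * r
    rows, cols, d2 = rows[inside], cols[inside], d2[inside]
    order = np.argsort(d2, kind="stable")
    return rows[order], cols[order]


def _carve_components(
    labels: np.ndarray,
    target_px: int,
    class_id: int,
    carvable: np.ndarray,
    radius_range: tuple[int, int],
    rng: np.random.Generator,
    center_pool: np.ndarray,
    min_center_sep: int = 0,
    existing_centers: list[tuple[int, int, int]] | None = None,
) -> list[dict]:
    """Paint disk components of ``class_id`` until ``target_px`` painted.

    ``carvable`` flags pixels that may be overwritten; ``center_pool``
    flags admissible disk centers.  The last disk is trimmed (pixels
    taken nearest-first) to hit the target exactly.  Returns per-object
    records (center, radius, painted area).
    """
    records: list[dict] = []
    centers = existing_centers if existing_centers is not None else []
    painted = 0
    attempts = 0
    while painted < target_px:
        attempts += 1
        if attempts > 20000:
            raise SpecError(
                f"cannot place {target_px} px of class {class_id}; "
                "fractions infeasible for this geometry"
            )
        pool = np.argwhere(center_pool)
        if len(pool) == 0:
            raise SpecError(
                f"no admissible centers left for class {class_id}"
            )
        cr, cc = pool[rng.integers(len(pool))]
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        if min_center_sep and any(
            (cr - pr) ** 2 + (cc - pc) ** 2 < (r + prr + min_center_sep) ** 2
            for pr, pc, prr in centers
        ):
            continue
        rows, cols = _disk_coords(int(cr), int(cc), r, labels.shape)
        ok = carvable[rows, cols]
        rows, cols = rows[ok], cols[ok]
        if len(rows) == 0:
            continue
        take = min(len(rows), target_px - painted)
        rows, cols = rows[:take], cols[:take]
        labels[rows, cols] = class_id
        carvable[rows, cols] = False
        center_pool[rows, cols] = False
        painted += take
        centers.append((int(cr), int(cc), r))
        records.append(
            {"center": (int(cr), int(cc)), "radius": r, "area_px": int(take)}
        )
    return records


def generate_mask(
    spec: SyntheticMaskSpec, seed: int
) -> tuple[TissueMask, dict]:
    """Generate one synthetic slide mask plus its ground-truth record.

    The ground truth records realized per-class areas, the density
    denominator, per-object placement categories, and the densities the
    analysis layer should recover.  Identical (spec, seed) pairs yield
    bit-identical masks.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    legend = default_legend(mpp=spec.mpp)
    ids = {n: legend.id_of(n) for n in legend.class_names}
    H, W, m = spec.height, spec.width, spec.back_margin_px

    labels = np.full((H, W), ids["LUNG_BENIGN"], dtype=np.int64)
    labels[:m, :] = ids["BACK"]
    labels[-m:, :] = ids["BACK"]
    labels[:, :m] = ids["BACK"]
    labels[:, -m:] = ids["BACK"]

    # -- tumor region: union of random disks around the canvas center ----
    interior_area = (H - 2 * m) * (W - 2 * m)
    target_tumor = spec.tumor_fraction * interior_area
    base_r = int(np.sqrt(target_tumor / (np.pi * spec.tumor_blob_count)) * 1.25)
    tumor_region = np.zeros((H, W), dtype=bool)
    cy, cx = H // 2, W // 2
    for i in range(spec.tumor_blob_count):
        if i == 0:
            cr, cc = cy, cx
        else:
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.4, 1.1) * base_r
            cr = int(np.clip(cy + dist * np.sin(ang), m + base_r, H - m - base_r))
            cc = int(np.clip(cx + dist * np.cos(ang), m + base_r, W - m - base_r))
        r = int(base_r * rng.uniform(0.8, 1.15))
        rows, cols = _disk_coords(cr, cc, r, (H, W))
        tumor_region[rows, cols] = True
    tumor_region[labels == ids["BACK"]] = False

    # texture the tumor region into epithelial tumor vs tumor stroma
    noise = ndimage.gaussian_filter(
        rng.standard_normal((H, W)), sigma=spec.texture_sigma
    )
    thr = np.quantile(noise[tumor_region], 1.0 - spec.stroma_share)
    labels[tumor_region] = ids["TUMOR"]
    labels[tumor_region & (noise > thr)] = ids["TU_STROMA"]

    area_t = int(tumor_region.sum())

    # -- pixel targets: fractions are relative to the FINAL denominator
    # (tumor + tumor stroma after carving), so solve for it first.
    p_in, p_peri, p_dist = spec.tls_placement
    p_qual = p_in + p_peri
    q_in = p_in / p_qual if p_qual > 0 else 0.0
    denom_final = area_t / (
        1.0 + spec.f_necrosis + spec.f_mucin + q_in * spec.f_tls
    )
    necr_target = int(round(spec.f_necrosis * denom_final))
    mucin_target = int(round(spec.f_mucin * denom_final))
    tls_qual_target = int(round(spec.f_tls * denom_final))
    tls_in_target = int(round(q_in * tls_qual_target))
    tls_peri_target = tls_qual_target - tls_in_target
    if p_qual > 0:
        tls_dist_target = int(round(tls_qual_target * p_dist / p_qual))
    else:
        tls_dist_target = int(round(spec.f_tls * area_t))

    inner_dist = ndimage.distance_transform_edt(tumor_region)
    outer_dist_um = ndimage.distance_transform_edt(~tumor_region) * spec.mpp

    carvable = tumor_region.copy()
    tls_centers: list[tuple[int, int, int]] = []

    # necrosis and mucin: carved strictly inside the tumor region so every
    # component is tumor-associated by construction
    necr_records = _carve_components(
        labels, necr_target, ids["NECROSIS"],
        carvable, spec.necrosis_radius_px, rng,
        center_pool=carvable & (inner_dist > spec.necrosis_radius_px[0]),
    )
    mucin_records = _carve_components(
        labels, mucin_target, ids["MUCIN"],
        carvable, spec.mucin_radius_px, rng,
        center_pool=carvable & (inner_dist > spec.mucin_radius_px[0]),
    ) if mucin_target else []

    # intratumoral TLS: centers deep enough that the disk stays interior
    rmax = spec.tls_radius_px[1]
    tls_in_records = _carve_components(
        labels, tls_in_target, ids["TLS"],
        carvable, spec.tls_radius_px, rng,
        center_pool=carvable & (inner_dist > rmax + 2),
        min_center_sep=3, existing_centers=tls_centers,
    )
    for rec in tls_in_records:
        rec["placement"] = "intratumoral"

    # peritumoral TLS: just outside the tumor, min object distance within
    # the placement band (and above touching distance)
    benign = (labels == ids["LUNG_BENIGN"])
    band_px = spec.peritumoral_band_um / spec.mpp
    peri_pool = benign & (outer_dist_um > (rmax + 3) * spec.mpp) & (
        outer_dist_um < (band_px - rmax) * spec.mpp
    )
    peri_paintable = benign.copy()
    tls_peri_records = _carve_components(
        labels, tls_peri_target, ids["TLS"],
        peri_paintable, spec.tls_radius_px, rng,
        center_pool=peri_pool,
        min_center_sep=3, existing_centers=tls_centers,
    ) if tls_peri_target else []
    for rec in tls_peri_records:
        rec["placement"] = "peritumoral"

    # distant TLS: beyond the association distance with margin
    benign = (labels == ids["LUNG_BENIGN"])
    dist_pool = benign & (
        outer_dist_um > spec.distant_min_um + (rmax + 5) * spec.mpp
    )
    dist_paintable = benign & (outer_dist_um > spec.distant_min_um)
    tls_dist_records = _carve_components(
        labels, tls_dist_target, ids["TLS"],
        dist_paintable, spec.tls_radius_px, rng,
        center_pool=dist_pool,
        min_center_sep=3, existing_centers=tls_centers,
    ) if tls_dist_target else []
    for rec in tls_dist_records:
        rec["placement"] = "distant"

    # benign surround texture: convert part of the remaining parenchyma
    # to non-tumor stroma (outside every density, pure scenery)
    benign = (labels == ids["LUNG_BENIGN"])
    if spec.benign_stroma_share > 0 and benign.any():
        thr2 = np.quantile(noise[benign], 1.0 - spec.benign_stroma_share)
        labels[benign & (noise > thr2)] = ids["STROMA"]

    mask = TissueMask(labels=labels, legend=legend)

    counts = np.bincount(labels.ravel(), minlength=legend.n_classes)
    areas = {n: int(counts[ids[n]]) for n in legend.class_names}
    denom = areas["TUMOR"] + areas["TU_STROMA"]
    tls_qual_px = sum(r["area_px"] for r in tls_in_records + tls_peri_records)
    necr_px = sum(r["area_px"] for r in necr_records)
    ground_truth = {
        "seed": int(seed),
        "spec": dataclasses.asdict(spec),
        "areas_px": areas,
        "denominator_px": int(denom),
        "necrosis_objects": necr_records,
        "mucin_objects": mucin_records,
        "tls_objects": tls_in_records + tls_peri_records + tls_dist_records,
        "tls_qualified_px": int(tls_qual_px),
        "tls_distant_px": int(sum(r["area_px"] for r in tls_dist_records)),
        "expected_tls_td": tls_qual_px / denom if denom else None,
        "expected_necr_td": necr_px / denom if denom else None,
        "expected_t_nr": (tls_qual_px / necr_px) if necr_px else None,
    }
    return mask, ground_truth


def generate_subtype_mask(
    main: TissueMask, pct_luad: float, seed: int, texture_sigma: float = 8.0
) -> TissueMask:
    """Paired subtype mask with a planted LUAD area percentage.

    Epithelial-tumor pixels of the main mask split into LUAD/LUSC along a
    smoothed random field so that ``pct_luad`` percent of them are LUAD;
    tumor stroma, necrosis and mucin carry over; everything else is
    background (the subtype layer is undefined there anyway).
    """
    if not 0.0 <= pct_luad <= 100.0:
        raise SpecError(f"pct_luad must lie in [0, 100], got {pct_luad}")
    rng = np.random.default_rng(seed)
    leg = subtype_legend(mpp=main.mpp)
    out = np.full(main.shape, leg.id_of("BACK"), dtype=np.int64)
    for name in ("TU_STROMA", "NECROSIS", "MUCIN"):
        if main.legend.has_class(name):
            out[main.class_support(name)] = leg.id_of(name)
    tumor = main.class_support("TUMOR")
    n_tumor = int(tumor.sum())
    if n_tumor:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(main.shape), sigma=texture_sigma
        )
        vals = noise[tumor]
        # exact planted split: the pct_luad% lowest field values become LUAD
        k = int(round(pct_luad / 100.0 * n_tumor))
        order = np.argsort(vals, kind="stable")
        sub = np.full(n_tumor, leg.id_of("TUMOR_LUSC"), dtype=np.int64)
        sub[order[:k]] = leg.id_of("TUMOR_LUAD")
        out[tumor] = sub
    return TissueMask(labels=out, legend=leg, origin_slide=main.origin_slide)


# ---------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort of cases with planted densities and linked survival.

    Hazard ratios are expressed per ``effect_scale`` units of density
    (0.05 by default, roughly the spread of the planted densities), with
    TLS protective and necrosis adverse.  Setting both ratios to 1 gives
    a null cohort.  A ``necrosis_free_fraction`` of cases carries exactly
    zero necrosis so the undefined-T/NR path is exercised.
    """

    n_cases: int = 200
    tls_td_range: tuple[float, float] = (0.0, 0.10)
    necr_td_range: tuple[float, float] = (0.0, 0.15)
    necrosis_free_fraction: float = 0.15
    hr_tls: float = 1.0 / 3.0
    hr_necr: float = 3.0
    effect_scale: float = 0.05
    baseline_hazard: float = 0.03  # events per month
    censoring_hazard: float = 0.012
    max_follow_up_months: float = 120.0
    stage_assoc: float = 1.5  # strength of pT/pN association with NECR-TD

    def validate(self) -> None:
        if self.n_cases < 2:
            raise SpecError("cohort needs at least 2 cases")
        if self.baseline_hazard <= 0 or self.effect_scale <= 0:
            raise SpecError("baseline_hazard and effect_scale must be positive")
        if self.hr_tls <= 0 or self.hr_necr <= 0:
            raise SpecError("hazard ratios must be positive")


_ENDPOINT_BASELINE = {"os": 1.0, "css": 0.8, "pfs": 1.4}


def _draw_endpoint(
    rng: np.random.Generator,
    hazard: np.ndarray,
    censoring_hazard: float,
    max_follow_up: float,
) -> tuple[np.ndarray, np.ndarray]:
    t_event = rng.exponential(1.0 / hazard)
    if censoring_hazard > 0:
        t_cens = np.minimum(
            rng.exponential(1.0 / censoring_hazard, size=hazard.size),
            max_follow_up,
        )
    else:
        t_cens = np.full(hazard.size, max_follow_up)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # strictly positive
    return time, event


def _ordinal_from_latent(
    latent: np.ndarray, labels: Sequence[str], quantiles: Sequence[float]
) -> np.ndarray:
    cuts = np.quantile(latent, quantiles)
    idx = np.searchsorted(cuts, latent, side="right")
    return np.array([labels[i] for i in idx])


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> pd.DataFrame:
    """Clinical table with planted densities, three endpoints and pT/pN.

    Columns: case_id, tls_td, necr_td, t_nr (NaN when necrosis-free),
    time_os/event_os, time_css/event_css, time_pfs/event_pfs, pT, pN.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_cases
    tls = rng.uniform(*spec.tls_td_range, size=n)
    necr = rng.uniform(*spec.necr_td_range, size=n)
    necr[rng.random(n) < spec.necrosis_free_fraction] = 0.0

    beta_tls = np.log(spec.hr_tls) / spec.effect_scale
    beta_necr = np.log(spec.hr_necr) / spec.effect_scale
    lin = beta_tls * (tls - tls.mean()) + beta_necr * (necr - necr.mean())

    df = pd.DataFrame(
        {
            "case_id": [f"case_{i:04d}" for i in range(n)],
            "tls_td": tls,
            "necr_td": necr,
            "t_nr": np.where(necr > 0, tls / np.where(necr > 0, necr, 1.0), np.nan),
        }
    )
    for ep, mult in _ENDPOINT_BASELINE.items():
        hazard = spec.baseline_hazard * mult * np.exp(lin)
        time, event = _draw_endpoint(
            rng, hazard, spec.censoring_hazard, spec.max_follow_up_months
        )
        df[f"time_{ep}"] = time
        df[f"event_{ep}"] = event

    scale = spec.effect_scale
    latent_t = spec.stage_assoc * necr / scale + rng.standard_normal(n)
    latent_n = 0.6 * spec.stage_assoc * necr / scale + rng.standard_normal(n)
    df["pT"] = _ordinal_from_latent(
        latent_t, ["pT1", "pT2", "pT3", "pT4"], [0.35, 0.70, 0.90]
    )
    df["pN"] = _ordinal_from_latent(latent_n, ["pN0", "pN1", "pN2"], [0.55, 0.85])
    return df


def generate_cutoff_cohort(
    n: int,
    cutoff: float,
    hazard_ratio: float,
    seed: int,
    baseline_hazard: float = 0.03,
    censoring_hazard: float = 0.012,
    max_follow_up_months: float = 120.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort with a planted step cutoff: hazard jumps by ``hazard_ratio``
    for cases whose (uniform) parameter value exceeds ``cutoff``.

    Returns ``(values, times, events)`` for cutoff-recovery studies;
    ``hazard_ratio = 1`` yields a null cohort for calibration checks.
    """
    if n < 4:
        raise SpecError("cutoff cohort needs at least 4 cases")
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 1.0, size=n)
    hazard = baseline_hazard * np.where(values > cutoff, hazard_ratio, 1.0)
    times, events = _draw_endpoint(
        rng, hazard, censoring_hazard, max_follow_up_months
    )
    return values, times, events


def generate_binary_cox_cohort(
    n: int,
    hazard_ratio: float,
    seed: int,
    baseline_hazard: float = 0.03,
    censoring_hazard: float = 0.012,
    max_follow_up_months: float = 120.0,
    extra_null_covariate: bool = False,
) -> pd.DataFrame:
    """Exponential cohort with one binary covariate of known hazard ratio.

    With ``extra_null_covariate`` a second, independent binary covariate
    with true hazard ratio 1 is added (for CI-coverage studies).
    Columns: time, event, x (and x_null).
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    hazard = baseline_hazard * hazard_ratio**x
    df = pd.DataFrame({"x": x.astype(float)})
    if extra_null_covariate:
        df["x_null"] = rng.integers(0, 2, size=n).astype(float)
    times, events = _draw_endpoint(
        rng, hazard, censoring_hazard, max_follow_up_months
    )
    df["time"] = times
    df["event"] = events
    return df
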