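"""End-to-end cohort pipeline: masks -> densities -> cutoffs -> survival.

Chains the per-slide quantification (area profiles, prognostic scores,
optional subtype calls) with cohort-level stratification (optimal
cutoffs, prognostic groups, Kaplan-Meier tables, log-rank, uni- and
multivariate Cox with pT/pN).  Processing is fail-soft: a broken slide
or case is flagged and the rest of the cohort completes.  Every
configured threshold is captured in the run log, and a re-run with
identical inputs produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import prognostics, subtyping, survival
from .errors import LungQuantError
from .io import read_clinical, read_manifest, read_mask
from .masks import ClassLegend, default_legend, load_legend, profile_areas

PARAMETERS = ("tls_td", "necr_td", "t_nr")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of a run, in one auditable place."""

    legend_path: str | None = None
    peritumoral_dist_um: float = prognostics.DEFAULT_PERITUMORAL_UM
    connectivity: int = 8
    cutoff_percentile_range: tuple[float, float, float] = (10.0, 90.0, 2.5)
    min_group_fraction: float = prognostics.MIN_GROUP_FRACTION
    borderline_pct: tuple[float, float] = (
        subtyping.BORDERLINE_LOW,
        subtyping.BORDERLINE_HIGH,
    )
    endpoints: tuple[str, ...] = ("os", "css", "pfs")
    primary_endpoint: str = "os"  # cutoff found here, reused for all endpoints
    make_plots: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def percentile_grid(self) -> np.ndarray:
        lo, hi, step = self.cutoff_percentile_range
        return np.arange(lo, hi + 1e-9, step)


@dataclass
class PipelineReport:
    out_dir: Path
    slide_scores: pd.DataFrame
    case_scores: pd.DataFrame
    cutoffs: dict
    models: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_legend(config: PipelineConfig) -> ClassLegend:
    if config.legend_path:
        return load_legend(config.legend_path)
    return default_legend()


def _endpoint_cols(clinical: pd.DataFrame, ep: str) -> tuple[str, str] | None:
    t, e = f"time_{ep}", f"event_{ep}"
    return (t, e) if t in clinical.columns and e in clinical.columns else None


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    clinical: pd.DataFrame | str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineReport:
    """Run the full quantification + stratification pipeline.

    ``manifest`` lists slides (case_id, slide_id, mask_path, optional
    subtype_mask_path); ``clinical`` supplies per-case survival endpoints
    and pT/pN (may be None for quantification-only runs).  Outputs land
    in ``out_dir``: per-slide profiles and scores, per-case scores,
    subtype calls, cutoffs, KM tables, model summaries and a run log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if clinical is not None and not isinstance(clinical, pd.DataFrame):
        clinical = read_clinical(clinical)
    legend = _load_legend(config)
    failures: list[dict] = []

    # -- per-slide quantification ---------------------------------------
    profile_rows: list[dict] = []
    slide_rows: list[dict] = []
    subtype_calls: dict[str, list[subtyping.SubtypeCall]] = {}
    for rec in manifest.to_dict("records"):
        case_id, slide_id = rec["case_id"], rec["slide_id"]
        try:
            mask = read_mask(rec["mask_path"], legend, origin_slide=slide_id)
            prof = profile_areas(mask)
            for name, px in prof.pixel_counts.items():
                profile_rows.append(
                    {
                        "case_id": case_id,
                        "slide_id": slide_id,
                        "class_name": name,
                        "pixels": px,
                        "area_um2": prof.area_um2[name],
                    }
                )
            scores = prognostics.compute_scores(
                mask,
                peritumoral_dist_um=config.peritumoral_dist_um,
                connectivity=config.connectivity,
            )
            row = {"case_id": case_id, "slide_id": slide_id}
            if scores is None:
                row.update(
                    status="no_tumor", tls_td=np.nan, necr_td=np.nan,
                    t_nr=np.nan, tls_area_px=0, necr_area_px=0,
                    denominator_px=0,
                )
            else:
                row.update(
                    status="ok",
                    tls_td=scores.tls_td,
                    necr_td=scores.necr_td,
                    t_nr=scores.t_nr if scores.t_nr is not None else np.nan,
                    tls_area_px=scores.tls_area_px,
                    necr_area_px=scores.necr_area_px,
                    denominator_px=scores.denominator_px,
                )
            slide_rows.append(row)
            sub_path = rec.get("subtype_mask_path")
            if sub_path and not (isinstance(sub_path, float) and math.isnan(sub_path)):
                sub_mask = read_mask(
                    sub_path, subtyping.subtype_legend(mpp=legend.mpp),
                    origin_slide=slide_id,
                )
                call = subtyping.classify_slide(mask, sub_mask)
                subtype_calls.setdefault(case_id, []).append(call)
        except (LungQuantError, OSError, FileNotFoundError) as exc:
            failures.append(
                {"stage": "slide", "case_id": case_id, "slide_id": slide_id,
                 "error": f"{type(exc).__name__}: {exc}"}
            )

    slide_df = pd.DataFrame(slide_rows)
    profile_df = pd.DataFrame(profile_rows)

    # -- per-case pooling (area-weighted across slides) ------------------
    case_rows: list[dict] = []
    if not slide_df.empty:
        for case_id, grp in slide_df.groupby("case_id", sort=True):
            denom = int(grp["denominator_px"].sum())
            tls = int(grp["tls_area_px"].sum())
            necr = int(grp["necr_area_px"].sum())
            case_rows.append(
                {
                    "case_id": case_id,
                    "n_slides": len(grp),
                    "status": "ok" if denom > 0 else "no_tumor",
                    "tls_td": tls / denom if denom else np.nan,
                    "necr_td": necr / denom if denom else np.nan,
                    "t_nr": tls / necr if necr else np.nan,
                    "tls_area_px": tls,
                    "necr_area_px": necr,
                    "denominator_px": denom,
                }
            )
    case_df = pd.DataFrame(case_rows)

    subtype_slide_rows = []
    subtype_case_rows = []
    for case_id, calls in sorted(subtype_calls.items()):
        for c in calls:
            subtype_slide_rows.append({"case_id": case_id, **_call_row(c)})
        agg = subtyping.aggregate_case(calls, origin=case_id)
        subtype_case_rows.append({"case_id": case_id, **_call_row(agg)})

    # -- cohort stratification + survival --------------------------------
    cutoffs: dict = {}
    model_rows: list[dict] = []
    if clinical is not None and not case_df.empty:
        # computed densities win over any like-named clinical columns
        clin = clinical.drop(
            columns=[c for c in clinical.columns
                     if c != "case_id" and c in case_df.columns]
        )
        merged = case_df.merge(clin, on="case_id", how="inner")
        primary = _endpoint_cols(clinical, config.primary_endpoint)
        if primary is None:
            avail = [ep for ep in config.endpoints if _endpoint_cols(clinical, ep)]
            primary = _endpoint_cols(clinical, avail[0]) if avail else None
        if primary is not None:
            for param in PARAMETERS:
                sub = merged.dropna(subset=[param, primary[0], primary[1]])
                try:
                    cut = prognostics.find_optimal_cutoff(
                        sub[param].to_numpy(),
                        sub[primary[0]].to_numpy(),
                        sub[primary[1]].to_numpy(),
                        parameter=param,
                        percentiles=config.percentile_grid(),
                        min_group_fraction=config.min_group_fraction,
                    )
                except LungQuantError as exc:
                    failures.append(
                        {"stage": "cutoff", "parameter": param,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
                    continue
                cutoffs[param] = {
                    "cutoff": cut.cutoff,
                    "p_value": cut.p_value,
                    "n_low": cut.n_low,
                    "n_high": cut.n_high,
                    "min_group_size": cut.min_group_size,
                    "grid": [float(g) for g in cut.grid],
                    "statistics": [
                        None if np.isnan(s) else float(s) for s in cut.statistics
                    ],
                }
                merged[f"{param}_group"] = np.where(
                    merged[param].isna(), "undefined",
                    prognostics.dichotomize(
                        merged[param].fillna(cut.cutoff).to_numpy(), cut.cutoff
                    ),
                )
            if {"tls_td_group", "necr_td_group"} <= set(merged.columns):
                merged["pg"] = [
                    prognostics.assign_prognostic_group(t, n)
                    if t in ("low", "high") and n in ("low", "high") else "undefined"
                    for t, n in zip(merged["tls_td_group"], merged["necr_td_group"])
                ]
            model_rows = _fit_models(merged, config, failures, out_dir)
            keep = ["case_id"] + [
                c for c in ("tls_td_group", "necr_td_group", "t_nr_group", "pg")
                if c in merged.columns
            ]
            case_df = case_df.merge(merged[keep], on="case_id", how="left")

    # -- emit -------------------------------------------------------------
    profile_df.to_csv(out_dir / "profiles.csv", index=False)
    slide_df.to_csv(out_dir / "slide_scores.csv", index=False)
    case_df.to_csv(out_dir / "case_scores.csv", index=False)
    if subtype_slide_rows:
        pd.DataFrame(subtype_slide_rows).to_csv(
            out_dir / "subtype_slides.csv", index=False
        )
        pd.DataFrame(subtype_case_rows).to_csv(
            out_dir / "subtype_cases.csv", index=False
        )
    (out_dir / "cutoffs.json").write_text(json.dumps(cutoffs, indent=2))
    models_df = pd.DataFrame(model_rows)
    models_df.to_csv(out_dir / "survival_models.csv", index=False)
    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_slides": len(manifest),
        "n_cases": len(case_df),
        "failures": failures,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return PipelineReport(
        out_dir=out_dir,
        slide_scores=slide_df,
        case_scores=case_df,
        cutoffs=cutoffs,
        models=models_df,
        failures=failures,
    )


def _call_row(c: subtyping.SubtypeCall) -> dict:
    return {
        "slide_id": c.origin,
        "level": c.level,
        "call": c.call,
        "pct_luad": c.pct_luad,
        "pct_lusc": c.pct_lusc,
        "borderline": c.borderline,
        "mucin_pct": c.mucin_pct,
        "luad_px": c.luad_px,
        "lusc_px": c.lusc_px,
    }


def _fit_models(
    merged: pd.DataFrame,
    config: PipelineConfig,
    failures: list[dict],
    out_dir: Path,
) -> list[dict]:
    """KM tables, log-rank and Cox per parameter and endpoint."""
    rows: list[dict] = []
    km_dir = out_dir / "km_tables"
    km_dir.mkdir(exist_ok=True)
    group_cols = [
        c for c in ("tls_td_group", "necr_td_group", "t_nr_group", "pg")
        if c in merged.columns
    ]
    for ep in config.endpoints:
        cols = _endpoint_cols(merged, ep)
        if cols is None:
            continue
        tcol, ecol = cols
        for gcol in group_cols:
            sub = merged[merged[gcol].isin(("low", "high", "PG1", "PG2", "PG3"))]
            sub = sub.dropna(subset=[tcol, ecol])
            groups = sorted(sub[gcol].unique())
            # KM table per group
            frames = []
            for g in groups:
                gg = sub[sub[gcol] == g]
                if gg.empty:
                    continue
                try:
                    km = survival.km_estimate(gg[tcol], gg[ecol])
                except (ValueError, LungQuantError):
                    continue
                f = km.to_frame()
                f.insert(0, "group", g)
                frames.append(f)
            if frames:
                pd.concat(frames).to_csv(
                    km_dir / f"km_{gcol}_{ep}.csv", index=False
                )
            # two-group log-rank where applicable
            if set(groups) == {"low", "high"}:
                lo = sub[sub[gcol] == "low"]
                hi = sub[sub[gcol] == "high"]
                try:
                    chi2, p = survival.logrank_statistic(
                        lo[tcol], lo[ecol], hi[tcol], hi[ecol]
                    )
                    rows.append(
                        {"endpoint": ep, "parameter": gcol, "model": "logrank",
                         "term": "high_vs_low", "statistic": chi2, "p": p,
                         "hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan}
                    )
                except LungQuantError as exc:
                    failures.append(
                        {"stage": "logrank", "parameter": gcol, "endpoint": ep,
                         "error": str(exc)}
                    )
                # Cox: univariate and multivariate with pT/pN
                fit_df = sub.copy()
                fit_df["param_high"] = (fit_df[gcol] == "high").astype(float)
                for model_name, covs in (
                    ("cox_uni", ["param_high"]),
                    ("cox_multi", ["param_high", "pT", "pN"]),
                ):
                    if any(c not in fit_df.columns for c in covs):
                        continue
                    enc = survival.encode_stage_covariates(
                        fit_df[[tcol, ecol] + covs]
                    )
                    covariates = [c for c in enc.columns if c not in (tcol, ecol)]
                    try:
                        res = survival.cox_fit(
                            enc, tcol, ecol, covariates, endpoint=ep.upper()
                        )
                        for term, eff in res.effects.items():
                            rows.append(
                                {"endpoint": ep, "parameter": gcol,
                                 "model": model_name, "term": term,
                                 "statistic": np.nan, "p": eff.p_value,
                                 "hr": eff.hazard_ratio,
                                 "ci_lower": eff.ci_lower,
                                 "ci_upper": eff.ci_upper}
                            )
                    except LungQuantError as exc:
                        failures.append(
                            {"stage": model_name, "parameter": gcol,
                             "endpoint": ep, "error": str(exc)}
                        )
            if config.make_plots and frames:
                _plot_km(pd.concat(frames), km_dir / f"km_{gcol}_{ep}.png",
                         title=f"{gcol} / {ep.upper()}")
    return rows


def _plot_km(km_table: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, grp in km_table.groupby("group"):
        t = np.concatenate([[0.0], grp["time"].to_numpy()])
        s = np.concatenate([[1.0], grp["survival"].to_numpy()])
        ax.step(t, s, where="post", label=str(g))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
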