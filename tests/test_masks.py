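"""Legend validation, area profiling and the 14->11 class merge."""

import numpy as np
import pytest

from lungquant import (
    annotation_legend,
    connective_tissue_classes,
    default_legend,
    load_legend,
    mask_from_rgb,
    merge_classes,
    profile_areas,
    save_legend,
)
from lungquant.errors import ConfigError, LegendError, ShapeError
from lungquant.masks import ClassLegend, TissueMask, default_legend_path


class TestLegend:
    def test_default_legend_is_11_tissue_classes_plus_background(self):
        leg = default_legend()
        assert leg.n_classes == 12
        assert len(leg.tissue_class_names()) == 11
        assert leg.name_of(leg.background_id) == "BACK"
        for name in ("TUMOR", "TU_STROMA", "NECROSIS", "MUCIN", "TLS",
                     "LUNG_BENIGN", "STROMA", "BRONCH", "BLOOD",
                     "GLAND_PERIBR", "CARTIL"):
            assert leg.has_class(name)

    def test_shipped_config_loads_default_legend(self):
        leg = load_legend(default_legend_path())
        assert leg.class_names == default_legend().class_names
        assert leg.name_of(leg.background_id) == "BACK"

    def test_roundtrip_yaml_and_json(self, tmp_path):
        for name in ("legend.yaml", "legend.json"):
            p = tmp_path / name
            save_legend(default_legend(mpp=0.5), p)
            leg = load_legend(p)
            assert leg.class_names == default_legend().class_names
            assert leg.mpp == 0.5

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda c: c["classes"][3].update(id=2), "duplicate class ids"),
            (lambda c: c["classes"][1].update(id=99), "contiguous"),
            (lambda c: c["classes"][1].update(name="BACK"), "duplicate class names"),
            (lambda c: c["classes"][1].update(group="background"),
             "exactly one background"),
            (lambda c: c["classes"][1].update(group="mystery"), "unknown group"),
            (lambda c: c.update(mpp=-1.0), "mpp must be positive"),
        ],
    )
    def test_malformed_configs_rejected(self, mutate, match):
        cfg = default_legend().to_dict()
        mutate(cfg)
        with pytest.raises(ConfigError, match=match):
            ClassLegend.from_dict(cfg)

    def test_missing_file_and_unparseable_file(self, tmp_path):
        with pytest.raises(ConfigError, match="not found"):
            load_legend(tmp_path / "nope.yaml")
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(ConfigError, match="cannot parse"):
            load_legend(bad)


class TestMergeAnnotationScheme:
    def test_merging_four_connective_classes_yields_11_class_scheme(self):
        pre = annotation_legend()
        assert len(pre.tissue_class_names()) == 14
        merged, id_map = merge_classes(
            pre, connective_tissue_classes(), "STROMA"
        )
        assert len(merged.tissue_class_names()) == 11
        assert set(merged.class_names) == set(default_legend().class_names)

    def test_id_map_converts_rasters(self):
        pre = annotation_legend()
        merged, id_map = merge_classes(pre, connective_tissue_classes(), "STROMA")
        labels = np.array([[pre.id_of(n) for n in
                            ("FAT", "MUSCLE", "VESSEL", "CONN_STROMA", "TUMOR")]])
        out = id_map[labels]
        stroma = merged.id_of("STROMA")
        assert list(out[0]) == [stroma] * 4 + [merged.id_of("TUMOR")]

    def test_merge_rejects_unknown_or_single_class(self):
        with pytest.raises(LegendError):
            merge_classes(default_legend(), ["TUMOR", "NOPE"], "X")
        with pytest.raises(LegendError):
            merge_classes(default_legend(), ["TUMOR"], "X")


class TestMaskValidation:
    def test_out_of_legend_values_rejected(self, legend):
        with pytest.raises(LegendError):
            TissueMask(labels=np.full((4, 4), 99), legend=legend)

    def test_non_2d_rejected(self, legend):
        with pytest.raises(ShapeError):
            TissueMask(labels=np.zeros((2, 2, 2), dtype=int), legend=legend)

    def test_rgb_ingest_via_color_table(self, make_mask, legend):
        mask = make_mask(np.array([[1, 2], [0, 5]]))
        rgb = np.zeros((2, 2, 3), dtype=np.uint8)
        for e in legend.entries:
            rgb[mask.labels == e.class_id] = e.color
        back = mask_from_rgb(rgb, legend)
        assert np.array_equal(back.labels, mask.labels)
        rgb[0, 0] = (1, 2, 3)  # color absent from the legend
        with pytest.raises(LegendError, match="absent"):
            mask_from_rgb(rgb, legend)


class TestProfileAreas:
    def test_small_mask_counts(self, make_mask, legend):
        labels = np.zeros((4, 4), dtype=int)
        labels[:2, :] = legend.id_of("TUMOR")          # 8 px
        labels[2, :] = legend.id_of("STROMA")          # 4 px
        labels[3, :] = legend.id_of("BACK")            # 4 px
        prof = profile_areas(make_mask(labels))
        assert prof.pixel_counts["TUMOR"] == 8
        assert prof.pixel_counts["STROMA"] == 4
        assert prof.pixel_counts["BACK"] == 4
        assert sum(v for k, v in prof.pixel_counts.items()
                   if k not in ("TUMOR", "STROMA", "BACK")) == 0

    def test_empty_region_gives_zero_counts(self, random_mask):
        mask = random_mask(0)
        prof = profile_areas(mask, restrict_to=np.zeros(mask.shape, dtype=bool))
        assert prof.total_pixels == 0

    def test_region_shape_mismatch(self, random_mask):
        with pytest.raises(ShapeError):
            profile_areas(random_mask(0), restrict_to=np.ones((3, 3), dtype=bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_tally_oracle(self, random_mask, seed):
        mask = random_mask(seed)
        prof = profile_areas(mask)
        oracle = {name: 0 for name in mask.legend.class_names}
        for r in range(mask.shape[0]):
            for c in range(mask.shape[1]):
                oracle[mask.legend.name_of(int(mask.labels[r, c]))] += 1
        assert prof.pixel_counts == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_restriction_additivity(self, random_mask, seed):
        mask = random_mask(seed, shape=(40, 56))
        full = profile_areas(mask)
        assert full.total_pixels == 40 * 56
        rng = np.random.default_rng(seed + 100)
        region_a = rng.random(mask.shape) < 0.4
        region_b = ~region_a
        pa = profile_areas(mask, restrict_to=region_a)
        pb = profile_areas(mask, restrict_to=region_b)
        for name in mask.legend.class_names:
            assert pa.pixel_counts[name] + pb.pixel_counts[name] == \
                full.pixel_counts[name]

    def test_mpp_scaling_quadruples_area(self, random_mask):
        m1 = random_mask(1, mpp=1.0)
        m2 = TissueMask(labels=m1.labels, legend=default_legend(mpp=2.0))
        p1, p2 = profile_areas(m1), profile_areas(m2)
        assert p1.pixel_counts == p2.pixel_counts
        for name in m1.legend.class_names:
            assert p2.area_um2[name] == pytest.approx(4.0 * p1.area_um2[name])
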