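"""Object extraction/qualification, densities and optimal-cutoff search."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from lungquant import (
    assign_prognostic_group,
    compute_necr_td,
    compute_scores,
    compute_t_nr,
    compute_tls_td,
    default_legend,
    extract_objects,
    find_optimal_cutoff,
    qualify_objects,
)
from lungquant.errors import LegendError, StratificationError
from lungquant.masks import TissueMask, profile_areas
from lungquant.prognostics import tumor_region_support


def flood_fill_components(binary, connectivity=8):
    """Independent BFS connected-components oracle."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary)
    comps = []
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < binary.shape[0]
                                and 0 <= nx < binary.shape[1]
                                and binary[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def brute_force_qualification(obj_pixels, reference_pixels, mpp,
                              peritumoral_dist_um):
    """Exhaustive min pairwise pixel distance qualification oracle."""
    if len(reference_pixels) == 0:
        return "non_tumor_associated", np.inf
    d = cdist(obj_pixels, reference_pixels).min() * mpp
    if d <= np.sqrt(2) * mpp * (1 + 1e-9):
        return "intratumoral", d
    if d <= peritumoral_dist_um:
        return "peritumoral", d
    return "non_tumor_associated", d


class TestExtractObjects:
    def test_two_disjoint_blobs(self, make_mask, legend):
        labels = np.zeros((12, 12), dtype=int)
        tls = legend.id_of("TLS")
        labels[1:2, 1:6] = tls          # 5 px
        labels[8:9, 2:9] = tls          # 7 px
        objs = extract_objects(make_mask(labels), "TLS")
        assert sorted(o.area_px for o in objs) == [5, 7]

    def test_single_pixel_object_is_kept(self, make_mask, legend):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = legend.id_of("NECROSIS")
        objs = extract_objects(make_mask(labels), "NECROSIS")
        assert len(objs) == 1 and objs[0].area_px == 1

    def test_connectivity_choice_matters_on_diagonals(self, make_mask, legend):
        labels = np.zeros((4, 4), dtype=int)
        tls = legend.id_of("TLS")
        labels[0, 0] = labels[1, 1] = tls
        mask = make_mask(labels)
        assert len(extract_objects(mask, "TLS", connectivity=8)) == 1
        assert len(extract_objects(mask, "TLS", connectivity=4)) == 2

    def test_unknown_class_rejected(self, random_mask):
        with pytest.raises(LegendError):
            extract_objects(random_mask(0), "NOPE")

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, make_mask, legend, seed,
                                       connectivity):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random((24, 24)) < 0.3, legend.id_of("TLS"), 0)
        objs = extract_objects(make_mask(labels), "TLS",
                               connectivity=connectivity)
        oracle = flood_fill_components(labels > 0, connectivity)
        got = sorted(
            tuple(sorted(map(tuple, o.pixels))) for o in objs
        )
        expected = sorted(tuple(sorted(c)) for c in oracle)
        assert got == expected


class TestQualifyObjects:
    def test_blob_inside_tumor_stroma_is_intratumoral(self, make_mask, legend):
        labels = np.full((20, 20), legend.id_of("TU_STROMA"), dtype=int)
        labels[8:12, 8:12] = legend.id_of("TLS")
        mask = make_mask(labels)
        objs = qualify_objects(extract_objects(mask, "TLS"), mask)
        assert objs[0].qualification == "intratumoral"

    def test_blob_10um_outside_with_250um_threshold_is_peritumoral(
            self, make_mask, legend):
        labels = np.zeros((30, 60), dtype=int)
        labels[:, :20] = legend.id_of("TUMOR")
        labels[14:16, 30:33] = legend.id_of("TLS")  # 10 px from tumor edge
        mask = make_mask(labels)  # mpp 1.0 -> 10 um gap
        objs = qualify_objects(extract_objects(mask, "TLS"), mask,
                               peritumoral_dist_um=250.0)
        assert objs[0].qualification == "peritumoral"
        assert objs[0].min_distance_um == pytest.approx(11.0)

    def test_far_blob_is_excluded(self, make_mask, legend):
        labels = np.zeros((30, 400), dtype=int)
        labels[:, :20] = legend.id_of("TUMOR")
        labels[14:16, 380:383] = legend.id_of("TLS")
        mask = make_mask(labels)
        objs = qualify_objects(extract_objects(mask, "TLS"), mask,
                               peritumoral_dist_um=250.0)
        assert objs[0].qualification == "non_tumor_associated"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_distance_oracle(self, make_mask, legend, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros((40, 40), dtype=int)
        labels[rng.random((40, 40)) < 0.15] = legend.id_of("TUMOR")
        labels[rng.random((40, 40)) < 0.08] = legend.id_of("TLS")
        mask = make_mask(labels)
        thresh = 12.0
        objs = qualify_objects(extract_objects(mask, "TLS"), mask,
                               peritumoral_dist_um=thresh)
        reference = np.argwhere(tumor_region_support(mask, exclude_class="TLS"))
        for obj in objs:
            expected, _ = brute_force_qualification(
                obj.pixels, reference, mask.mpp, thresh
            )
            assert obj.qualification == expected

    def test_empty_object_list_passes_through(self, random_mask):
        assert qualify_objects([], random_mask(0)) == []


class TestDensities:
    def base_mask(self, legend, tls=0, necr=0, tumor=60, stroma=30):
        """One row of TUMOR/TU_STROMA with TLS/NECROSIS carved adjacent."""
        n = tumor + stroma + tls + necr
        labels = np.zeros((3, n), dtype=int)
        pos = 0
        for name, count in (("TUMOR", tumor), ("TU_STROMA", stroma),
                            ("TLS", tls), ("NECROSIS", necr)):
            labels[1, pos:pos + count] = legend.id_of(name)
            pos += count
        return labels

    def test_tls_td_arithmetic(self, make_mask, legend):
        mask = make_mask(self.base_mask(legend, tls=9))
        assert compute_tls_td(mask) == pytest.approx(9 / 90)

    def test_no_tls_gives_zero(self, make_mask, legend):
        mask = make_mask(self.base_mask(legend))
        assert compute_tls_td(mask) == 0.0

    def test_necr_td_arithmetic(self, make_mask, legend):
        mask = make_mask(self.base_mask(legend, necr=10))
        assert compute_necr_td(mask) == pytest.approx(10 / 90)

    def test_isolated_necrosis_in_benign_lung_is_excluded(self, make_mask,
                                                          legend):
        labels = np.zeros((30, 500), dtype=int)
        labels[:, :90] = legend.id_of("TUMOR")
        labels[14:16, 480:485] = legend.id_of("NECROSIS")  # ~390 um away
        mask = make_mask(labels)
        assert compute_necr_td(mask, peritumoral_dist_um=250.0) == 0.0

    def test_t_nr_ratio_and_undefined_sentinel(self, make_mask, legend):
        mask = make_mask(self.base_mask(legend, tls=20, necr=10))
        assert compute_t_nr(mask) == pytest.approx(2.0)
        mask = make_mask(self.base_mask(legend, tls=0, necr=10))
        assert compute_t_nr(mask) == 0.0
        mask = make_mask(self.base_mask(legend, tls=20, necr=0))
        assert compute_t_nr(mask) is None

    def test_no_tumor_outcome(self, make_mask, legend):
        labels = np.full((5, 5), legend.id_of("LUNG_BENIGN"), dtype=int)
        mask = make_mask(labels)
        assert compute_tls_td(mask) is None
        assert compute_necr_td(mask) is None
        assert compute_scores(mask) is None

    def test_monotonicity_in_tls_and_tumor_area(self, make_mask, legend):
        base = self.base_mask(legend, tls=9)
        m0 = make_mask(base)
        added = base.copy()
        added[0, 0:4] = legend.id_of("TLS")  # adjacent to tumor row below
        m1 = make_mask(added)
        assert compute_tls_td(m1) > compute_tls_td(m0)
        grown = np.vstack([base, np.full((1, base.shape[1]),
                                         legend.id_of("TUMOR"))])
        m2 = make_mask(grown)
        assert compute_tls_td(m2) < compute_tls_td(m0)

    def test_editing_benign_lung_never_changes_densities(self, make_mask,
                                                         legend):
        labels = self.base_mask(legend, tls=9, necr=5)
        m0 = make_mask(labels)
        edited = labels.copy()
        benign = edited == legend.id_of("BACK")
        edited[benign] = legend.id_of("LUNG_BENIGN")
        edited[0, -3:] = legend.id_of("STROMA")
        m1 = make_mask(edited)
        assert compute_tls_td(m1) == compute_tls_td(m0)
        assert compute_necr_td(m1) == compute_necr_td(m0)

    def test_qualified_area_equals_profile_count_when_all_qualify(
            self, make_mask, legend):
        """No-filtering fidelity: every component down to 1 px is counted."""
        labels = np.full((20, 20), legend.id_of("TU_STROMA"), dtype=int)
        rng = np.random.default_rng(0)
        spots = rng.random((20, 20)) < 0.1
        labels[spots] = legend.id_of("TLS")
        mask = make_mask(labels)
        prof = profile_areas(mask)
        scores = compute_scores(mask)
        assert scores.tls_area_px == prof.pixel_counts["TLS"]


class TestOptimalCutoff:
    def test_separated_clusters_with_different_hazards(self):
        rng = np.random.default_rng(1)
        n = 60
        values = np.concatenate([rng.uniform(0.0, 0.2, n),
                                 rng.uniform(0.8, 1.0, n)])
        hazard = np.where(values > 0.5, 0.15, 0.03)
        times = rng.exponential(1.0 / hazard)
        events = np.ones(2 * n, dtype=int)
        res = find_optimal_cutoff(values, times, events)
        assert 0.2 <= res.cutoff <= 0.8
        # grid search attains (nearly) the brute-force optimum over all
        # admissible midpoints
        from lungquant.survival import logrank_statistic

        def chi2_at(c):
            low = values <= c
            return logrank_statistic(times[low], events[low],
                                     times[~low], events[~low])[0]

        order = np.sort(values)
        mids = (order[:-1] + order[1:]) / 2
        best_chi2 = max(
            chi2_at(m) for m in mids if 6 <= (values <= m).sum() <= 2 * n - 6
        )
        assert chi2_at(res.cutoff) >= 0.9 * best_chi2

    def test_identical_values_raise(self):
        with pytest.raises(StratificationError):
            find_optimal_cutoff(
                np.ones(30), np.arange(1, 31, dtype=float),
                np.ones(30, dtype=int),
            )

    def test_no_events_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(StratificationError):
            find_optimal_cutoff(
                rng.random(30), rng.uniform(1, 10, 30), np.zeros(30, dtype=int)
            )

    def test_trace_covers_grid_and_respects_min_group_size(self):
        rng = np.random.default_rng(2)
        values = rng.random(50)
        times = rng.exponential(20, 50)
        events = rng.integers(0, 2, 50)
        res = find_optimal_cutoff(values, times, events)
        assert len(res.statistics) == len(res.grid)
        assert res.cutoff in res.grid
        assert res.n_low >= res.min_group_size
        assert res.n_high >= res.min_group_size


class TestPrognosticGroups:
    @pytest.mark.parametrize("tls,necr,expected", [
        ("high", "low", "PG1"),
        ("low", "high", "PG3"),
        ("high", "high", "PG2"),
        ("low", "low", "PG2"),
    ])
    def test_mapping(self, tls, necr, expected):
        assert assign_prognostic_group(tls, necr) == expected

    def test_four_combinations_give_exactly_three_groups(self):
        groups = {
            assign_prognostic_group(t, n)
            for t in ("low", "high") for n in ("low", "high")
        }
        assert groups == {"PG1", "PG2", "PG3"}

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            assign_prognostic_group("high", None)
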