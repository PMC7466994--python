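"""Calibration-set selection, CDmean exchange, scoring, marker curves."""

import itertools

import numpy as np
import pytest

from poolgp import (
    build_gwas_set,
    evaluate_calibration,
    kinship,
    marker_curve,
    performance,
    select_by_clustering,
    select_cdmean,
    select_clustgeo,
)
from poolgp.calibopt import CalibrationSet, _cdmean
from poolgp.spatialstats import DistanceMatrix, euclidean_distances

from conftest import toy_matrix


def _dm(D, ids=None, units="euclidean-genetic"):
    n = D.shape[0]
    return DistanceMatrix(ids=ids or [f"p{i:02d}" for i in range(n)], D=D, units=units)


def two_cluster_distance(n_a=6, n_b=6, gap=100.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (n_a, 2)), rng.normal(gap, 1, (n_b, 2))])
    D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return _dm(D)


class TestClusteringSelection:
    def test_k_equals_n_selects_all(self):
        D = two_cluster_distance()
        sel = select_by_clustering(D, k=D.n)
        assert sorted(sel.pop_ids) == sorted(D.ids)

    def test_k_one_selects_global_medoid(self):
        D = two_cluster_distance()
        sel = select_by_clustering(D, k=1)
        mean_d = D.D.sum(axis=1) / (D.n - 1)
        assert sel.pop_ids == [D.ids[int(np.argmin(mean_d))]]

    def test_two_separated_clusters_one_rep_each(self):
        D = two_cluster_distance()
        sel = select_by_clustering(D, k=2)
        assert len(sel.pop_ids) == 2
        groups = [int(p[1:]) < 6 for p in sel.pop_ids]
        assert sorted(groups) == [False, True]

    def test_invalid_k(self):
        D = two_cluster_distance()
        with pytest.raises(ValueError):
            select_by_clustering(D, k=D.n + 1)


class TestClustGeo:
    def test_alpha_zero_matches_genetic(self, small_panel, small_imputed):
        from poolgp.spatialstats import geo_distances

        D_gen = euclidean_distances(small_imputed.values, small_imputed.pop_ids)
        D_geo = geo_distances(small_panel)
        a0 = select_clustgeo(D_gen, D_geo, k=10, alpha=0.0)
        ref = select_by_clustering(D_gen, k=10)
        assert a0.pop_ids == ref.pop_ids

    def test_alpha_one_matches_spatial(self, small_panel, small_imputed):
        from poolgp.spatialstats import geo_distances

        D_gen = euclidean_distances(small_imputed.values, small_imputed.pop_ids)
        D_geo = geo_distances(small_panel)
        a1 = select_clustgeo(D_gen, D_geo, k=10, alpha=1.0)
        ref = select_by_clustering(D_geo, k=10)
        assert a1.pop_ids == ref.pop_ids

    def test_coincident_structures_agree_at_any_alpha(self):
        D = two_cluster_distance()
        sel_half = select_clustgeo(D, D, k=2, alpha=0.5)
        sel_gen = select_by_clustering(D, k=2)
        assert sel_half.pop_ids == sel_gen.pop_ids

    def test_mismatched_ids_rejected(self):
        D = two_cluster_distance()
        other = _dm(D.D, ids=[f"x{i}" for i in range(D.n)])
        with pytest.raises(ValueError, match="mismatched"):
            select_clustgeo(D, other, k=2)


class TestCdmean:
    def test_trajectory_strictly_increasing(self, small_G):
        sel = select_cdmean(small_G, k=15, n_iter=200, seed=3)
        traj = sel.params["trajectory"]
        assert all(b > a for a, b in zip(traj, traj[1:]))

    def test_k_n_minus_1_matches_exhaustive_enumeration(self, small_imputed):
        """With one validation population the best set is found by brute force."""
        sub = small_imputed.subset_pops(small_imputed.pop_ids[:12])
        G = kinship(sub)
        n = G.n
        ridge = 1e-6 * float(np.diag(G.G).mean())
        Ginv = np.linalg.inv(G.G + ridge * np.eye(n))
        best_val, best_cd = None, -np.inf
        for val in range(n):
            cal = np.array([i for i in range(n) if i != val])
            cd = _cdmean(G.G, Ginv, 1.0, cal, np.array([val]))
            if cd > best_cd:
                best_val, best_cd = val, cd
        sel = select_cdmean(G, k=n - 1, n_iter=500, seed=0)
        left_out = set(G.pop_ids) - set(sel.pop_ids)
        assert left_out == {G.pop_ids[best_val]}
        assert sel.params["cdmean"] == pytest.approx(best_cd, abs=1e-10)

    def test_beats_random_sets(self, small_G):
        rng = np.random.default_rng(7)
        n, k = small_G.n, 15
        ridge = 1e-6 * float(np.diag(small_G.G).mean())
        Ginv = np.linalg.inv(small_G.G + ridge * np.eye(n))
        random_cds = []
        for _ in range(100):
            cal = rng.choice(n, k, replace=False)
            val = np.setdiff1d(np.arange(n), cal)
            random_cds.append(_cdmean(small_G.G, Ginv, 1.0, cal, val))
        for seed in range(3):
            sel = select_cdmean(small_G, k=k, n_iter=300, seed=seed)
            assert sel.params["cdmean"] >= np.mean(random_cds)

    def test_invalid_arguments(self, small_G):
        with pytest.raises(ValueError):
            select_cdmean(small_G, k=small_G.n)
        with pytest.raises(ValueError):
            select_cdmean(small_G, k=5, lam=0.0)


class TestPerformance:
    def test_midpoint_is_half(self):
        assert performance(0.4, 0.2, 0.6) == pytest.approx(0.5)

    def test_max_is_one(self):
        assert performance(0.6, 0.2, 0.6) == pytest.approx(1.0)

    def test_above_one_permitted(self):
        assert performance(0.7, 0.2, 0.6) == pytest.approx(1.25)

    def test_degenerate_envelope_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            performance(0.5, 0.6, 0.6)


class TestEvaluateCalibration:
    def test_random_set_score_within_envelope(self, small_imputed, small_G):
        """A set drawn by the same random mechanism as the envelope scores
        inside [0, 1] whenever it is among the draws."""
        rng = np.random.default_rng(11)
        y = small_imputed.values[:, :40] @ rng.standard_normal(40)
        y = (y - y.mean()) / y.std() + rng.normal(0, 0.3, small_imputed.n_pops)
        k = 20
        ids = [small_imputed.pop_ids[i] for i in rng.choice(small_imputed.n_pops, k, replace=False)]
        sel = CalibrationSet(pop_ids=ids, method="random")
        score = evaluate_calibration(small_imputed, y, sel, n_random=50, seed=12)
        assert score.min_pa <= score.max_pa
        assert np.nanmin(score.random_pas) == pytest.approx(score.min_pa)
        # envelope coherence: median of randoms inside [min, max]
        assert score.min_pa <= np.nanmedian(score.random_pas) <= score.max_pa

    def test_oversized_set_rejected(self, small_imputed):
        sel = CalibrationSet(pop_ids=list(small_imputed.pop_ids), method="genetic")
        with pytest.raises(ValueError):
            evaluate_calibration(small_imputed, np.zeros(small_imputed.n_pops), sel)


class TestBuildGwasSet:
    def test_monogenic_first_pick_is_qtl(self, small_imputed, small_G):
        rng = np.random.default_rng(13)
        qtl_col = int(np.argmax(small_imputed.values.std(axis=0)))
        y = 4.0 * small_imputed.values[:, qtl_col] + rng.normal(0, 0.05, small_imputed.n_pops)
        gwas_set = build_gwas_set(small_imputed, y, small_G)
        assert gwas_set, "expected a non-empty GWAS set"
        qtl_scaffold = small_imputed.marker_map.iloc[qtl_col]["scaffold"]
        first_scaffold = small_imputed.marker_map.loc[gwas_set[0], "scaffold"]
        assert first_scaffold == qtl_scaffold

    def test_null_trait_small_set(self, small_imputed, small_G):
        sizes = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=small_imputed.n_pops)
            sizes.append(len(build_gwas_set(small_imputed, y, small_G)))
        assert np.mean(sizes) <= 0.10 * small_imputed.n_markers

    def test_duplicated_top_marker_never_added_twice(self, small_G):
        rng = np.random.default_rng(14)
        col = rng.uniform(0.1, 0.9, small_G.n)
        other = rng.uniform(0.1, 0.9, (small_G.n, 3))
        freqs = toy_matrix(
            np.column_stack([col, col, other]), pop_ids=list(small_G.pop_ids)
        )
        y = 3 * col + rng.normal(0, 0.1, small_G.n)
        gwas_set = build_gwas_set(freqs, y, small_G)
        assert not {"m0", "m1"} <= set(gwas_set)


@pytest.fixture(scope="module")
def curve_setup(small_imputed, small_G):
    rng = np.random.default_rng(15)
    qtl_col = int(np.argmax(small_imputed.values.std(axis=0)))
    y = 5.0 * small_imputed.values[:, qtl_col] + rng.normal(0, 0.02, small_imputed.n_pops)
    D_gen = euclidean_distances(small_imputed.values, small_imputed.pop_ids)
    cal = select_by_clustering(D_gen, k=40)
    idx = {p: i for i, p in enumerate(small_imputed.pop_ids)}
    f_cal = small_imputed.subset_pops(cal.pop_ids)
    G_cal = kinship(f_cal)
    y_cal = y[[idx[p] for p in cal.pop_ids]]
    gwas_set = build_gwas_set(f_cal, y_cal, G_cal)
    return small_imputed, y, cal, gwas_set, qtl_col


class TestMarkerCurve:
    def test_monogenic_min95_is_one(self, curve_setup):
        freqs, y, cal, gwas_set, qtl_col = curve_setup
        assert freqs.marker_ids[qtl_col] == gwas_set[0]
        curve = marker_curve(freqs, y, cal, gwas_set, max_random=30, seed=1)
        assert curve.min_markers_95_gwas == 1

    def test_curve_max_at_least_first_point(self, curve_setup):
        freqs, y, cal, gwas_set, _ = curve_setup
        curve = marker_curve(freqs, y, cal, gwas_set, max_random=30, seed=2)
        assert np.nanmax(curve.pa_gwas_first) >= curve.pa_gwas_first[0] - 1e-12
        assert (np.diff(curve.counts) == 1).all()

    def test_overlapping_sets_rejected(self, curve_setup):
        freqs, y, cal, gwas_set, _ = curve_setup
        with pytest.raises(ValueError, match="overlap"):
            marker_curve(freqs, y, cal, gwas_set, validation_ids=cal.pop_ids[:3])
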