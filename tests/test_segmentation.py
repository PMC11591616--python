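"""AAHC clustering, GEV, temporal constraint and k selection."""

import itertools

import numpy as np
import pytest

import topomicro as tm
from topomicro.segmentation import (
    SegmentationParams,
    aahc_cluster,
    build_frames,
    compute_gev,
    compute_gev_frames,
    meta_criterion_select,
)
from topomicro.topography import EvokedERP

from conftest import CELLS, orthogonal_templates, tiled_grand_averages


def _params(**kw):
    base = dict(analysis_window_ms=(0.0, 700.0))
    base.update(kw)
    return SegmentationParams(**base)


class TestAahcExactRecovery:
    def test_planted_orthogonal_blocks_recovered(self):
        templates = orthogonal_templates(32, 4, seed=0)
        gas, _ = tiled_grand_averages(templates, noise_sd=0.0)
        frames = build_frames(gas, _params())
        sol = aahc_cluster(frames, _params())[4]
        assert sol.gev_total >= 0.999
        matching = tm.match_templates(sol.templates, templates)
        for planted in templates:
            rec = sol.templates[matching[planted.map_id]]
            corr = tm.spatial_correlation(planted.vector, rec.vector)
            assert abs(corr) >= 0.999

    def test_k1_gev_matches_bruteforce(self):
        """Total GEV at k=1 is the GFP²-weighted mean squared correlation
        with the single centroid, recomputed by brute force."""
        rng = np.random.default_rng(1)
        gas = [
            EvokedERP(
                data=rng.normal(size=(16, 40)), sfreq=256.0, t0_ms=0.0,
                subject_id="ga", language=l, embodiment=e,
            )
            for l, e in CELLS[:1]
        ]
        frames = build_frames(gas, _params())
        sol = aahc_cluster(frames, _params(k_max=1))[1]
        centroid = sol.templates[0].vector
        num = 0.0
        for t in range(frames.n_frames):
            u = frames.unit[:, t] * frames.gfp[t] * np.sqrt(16)
            c = tm.spatial_correlation(u, centroid)
            num += (tm.gfp(u) * c) ** 2
        assert sol.gev_total == pytest.approx(num / frames.gfp2_total, abs=1e-10)

    def test_sweep_gev_nondecreasing_in_k(self):
        templates = orthogonal_templates(24, 4, seed=2)
        gas, _ = tiled_grand_averages(templates, noise_sd=0.3, seed=2)
        frames = build_frames(gas, _params())
        sols = aahc_cluster(frames, _params(k_max=20))
        gev = [sols[k].gev_total for k in sorted(sols)]
        assert all(b >= a - 1e-12 for a, b in zip(gev, gev[1:]))


class TestAahcVsExhaustive:
    @pytest.mark.parametrize("k,seed", [(2, 0), (2, 1), (3, 0), (3, 1)])
    def test_within_2pct_of_best_partition(self, k, seed):
        """AAHC total GEV on a 10-frame planted toy instance reaches
        within 2% of the best over all partition-induced labelings."""
        from conftest import exhaustive_best_gev, planted_toy_instance

        data = planted_toy_instance(seed, k, n_frames=10)
        ga = EvokedERP(
            data=data, sfreq=100.0, t0_ms=0.0, subject_id="ga",
            language="L1", embodiment="motor",
        )
        p = _params(analysis_window_ms=(0.0, 100.0), k_max=k)
        frames = build_frames([ga], p)
        best = exhaustive_best_gev(frames, k)
        aahc = aahc_cluster(frames, p)[k].gev_total
        assert aahc >= best * 0.98


class TestComputeGev:
    def test_pure_template_data_gives_unit_gev(self):
        tmpl = orthogonal_templates(8, 1, seed=3)[0]
        env = np.array([1.0, 2.5, 0.7, 3.0])
        data = tmpl.vector[:, None] * env[None, :]
        per_map, total = compute_gev(data, [tmpl], np.zeros(4, dtype=int))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_unlabeled_gives_zero(self):
        tmpl = orthogonal_templates(8, 1, seed=4)[0]
        data = np.random.default_rng(4).normal(size=(8, 5))
        per_map, total = compute_gev(data, [tmpl], np.full(5, -1))
        assert total == 0.0

    def test_hand_computed_two_channel_instance(self):
        # 2 channels × 3 samples; template [1, −1] (zero mean, GFP 1)
        tmpl = tm.TemplateMap(map_id=0, vector=np.array([1.0, -1.0]))
        data = np.array([[2.0, 1.0, -1.0], [-2.0, 3.0, 1.0]])
        labels = np.array([0, 0, -1])
        # by hand: avg-ref columns → [2,−2],[−1,1] GFP 2,1 corr 1,−1 ; col3 unlabeled
        # GEV = (2² · 1² + 1² · (−1)²) / (2² + 1² + 1²) = 5/6
        per_map, total = compute_gev(data, [tmpl], labels)
        assert total == pytest.approx(5.0 / 6.0, abs=1e-12)


class TestTemporalConstraint:
    def _labels_and_data(self, runs, templates, sfreq):
        labels = np.concatenate([np.full(n, lab) for lab, n in runs])
        data = np.column_stack(
            [templates[lab].vector * 2.0 for lab in labels]
        )
        return labels, data

    def test_run_above_threshold_preserved(self):
        templates = orthogonal_templates(16, 3, seed=5)
        labels, data = self._labels_and_data(
            [(0, 40), (1, 12), (2, 40)], templates, 1024.0
        )  # 12 samples ≈ 11.7 ms ≥ 10 ms
        out = tm.apply_temporal_constraint(labels, 10.0, 1024.0, data, templates)
        assert np.array_equal(out, labels)

    def test_short_run_absorbed_and_no_short_runs_remain(self):
        templates = orthogonal_templates(16, 3, seed=6)
        labels, data = self._labels_and_data(
            [(0, 40), (1, 5), (2, 40)], templates, 1024.0
        )  # 5 samples ≈ 4.9 ms < 10 ms
        out = tm.apply_temporal_constraint(labels, 10.0, 1024.0, data, templates)
        assert 1 not in out
        assert set(out[40:45]) <= {0, 2}
        # post-condition scan: every remaining run lasts ≥ 10 ms
        change = np.flatnonzero(np.diff(out)) + 1
        bounds = np.r_[0, change, len(out)]
        for a, b in zip(bounds, bounds[1:]):
            assert (b - a) * 1000.0 / 1024.0 >= 10.0

    def test_zero_minimum_is_noop(self):
        templates = orthogonal_templates(16, 2, seed=7)
        labels, data = self._labels_and_data([(0, 3), (1, 2)], templates, 1024.0)
        out = tm.apply_temporal_constraint(labels, 0.0, 1024.0, data, templates)
        assert np.array_equal(out, labels)

    def test_constraint_only_loses_gev(self, scaled_analysis):
        seg = scaled_analysis.segmentation
        before = seg.solutions[seg.selected_k].gev_total
        after = seg.gev_total_constrained
        assert after <= before + 1e-12


class TestMetaCriterionSelect:
    def test_recovers_planted_k_over_seeds(self):
        """Four well-separated planted maps, low noise → k = 4 in ≥ 95%
        of 50 seeded instances."""
        hits = 0
        for seed in range(50):
            m = tm.make_montage(32, seed=seed)
            templates = tm.make_templates(m, 4, seed=seed, min_separation=0.5)
            gas, _ = tiled_grand_averages(templates, noise_sd=0.05, seed=seed)
            p = _params()
            frames = build_frames(gas, p)
            k, _ = meta_criterion_select(frames, aahc_cluster(frames, p))
            hits += k == 4
        assert hits >= 48  # ≥ 95% of 50

    def test_pure_noise_selects_few_clusters(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            gas = [
                EvokedERP(
                    data=rng.normal(size=(32, 150)), sfreq=256.0, t0_ms=0.0,
                    subject_id="ga", language=l, embodiment=e,
                )
                for l, e in CELLS
            ]
            p = _params()
            frames = build_frames(gas, p)
            k, _ = meta_criterion_select(frames, aahc_cluster(frames, p))
            assert k <= 3

    def test_sweep_respects_k_max(self):
        templates = orthogonal_templates(16, 2, seed=8)
        gas, _ = tiled_grand_averages(templates, noise_sd=0.2, seed=8)
        sols = aahc_cluster(build_frames(gas, _params()), _params(k_max=20))
        assert max(sols) == 20 and min(sols) == 1


class TestSegmentGrandAverages:
    def test_recovers_planted_windows(self, scaled_dataset, scaled_analysis):
        """The planted P1 (100–150 ms) and N1 (150–300 ms) maps come back
        as distinct templates occupying overlapping windows (Jaccard ≥ 0.8)."""
        seg = scaled_analysis.segmentation
        matching = tm.match_templates(seg.templates, scaled_dataset.timeline.templates)
        assert matching[0] != matching[1]
        for entry in scaled_dataset.timeline.entries[:2]:
            rec_id = matching[entry.map_id]
            # score the map's dominant window in each condition (the map
            # may also win scattered stretches of the noise periods)
            jaccards = []
            for cell in CELLS:
                lo, hi = entry.t_start_ms, entry.t_end_ms
                best = 0.0
                for a, b in seg.map_windows[tuple(cell)].get(rec_id, []):
                    inter = max(0.0, min(b, hi) - max(a, lo))
                    union = (hi - lo) + (b - a) - inter
                    best = max(best, inter / union)
                jaccards.append(best)
            assert np.mean(jaccards) >= 0.8

    def test_identical_conditions_get_identical_labelings(self):
        templates = orthogonal_templates(24, 3, seed=9)
        gas, _ = tiled_grand_averages(templates, noise_sd=0.0, seed=9)
        result = tm.segment_grand_averages(gas, _params())
        per_cond = [
            result.labels[result.frames.condition == ci] for ci in range(4)
        ]
        for lab in per_cond[1:]:
            assert np.array_equal(lab, per_cond[0])

    def test_deterministic_rerun(self, scaled_dataset, scaled_analysis):
        erps = [tm.average_reference(e) for e in scaled_dataset.erps]
        by_cell = {}
        for e in erps:
            by_cell.setdefault(e.cell, []).append(e)
        gas = [tm.grand_average(by_cell[c]) for c in sorted(by_cell)]
        rerun = tm.segment_grand_averages(gas)
        assert rerun.selected_k == scaled_analysis.segmentation.selected_k
        assert np.array_equal(rerun.labels, scaled_analysis.segmentation.labels)
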