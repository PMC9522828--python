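"""Marker discovery: directional counts, Fisher pair tests, threshold learning, panels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphamark.markers import (
    DEFAULT_GRID,
    DiscoveryParams,
    MarkerCandidate,
    build_marker_panels,
    directional_count,
    discover_markers,
    filter_by_reference,
    merge_marker_sets,
    pair_test,
    select_threshold,
)
from alphamark.read_io import AlphaDistribution

from conftest import make_pair_data


def hypergeom_tail(a: int, n_a: int, b: int, n_b: int) -> float:
    """Brute-force one-sided Fisher p: upper tail of the hypergeometric pmf."""
    total, k_dir = n_a + n_b, a + b
    denom = math.comb(total, n_a)
    return sum(
        math.comb(k_dir, k) * math.comb(total - k_dir, n_a - k)
        for k in range(a, min(k_dir, n_a) + 1)
    ) / denom


ALPHAS = np.array([0.1, 0.6, 0.9, 1.0])


@pytest.mark.parametrize(
    "thr, direction, expected",
    [(0.8, "hyper", 2), (0.0, "hyper", 4), (0.1, "hypo", 1), (1.0, "hypo", 4), (1.0, "hyper", 1)],
)
def test_directional_count(thr, direction, expected):
    assert directional_count(ALPHAS, thr, direction) == expected


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=0, max_size=40))
def test_directional_count_monotone_in_threshold(alphas):
    a = np.array(alphas)
    hyper = [directional_count(a, t, "hyper") for t in DEFAULT_GRID]
    hypo = [directional_count(a, t, "hypo") for t in DEFAULT_GRID]
    assert all(x >= y for x, y in zip(hyper, hyper[1:]))
    assert all(x <= y for x, y in zip(hypo, hypo[1:]))
    assert hyper[0] == len(a) and hypo[-1] == len(a)


class TestPairTest:
    def test_two_of_two_vs_zero_of_two(self):
        p = pair_test(np.array([1.0, 1.0]), np.array([0.0, 0.0]), 0.8, "hyper")
        assert p == pytest.approx(1 / 6)

    def test_identical_distributions_uninformative(self):
        a = np.array([0.2, 0.9, 0.9])
        assert pair_test(a, a.copy(), 0.8, "hyper") >= 0.5

    def test_strong_enrichment(self):
        a = np.array([1.0] * 10 + [0.0] * 10)
        b = np.zeros(20)
        assert pair_test(a, b, 0.9, "hyper") < 0.001

    def test_empty_side_is_flagged_uninformative(self):
        assert pair_test(np.array([]), np.array([0.5]), 0.5, "hyper") == 1.0

    def test_matches_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_a, n_b = rng.integers(1, 20, size=2)
            a, b = rng.integers(0, n_a + 1), rng.integers(0, n_b + 1)
            alphas_a = np.r_[np.ones(a), np.zeros(n_a - a)]
            alphas_b = np.r_[np.ones(b), np.zeros(n_b - b)]
            expected = hypergeom_tail(int(a), int(n_a), int(b), int(n_b))
            assert pair_test(alphas_a, alphas_b, 0.5, "hyper") == pytest.approx(expected, abs=1e-12)


class TestSelectThreshold:
    def test_tie_breaks_to_extreme_threshold(self):
        tumors = np.r_[np.ones(5), np.zeros(5)]
        normals = np.zeros(10)
        pairs = [(tumors, normals)] * 3
        thr, n_support = select_threshold(pairs, "hyper", p_cut=0.05)
        assert thr == 1.0 and n_support == 3

    def test_no_signal_yields_zero_support(self):
        a = np.full(10, 0.5)
        thr, n_support = select_threshold([(a, a.copy())] * 4, "hyper", p_cut=0.05)
        assert n_support == 0

    def test_single_pair_perfect_separation(self):
        thr, n_support = select_threshold(
            [(np.ones(6), np.zeros(6))], "hyper", p_cut=0.5
        )
        assert n_support == 1 and thr == 1.0

    def test_hypo_ties_break_low(self):
        tumors = np.zeros(10)
        normals = np.ones(10)
        thr, n_support = select_threshold([(tumors, normals)] * 2, "hypo", p_cut=0.05)
        assert thr == 0.0 and n_support == 2

    def test_support_matches_per_threshold_fisher_oracle(self):
        """The selected support equals the max over the grid of pair-counted Fisher calls."""
        rng = np.random.default_rng(3)
        pairs = [(rng.random(15), rng.random(15) * 0.5) for _ in range(6)]
        thr, n_support = select_threshold(pairs, "hyper", p_cut=0.05)
        oracle = max(
            sum(pair_test(a, b, t, "hyper") < 0.05 for a, b in pairs) for t in DEFAULT_GRID
        )
        assert n_support == oracle


class TestReferenceFilter:
    cand = MarkerCandidate("r", "hyper", 0.8, 5, 0.5)

    def _refs(self, fracs, n_reads=20):
        out = []
        for i, f in enumerate(fracs):
            k = round(f * n_reads)
            out.append(AlphaDistribution("r", f"ref{i}", np.r_[np.ones(k), np.zeros(n_reads - k)]))
        return out

    def test_all_clean_passes(self):
        assert filter_by_reference(self.cand, self._refs([0.0] * 30))

    def test_half_dirty_fails(self):
        refs = self._refs([0.5] * 15 + [0.0] * 15)
        assert not filter_by_reference(self.cand, refs, max_frac=0.05, min_pass_frac=0.9)

    def test_28_of_30_clean_passes(self):
        refs = self._refs([0.0] * 28 + [0.5] * 2)
        assert filter_by_reference(self.cand, refs, max_frac=0.05, min_pass_frac=0.9)

    def test_no_reference_samples_is_an_error(self):
        with pytest.raises(ValueError):
            filter_by_reference(self.cand, [])

    def test_sample_without_reads_counts_clean(self):
        refs = [AlphaDistribution("r", "e", np.empty(0))] + self._refs([0.0] * 9)
        assert filter_by_reference(self.cand, refs)


class TestDiscoverMarkers:
    def test_recovers_planted_hyper_dmrs(self):
        dists, region_ids, pairs, planted = make_pair_data(seed=21, n_dmr=5)
        ms = discover_markers(
            dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
            "hyper", pairing="paired", pairs=pairs,
        )
        assert set(ms.region_ids) == set(planted)

    def test_hypo_run_on_hyper_data_returns_none(self):
        dists, region_ids, pairs, planted = make_pair_data(seed=22, n_dmr=5, direction="hypo")
        hypo = discover_markers(dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
                                "hypo", pairing="paired", pairs=pairs)
        hyper = discover_markers(dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
                                 "hyper", pairing="paired", pairs=pairs)
        assert set(hypo.region_ids) == set(planted)
        assert len(hyper) == 0

    def test_null_data_yields_almost_no_markers(self):
        dists, region_ids, pairs, _ = make_pair_data(seed=23, n_dmr=0)
        ms = discover_markers(dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
                              "hyper", pairing="paired", pairs=pairs)
        assert len(ms) / len(region_ids) < 0.05

    def test_input_validation(self):
        dists, region_ids, pairs, _ = make_pair_data(seed=24, n_regions=10, n_pairs=2, n_dmr=0)
        with pytest.raises(ValueError, match="empty region"):
            discover_markers(dists, [], ["t0", "t1"], ["n0", "n1"], "hyper",
                             pairing="paired", pairs=pairs)
        with pytest.raises(ValueError, match="at least 2"):
            discover_markers(dists, region_ids, ["t0"], ["n0", "n1"], "hyper",
                             pairing="paired", pairs=pairs)

    def test_unpaired_pseudo_pairing_recovers_planted(self):
        dists, region_ids, pairs, planted = make_pair_data(seed=25, n_dmr=5)
        rng = np.random.default_rng(1)
        ms = discover_markers(dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
                              "hyper", pairing="unpaired", rng=rng)
        assert set(planted) <= set(ms.region_ids)

    def test_ranking_is_by_support_then_delta(self):
        dists, region_ids, pairs, _ = make_pair_data(seed=26, n_dmr=6)
        ms = discover_markers(dists, region_ids, [a for a, _ in pairs], [b for _, b in pairs],
                              "hyper", pairing="paired", pairs=pairs)
        keys = [(-m.n_support, -m.mean_delta) for m in ms.markers]
        assert keys == sorted(keys)


class TestBuildPanels:
    def test_panels_recover_planted_truth(self, small_cohort, small_dists):
        region_ids = [r.region_id for r in small_cohort.regions]
        meta = small_cohort.meta.copy()
        ref_ids = meta.loc[meta["condition"] == "noncancer", "sample_id"].tolist()[:10]
        panels = build_marker_panels(small_dists, meta, region_ids, seed=0, reference_ids=ref_ids)
        truth = small_cohort.truth
        pan_hyper = set(truth.dmr_ids(kind="pan_cancer", direction="hyper"))
        got = panels["detection"]["cancer_hyper"].region_ids
        # every planted pan-cancer hyper DMR appears exactly once in the merged panel
        assert pan_hyper <= set(got)
        assert len(got) == len(set(got))
        # tissue panels carry the planted tissue-specific DMRs
        tissue_planted = set(truth.dmr_ids(kind="tissue", direction="hyper"))
        assert tissue_planted <= set(panels["detection"]["tissue_hyper"].region_ids)

    def test_top_m_zero_gives_empty_sets(self, small_cohort, small_dists):
        region_ids = [r.region_id for r in small_cohort.regions]
        meta = small_cohort.meta
        ref_ids = meta.loc[meta["condition"] == "noncancer", "sample_id"].tolist()[:10]
        panels = build_marker_panels(
            small_dists, meta, region_ids, DiscoveryParams(top_m=0), seed=0, reference_ids=ref_ids
        )
        assert all(len(ms) == 0 for task in panels.values() for ms in task.values())

    def test_missing_tissue_type_raises(self, small_cohort, small_dists):
        meta = small_cohort.meta.copy()
        meta = meta[~((meta["tissue"] == "colon") & (meta["condition"] == "adjacent_normal"))]
        ref_ids = meta.loc[meta["condition"] == "noncancer", "sample_id"].tolist()[:10]
        with pytest.raises(ValueError, match="colon"):
            build_marker_panels(small_dists, meta, [r.region_id for r in small_cohort.regions],
                                seed=0, reference_ids=ref_ids)


def test_merge_keeps_best_ranked_duplicate():
    a = MarkerCandidate("r1", "hyper", 0.8, 5, 0.4)
    b = MarkerCandidate("r1", "hyper", 0.9, 7, 0.3)
    from alphamark.markers import MarkerSet

    merged = merge_marker_sets(
        [MarkerSet("t", "hyper", "c1", [a]), MarkerSet("t", "hyper", "c2", [b])], "t", "hyper"
    )
    assert len(merged) == 1 and merged.markers[0].n_support == 7
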