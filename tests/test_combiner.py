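import numpy as np
import pytest

from disgrou import (
    Config,
    Dataset,
    Interval,
    IntervalSet,
    Selector,
    build_tree,
    make_raw_selectors,
    run_disgrou,
    subgroup_extent,
    target_mean,
)
from disgrou.combiner import (
    collect_branches,
    combination_to_description,
    enumerate_candidates,
    rank_subgroups,
)
from disgrou.selectors import SelectorVocabulary
from disgrou.validation import brute_force_search, random_instance

from conftest import assert_subgroups_match


class TestCollectBranches:
    def test_toy_tree_paths(self, tree_dataset, tree_vocabulary):
        tree = build_tree(tree_dataset, tree_vocabulary)
        s1, s2 = tree_vocabulary.selectors
        (b2,) = collect_branches(tree, s2, tree_vocabulary)
        assert b2.path_selectors == (0, 1)
        assert (b2.count, b2.target_sum) == (2, 10.0)
        (b1,) = collect_branches(tree, s1, tree_vocabulary)
        assert b1.path_selectors == (0,)
        assert (b1.count, b1.target_sum) == (3, 11.0)

    def test_absent_selector_gives_empty_list(self, tree_dataset, tree_vocabulary):
        tree = build_tree(tree_dataset, tree_vocabulary)
        stranger = Selector("x", IntervalSet.from_bounds((-9, -8)))
        assert collect_branches(tree, stranger, tree_vocabulary) == []


class TestEnumerateCandidates:
    def test_toy_candidate_table(self, tree_dataset, tree_vocabulary):
        tree = build_tree(tree_dataset, tree_vocabulary)
        cands = enumerate_candidates(
            tree, tree_vocabulary, Config(beta_abs=1), beta_abs=1
        )
        assert cands[(0,)] == (3, 11.0)
        assert cands[(0, 1)] == (2, 10.0)
        assert cands[(1,)] == (2, 10.0)

    def test_single_selector_vocabulary(self):
        ds = Dataset(["x"], np.array([[1.0], [2.0]]), np.array([3.0, 1.0]))
        sel = Selector("x", IntervalSet.from_bounds((1, 2)))
        voc = SelectorVocabulary.from_selectors([sel], ds)
        tree = build_tree(ds, voc)
        cands = enumerate_candidates(tree, voc, Config(beta_abs=1), beta_abs=1)
        assert cands == {(0,): (2, 4.0)}

    @pytest.mark.parametrize("seed", range(15))
    def test_candidate_counts_equal_direct_extents(self, seed):
        """The central aggregation theorem, checked by direct filtering."""
        ds, cfg = random_instance(seed)
        voc = make_raw_selectors(ds, cfg)
        beta_abs = cfg.resolve_beta_abs(
            len(np.flatnonzero(ds.target > target_mean(ds)))
        )
        tree = build_tree(ds, voc)
        cands = enumerate_candidates(tree, voc, cfg, beta_abs=beta_abs)
        assert cands, "fuzz instance produced no candidates"
        for combo, (count, tsum) in cands.items():
            desc = combination_to_description([voc[i] for i in combo])
            ext = subgroup_extent(desc, ds)
            assert len(ext) == count
            assert float(ds.target[ext].sum()) == pytest.approx(tsum, abs=1e-9)


class TestDescriptions:
    def test_same_attribute_intersection(self):
        a = Selector("temp", IntervalSet.from_bounds((23, 33)))
        b = Selector("temp", IntervalSet.from_bounds((20, 25), (28, 40)))
        desc = combination_to_description([a, b])
        assert desc == {"temp": IntervalSet.from_bounds((23, 25), (28, 33))}

    def test_single_selector_identity(self):
        a = Selector("temp", IntervalSet.from_bounds((23, 33)))
        assert combination_to_description([a]) == {
            "temp": IntervalSet.from_bounds((23, 33))
        }

    def test_distinct_attributes_pass_through(self):
        a = Selector("temp", IntervalSet.from_bounds((23, 33)))
        b = Selector("rain", IntervalSet.from_bounds((3, 6)))
        desc = combination_to_description([a, b])
        assert set(desc) == {"temp", "rain"}
        assert desc["temp"] == a.ranges and desc["rain"] == b.ranges


class TestRanking:
    def test_toy_qualities_and_tie_break(self, tree_dataset, tree_vocabulary):
        # m0 = 11/3: q({s1}) = 0 while q({s1,s2}) = q({s2}) = 8/3; the
        # quality tie is broken toward the smaller description {s2}
        tree = build_tree(tree_dataset, tree_vocabulary)
        cands = enumerate_candidates(
            tree, tree_vocabulary, Config(beta_abs=1), beta_abs=1
        )
        ranked = rank_subgroups(
            cands, tree_dataset, Config(beta_abs=1, alpha=1.0), tree_vocabulary
        )
        assert [round(s.quality, 9) for s in ranked] == [
            round(8 / 3, 9), round(8 / 3, 9), 0.0
        ]
        assert ranked[0].description == {
            "y": IntervalSet.from_bounds((0, 1))
        }
        assert set(ranked[1].description) == {"x", "y"}

    def test_alpha_zero_ranks_by_mean_alone(self):
        ds = Dataset(
            ["x"],
            np.array([[1.0], [2.0], [3.0], [5.0], [5.0]]),
            np.array([2.0, 2.0, 2.0, 10.0, 10.0]),
        )
        best = run_disgrou(ds, Config(beta_abs=1, alpha=0.0, top_k=1))[0]
        assert best.description == {"x": IntervalSet.from_bounds((5, 5))}
        assert best.mean == pytest.approx(10.0)

    def test_top_k_truncates(self, toy_dataset):
        assert len(run_disgrou(toy_dataset, Config(beta_abs=1, top_k=1))) == 1


class TestPipeline:
    def test_reported_subgroups_are_extent_consistent(self, toy_dataset):
        subs = run_disgrou(toy_dataset, Config(beta_abs=1))
        for sub in subs:
            ext = subgroup_extent(sub.description, toy_dataset)
            assert len(ext) == sub.n
            assert float(toy_dataset.target[ext].sum()) == pytest.approx(
                sub.target_sum, abs=1e-9
            )

    def test_constant_target_raises(self):
        ds = Dataset(["x"], np.array([[1.0], [2.0]]), np.array([5.0, 5.0]))
        with pytest.raises(Exception, match="no positive transactions"):
            run_disgrou(ds, Config(beta_abs=1))

    def test_continuous_optimum_is_found(self):
        # the best mean-exceeding region is one continuous interval: the
        # miner's top-1 equals the continuous-only exhaustive optimum
        rng = np.random.default_rng(5)
        values = np.arange(20.0)
        target = np.where((values >= 5) & (values <= 9), 10.0, 1.0)
        ds = Dataset(["x"], values[:, None], target)
        cfg = Config(beta_abs=2, alpha=1.0, top_k=1)
        best = run_disgrou(ds, cfg)[0]
        m0 = target_mean(ds)
        # continuous brute force over all value intervals
        best_cont = max(
            (
                values[(values >= lo) & (values <= hi)].size
                * (
                    target[(values >= lo) & (values <= hi)].mean() - m0
                )
                for lo in values
                for hi in values[values >= lo]
            ),
        )
        assert best.quality == pytest.approx(best_cont)

    def test_raising_beta_never_improves_top1(self):
        for seed in range(6):
            ds, cfg = random_instance(seed)
            qualities = []
            for beta_abs in (1, 2, 3, 4):
                subs = run_disgrou(
                    ds,
                    Config(beta_abs=beta_abs, alpha=cfg.alpha, top_k=1),
                )
                qualities.append(subs[0].quality if subs else None)
            present = [q for q in qualities if q is not None]
            assert all(
                later <= earlier + 1e-9
                for earlier, later in zip(present, present[1:])
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        ds, cfg = random_instance(seed)
        voc = make_raw_selectors(ds, cfg)
        subs = run_disgrou(ds, cfg)
        oracle = brute_force_search(ds, voc, cfg)
        if oracle is None:
            assert subs == []
        else:
            assert_subgroups_match(subs[0], oracle)
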