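"""KS tag statistics, instance scoring, scaling, aggregation and ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senesig import (Instance, InstanceDatabase, TagLists, ks_tag_statistic,
                     score_instance, scale_scores, aggregate_perturbagen,
                     rank_results, query)
from senesig.connectivity import InstanceScore
from senesig.errors import MissingTagError, ValidationError


def make_db(rankings, perturbagens, cell_line="MCF7", ids=None):
    instances = []
    for i, (rank, pert) in enumerate(zip(rankings, perturbagens)):
        iid = f"i{i:03d}" if ids is None else ids[i]
        instances.append(Instance(
            instance_id=iid, perturbagen=pert, concentration="1uM",
            batch="b1", ranking=np.asarray(rank), cell_line=cell_line))
    return InstanceDatabase.from_instances(instances)


def probe_names(n):
    return np.array([f"pr{i:03d}" for i in range(n)])


class TestKsTagStatistic:
    def test_top_block_closed_form(self):
        # tags at ranks (1, 2) of 10: a = 0.8, b = 0.1 -> 0.8; generally 1 - t/n
        assert ks_tag_statistic([1, 2], 10) == pytest.approx(0.8)
        for t, n in [(3, 10), (5, 50), (10, 40)]:
            assert ks_tag_statistic(np.arange(1, t + 1), n) == pytest.approx(1 - t / n)

    def test_bottom_block_closed_form(self):
        assert ks_tag_statistic([9, 10], 10) == pytest.approx(-0.9)

    def test_evenly_spread_tags_near_zero(self):
        for t, n in [(5, 50), (10, 100)]:
            ranks = np.arange(1, t + 1) * (n // t)
            assert abs(ks_tag_statistic(ranks, n)) <= 1 / t + 1 / n

    def test_matches_scipy_one_sample_ks_oracle(self):
        # exhaustively for small n, then randomly up to n=50, t=10:
        # a and b are the D+ / D- statistics of V/n against U(0, 1]
        cases = [(np.array(c), n) for n in (5, 8)
                 for t in range(1, n)
                 for c in itertools.combinations(range(1, n + 1), t)]
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(11, 51))
            t = int(rng.integers(1, 11))
            cases.append((rng.choice(n, t, replace=False) + 1, n))
        for ranks, n in cases:
            ours = ks_tag_statistic(ranks, n)
            sample = np.sort(ranks) / n
            dplus = stats.ks_1samp(sample, stats.uniform(0, 1).cdf,
                                   alternative="greater").statistic
            dminus = stats.ks_1samp(sample, stats.uniform(0, 1).cdf,
                                    alternative="less").statistic
            expect = dplus if dplus > dminus else -dminus
            assert ours == pytest.approx(expect, abs=1e-12), (ranks, n)

    def test_invalid_tags_rejected(self):
        with pytest.raises(ValidationError):
            ks_tag_statistic([], 10)
        with pytest.raises(ValidationError):
            ks_tag_statistic([1, 1], 10)
        with pytest.raises(ValidationError):
            ks_tag_statistic(list(range(1, 11)), 10)


class TestInstanceScoring:
    def test_signature_at_extremes_scores_positive(self):
        probes = probe_names(20)
        inst = Instance("i0", "drugA", "1uM", "b1", probes)
        tags = TagLists(up_tags=list(probes[:3]), down_tags=list(probes[-3:]))
        s = score_instance(tags, inst)
        assert s.ks_up > 0 > s.ks_down
        assert s.raw_score == pytest.approx(s.ks_up - s.ks_down)

    def test_same_sign_ks_gives_zero(self):
        probes = probe_names(20)
        inst = Instance("i0", "drugA", "1uM", "b1", probes)
        tags = TagLists(up_tags=list(probes[:3]), down_tags=list(probes[3:6]))
        assert score_instance(tags, inst).raw_score == 0.0

    def test_swapping_tag_lists_negates_raw(self):
        rng = np.random.default_rng(1)
        probes = probe_names(50)
        inst = Instance("i0", "drugA", "1uM", "b1", rng.permutation(probes))
        tags = TagLists(up_tags=list(probes[:5]), down_tags=list(probes[10:15]))
        fwd = score_instance(tags, inst)
        rev = score_instance(TagLists(up_tags=tags.down_tags,
                                      down_tags=tags.up_tags), inst)
        if fwd.raw_score != 0:
            assert rev.raw_score == pytest.approx(-fwd.raw_score)

    def test_missing_tag_error_lists_tags(self):
        inst = Instance("i0", "drugA", "1uM", "b1", probe_names(10))
        tags = TagLists(up_tags=["pr000", "absent"], down_tags=["pr009"])
        with pytest.raises(MissingTagError, match="absent"):
            score_instance(tags, inst)


class TestScaling:
    def make(self, raws):
        return [InstanceScore(f"i{k}", 0.5, -0.5, r) for k, r in enumerate(raws)]

    def test_direct_division_example(self):
        scaled = scale_scores(self.make([0.4, 0.2, -0.5]))
        assert [s.scaled_score for s in scaled] == pytest.approx([1.0, 0.5, -1.0])

    def test_max_positive_scales_to_one_and_bounds(self):
        rng = np.random.default_rng(2)
        scaled = scale_scores(self.make(rng.uniform(-2, 2, 40)))
        vals = np.array([s.scaled_score for s in scaled])
        assert np.abs(vals).max() <= 1.0
        assert np.sum(vals == 1.0) == 1

    def test_all_zero_raws_stay_zero(self):
        scaled = scale_scores(self.make([0.0, 0.0]))
        assert all(s.scaled_score == 0 for s in scaled)


class TestAggregationAndRanking:
    def test_top_block_enrichment_closed_form(self):
        # one perturbagen's 3 instances occupy the top 3 of 30 positions
        rng = np.random.default_rng(3)
        scored = pd.DataFrame({
            "instance_id": [f"i{k:03d}" for k in range(30)],
            "scaled_score": np.sort(rng.uniform(-1, 1, 30))[::-1],
        })
        meta = pd.DataFrame({"instance_id": scored["instance_id"],
                             "perturbagen": ["hit"] * 3 + ["null"] * 27})
        res = aggregate_perturbagen(scored, meta, n_draws=500, seed=0)
        hit = res[res["name"] == "hit"].iloc[0]
        assert hit["enrichment"] == pytest.approx(1 - 3 / 30)
        assert hit["p_value"] <= 2 * 3 / 501  # at/near the permutation floor
        assert hit["n"] == 3

    def test_single_median_instance_p_near_half(self):
        scored = pd.DataFrame({
            "instance_id": [f"i{k:03d}" for k in range(101)],
            "scaled_score": np.linspace(1, -1, 101),
        })
        perts = ["null"] * 101
        perts[50] = "mid"
        meta = pd.DataFrame({"instance_id": scored["instance_id"], "perturbagen": perts})
        res = aggregate_perturbagen(scored, meta, n_draws=4000, seed=1)
        mid = res[res["name"] == "mid"].iloc[0]
        assert 0.3 < mid["p_value"] <= 1.0

    def test_mean_and_n_are_plain_aggregates(self):
        scored = pd.DataFrame({"instance_id": ["a", "b"],
                               "scaled_score": [0.8, 0.9]})
        meta = pd.DataFrame({"instance_id": ["a", "b"], "perturbagen": ["x", "x"]})
        res = aggregate_perturbagen(scored, meta, n_draws=100, seed=0)
        assert res.iloc[0]["mean"] == pytest.approx(0.85)
        assert res.iloc[0]["n"] == 2

    def test_ranking_keys_and_tie_rule(self):
        res = pd.DataFrame({
            "name": ["slow", "beta", "alpha", "weak"],
            "mean": [0.5] * 4, "n": [2] * 4,
            "enrichment": [0.7, 0.994, 0.999, 0.994],
            "p_value": [0.01, 0.0005, 0.0005, 0.0005],
            "specificity": [np.nan] * 4,
        })
        ranked = rank_results(res)
        # p ascending, then |enrichment| descending, then name
        assert list(ranked["name"]) == ["alpha", "beta", "weak", "slow"]
        assert list(ranked["rank"]) == [1, 2, 3, 4]

    def test_ranking_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        probes = probe_names(60)
        rankings = [rng.permutation(probes) for _ in range(12)]
        perts = [f"pert{k % 4}" for k in range(12)]
        ids = [f"i{k:03d}" for k in range(12)]
        tags = TagLists(up_tags=list(probes[:5]), down_tags=list(probes[5:10]))
        db1 = make_db(rankings, perts, ids=ids)
        db2 = make_db(list(reversed(rankings)), list(reversed(perts)),
                      ids=list(reversed(ids)))
        r1 = query(tags, db1, n_draws=500, seed=9)
        r2 = query(tags, db2, n_draws=500, seed=9)
        pd.testing.assert_frame_equal(
            r1.drop(columns="specificity"), r2.drop(columns="specificity"))


class TestQuery:
    def test_swapped_tags_negate_scaled_scores(self):
        rng = np.random.default_rng(5)
        probes = probe_names(80)
        db = make_db([rng.permutation(probes) for _ in range(10)],
                     [f"p{k}" for k in range(10)])
        tags = TagLists(up_tags=list(probes[:6]), down_tags=list(probes[6:12]))
        from senesig.connectivity import _score_db
        fwd = scale_scores(_score_db(tags, db, False))
        rev = scale_scores(_score_db(
            TagLists(up_tags=tags.down_tags, down_tags=tags.up_tags), db, False))
        np.testing.assert_allclose(fwd["scaled_score"], -rev["scaled_score"])

    def test_positive_only_filter(self):
        rng = np.random.default_rng(6)
        probes = probe_names(100)
        db = make_db([rng.permutation(probes) for _ in range(30)],
                     [f"p{k % 10}" for k in range(30)])
        tags = TagLists(up_tags=list(probes[:8]), down_tags=list(probes[8:16]))
        rep = query(tags, db, positive_only=True, n_draws=200, seed=0)
        assert (rep["enrichment"] > 0).all()

    def test_metadata_filter_restricts_and_empty_filter_errors(self):
        rng = np.random.default_rng(7)
        probes = probe_names(40)
        instances = []
        for k in range(8):
            instances.append(Instance(
                f"i{k}", f"p{k}", "1uM", "b1", rng.permutation(probes),
                cell_line="MCF7" if k < 5 else "PC3"))
        db = InstanceDatabase.from_instances(instances)
        tags = TagLists(up_tags=list(probes[:4]), down_tags=list(probes[4:8]))
        rep = query(tags, db, metadata_filter={"cell_line": "MCF7"},
                    n_draws=100, seed=0)
        assert set(rep["name"]) <= {f"p{k}" for k in range(5)}
        with pytest.raises(ValidationError):
            query(tags, db, metadata_filter={"cell_line": "K562"},
                  n_draws=100, seed=0)

    def test_drop_missing_tags_mode(self):
        rng = np.random.default_rng(8)
        probes = probe_names(40)
        db = make_db([rng.permutation(probes) for _ in range(4)], list("abcd"))
        tags = TagLists(up_tags=list(probes[:4]) + ["foreign"],
                        down_tags=list(probes[4:8]))
        with pytest.raises(MissingTagError):
            query(tags, db, n_draws=100, seed=0)
        rep = query(tags, db, n_draws=100, seed=0, drop_missing_tags=True)
        assert len(rep) == 4

    def test_db_round_trip_through_rank_files(self, tmp_path):
        rng = np.random.default_rng(9)
        probes = probe_names(25)
        db = make_db([rng.permutation(probes) for _ in range(3)], list("xyz"))
        db.to_dir(tmp_path / "db")
        back = InstanceDatabase.from_dir(tmp_path / "db")
        tags = TagLists(up_tags=list(probes[:3]), down_tags=list(probes[3:6]))
        from senesig.connectivity import _score_db
        pd.testing.assert_frame_equal(_score_db(tags, db, False),
                                      _score_db(tags, back, False))
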