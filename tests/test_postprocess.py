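import numpy as np
import pytest

from ontoquant.encoder import Encoder, small_config
from ontoquant.errors import ValidationError
from ontoquant.fixtures import SynthConfig, gen_aligned_corpora
from ontoquant.postprocess import (Constraints, EvalPoint, QuantCandidate,
                                   RatedAlignment, complementarity_merge,
                                   minmax_rescale, pareto_frontier,
                                   search_quant_configs)
from ontoquant.quantcore import PER_TENSOR, per_channel


class TestMinMaxRescale:
    def test_formula(self):
        np.testing.assert_allclose(minmax_rescale([0.2, 0.6, 1.0], 0, 5),
                                   [0.0, 2.5, 5.0])

    def test_constant_maps_to_lo(self):
        np.testing.assert_array_equal(minmax_rescale([0.9, 0.9], 0, 5),
                                      [0.0, 0.0])

    def test_identity_on_spanning_input(self):
        np.testing.assert_allclose(minmax_rescale([0.0, 5.0], 0, 5),
                                   [0.0, 5.0])

    def test_monotone_and_idempotent_once_spanning(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=20)
        y = minmax_rescale(x, 0, 5)
        assert np.all(np.diff(y[np.argsort(x)]) >= 0)
        np.testing.assert_allclose(minmax_rescale(y, 0, 5), y, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            minmax_rescale([], 0, 5)


def _ra(src, rating, tag, target="T"):
    return RatedAlignment(source_key=src, target_key=target, score=0.5,
                          rating=rating, model_tag=tag)


class TestComplementarityMerge:
    def test_descending_rating_walkthrough(self):
        a = [_ra("t1", 5, "A"), _ra("t2", 4, "A"), _ra("t3", 3, "A")]
        b = [_ra("t1", 4, "B"), _ra("t2", 5, "B"), _ra("t4", 5, "B")]
        merged = complementarity_merge(a, b)
        picks = [(m.source_key, m.model_tag, m.rating) for m in merged]
        assert picks == [("t1", "A", 5), ("t2", "B", 5), ("t4", "B", 5),
                         ("t3", "A", 3)]

    def test_empty_secondary_is_neutral(self):
        a = [_ra("t1", 5, "A"), _ra("t2", 2, "A")]
        assert complementarity_merge(a, []) == [a[0], a[1]]

    def test_union_coverage(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            srcs_a = rng.choice(20, size=rng.integers(1, 10), replace=False)
            srcs_b = rng.choice(20, size=rng.integers(1, 10), replace=False)
            a = [_ra(f"s{i}", int(rng.integers(6)), "A") for i in srcs_a]
            b = [_ra(f"s{i}", int(rng.integers(6)), "B") for i in srcs_b]
            merged = complementarity_merge(a, b)
            merged_keys = {m.source_key for m in merged}
            assert len(merged) == len(merged_keys)
            assert merged_keys == ({f"s{i}" for i in srcs_a}
                                   | {f"s{i}" for i in srcs_b})

    def test_primary_rating5_retained_verbatim(self):
        a = [_ra("t1", 5, "A", target="good")]
        b = [_ra("t1", 5, "B", target="other")]
        (m,) = complementarity_merge(a, b)
        assert (m.model_tag, m.target_key) == ("A", "good")

    def test_duplicate_source_rejected(self):
        with pytest.raises(ValidationError):
            complementarity_merge([_ra("t1", 5, "A"), _ra("t1", 4, "A")], [])


def _pt(quality, cost):
    cand = QuantCandidate(scheme=PER_TENSOR, alpha=None, label="x")
    return EvalPoint(candidate=cand, quality=quality, cost=cost)


class TestParetoFrontier:
    def test_dominated_point_removed(self):
        pts = [_pt(0.9, 10), _pt(0.8, 5), _pt(0.85, 12)]
        front = pareto_frontier(pts)
        assert [(p.quality, p.cost) for p in front] == [(0.9, 10), (0.8, 5)]

    def test_singleton(self):
        pts = [_pt(0.5, 1)]
        assert pareto_frontier(pts) == pts

    def test_duplicates_all_retained(self):
        pts = [_pt(0.5, 1), _pt(0.5, 1), _pt(0.5, 1)]
        assert pareto_frontier(pts) == pts

    def test_matches_pairwise_dominance_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 12))
            pts = [_pt(float(rng.choice([0.2, 0.5, 0.8, 0.9])),
                       float(rng.choice([1, 2, 5, 10])))
                   for _ in range(n)]

            def dominated(p):
                return any(q.quality >= p.quality and q.cost <= p.cost
                           and (q.quality > p.quality or q.cost < p.cost)
                           for q in pts)

            oracle = [p for p in pts if not dominated(p)]
            assert pareto_frontier(pts) == oracle

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pareto_frontier([])


@pytest.fixture(scope="module")
def setup():
    corp = gen_aligned_corpora(SynthConfig(n_concepts=15, seed=5))
    enc = Encoder(small_config(seed=42))
    candidates = [
        QuantCandidate(per_channel(1), alpha=0.5, label="w8a8_smooth"),
        QuantCandidate(PER_TENSOR, alpha=None, label="w8a8_pertensor"),
    ]
    return corp, enc, candidates


class TestSearch:

    def test_report_structure_and_cost_bound(self, setup):
        corp, enc, candidates = setup
        report = search_quant_configs(candidates, enc, corp)
        assert len(report.points) == 2
        for p in report.points:
            assert p.cost <= 0.30 * report.fp_cost
        d = report.to_dict()
        assert {c["label"] for c in d["candidates"]} == \
            {"w8a8_smooth", "w8a8_pertensor"}

    def test_vacuous_constraints_make_all_feasible(self, setup):
        corp, enc, candidates = setup
        report = search_quant_configs(
            candidates, enc, corp,
            Constraints(max_degradation=1.0, min_cost_reduction=0.0))
        assert all(report.feasible)

    def test_empty_feasible_set_reported_not_raised(self, setup):
        corp, enc, candidates = setup
        report = search_quant_configs(
            candidates, enc, corp,
            Constraints(max_degradation=0.0, min_cost_reduction=1.0))
        assert not any(report.feasible)
        assert report.best_index is None
        assert report.frontier_indices  # frontier still reported

    def test_smoothed_per_channel_not_worse(self):
        # quality comparison across seeds: per-channel + smoothing should
        # match FP32 argmax at least as often as plain per-tensor weights
        wins = 0
        seeds = [1, 2, 3]
        for seed in seeds:
            corp = gen_aligned_corpora(SynthConfig(n_concepts=15, seed=seed))
            enc = Encoder(small_config(seed=seed + 50))
            report = search_quant_configs(
                [QuantCandidate(per_channel(1), 0.5, "smooth"),
                 QuantCandidate(PER_TENSOR, None, "plain")], enc, corp)
            q_smooth, q_plain = (report.points[0].quality,
                                 report.points[1].quality)
            wins += q_smooth >= q_plain
        assert wins > len(seeds) / 2

    def test_empty_candidates_rejected(self, setup):
        corp, enc, _ = setup
        with pytest.raises(ValidationError):
            search_quant_configs([], enc, corp)
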