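import io
import math

import numpy as np
import pytest

from signet.condense import (
    ConditionPair,
    condense,
    gene_values,
    link_score,
    overlay_colors,
)
from signet.errors import (
    NoScorableLinksError,
    ParameterError,
    UnmeasuredGeneError,
)
from signet.model import GeneNode, LinkType, RegLink, build_network
from signet.simulate import (
    ExpressionGenParams,
    choose_planted,
    simulate_expression,
)


def pair_of(values, **kwargs):
    return ConditionPair(values=values, **kwargs)


class TestGeneValues:
    def test_log2_means(self):
        pair = pair_of({"g": ((4.0, 4.0), (8.0, 8.0))}, transform="log2")
        assert gene_values(pair, "g") == (2.0, 3.0)

    def test_degenerate_variance_keeps_equality(self):
        pair = pair_of(
            {"g": ((5.0, 5.0), (5.0, 5.0))}, scoring_mode="variance_corrected"
        )
        v1, v2 = gene_values(pair, "g")
        assert v1 == v2

    def test_variance_correction_divides_by_pooled_sd(self):
        vals = ((1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        pair = pair_of({"g": vals}, scoring_mode="variance_corrected")
        pooled_sd = np.std(np.array(vals).ravel(), ddof=1)
        v1, v2 = gene_values(pair, "g")
        assert v1 == pytest.approx(2.0 / pooled_sd)
        assert v2 == pytest.approx(5.0 / pooled_sd)

    def test_random_replicates_match_direct_means(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v1 = tuple(rng.uniform(1, 10, size=4))
            v2 = tuple(rng.uniform(1, 10, size=3))
            pair = pair_of({"g": (v1, v2)})
            assert gene_values(pair, "g") == pytest.approx(
                (np.mean(v1), np.mean(v2))
            )

    def test_unmeasured_gene_signals(self):
        with pytest.raises(UnmeasuredGeneError):
            gene_values(pair_of({"g": ((1.0,), (1.0,))}), "other")

    def test_log2_requires_positive_intensities(self):
        with pytest.raises(ParameterError):
            pair_of({"g": ((0.0,), (1.0,))}, transform="log2")


class TestLinkScore:
    def test_hand_arithmetic(self):
        pair = pair_of({"a": ((1.0,), (2.0,)), "b": ((1.0,), (2.0,))})
        link = RegLink("a", "b", LinkType.STIMULATION)
        assert link_score(link, pair) == 3.0  # 2*2 - 1*1

    def test_identical_conditions_score_zero(self):
        pair = pair_of({"a": ((1.5,), (1.5,)), "b": ((2.5,), (2.5,))})
        assert link_score(RegLink("a", "b", LinkType.INHIBITION), pair) == 0.0

    def test_swapping_conditions_negates_scores(self):
        rng = np.random.default_rng(11)
        values = {
            g: (tuple(rng.uniform(1, 10, 3)), tuple(rng.uniform(1, 10, 3)))
            for g in "abcd"
        }
        pair = pair_of(values)
        for src, tgt in [("a", "b"), ("c", "d"), ("b", "c")]:
            link = RegLink(src, tgt, LinkType.STIMULATION)
            assert link_score(link, pair.swapped()) == -link_score(link, pair)


def two_node_net():
    return build_network(
        [GeneNode("a"), GeneNode("b"), GeneNode("c")],
        [
            RegLink("a", "b", LinkType.STIMULATION),
            RegLink("b", "c", LinkType.INHIBITION),
        ],
    )


class TestCondense:
    def test_tail_sizes_bounded_by_fraction(self, make_network):
        net = make_network(40, 100, seed=2)
        planted = choose_planted(net, 4, seed=2)
        pair = simulate_expression(net, ExpressionGenParams(direction=planted, seed=2))
        result = condense(net, pair, 0.05)
        bound = math.ceil(0.05 * result.n_scored)
        assert len(result.startups) <= bound
        assert len(result.shutdowns) <= bound
        assert result.n_scored + result.n_unscored == net.n_links

    def test_fraction_out_of_range(self, make_network):
        net = two_node_net()
        pair = pair_of({g: ((1.0,), (2.0,)) for g in "abc"})
        for bad in (0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                condense(net, pair, bad)

    def test_unmeasured_links_counted_not_imputed(self):
        net = two_node_net()
        pair = pair_of({"a": ((1.0,), (2.0,)), "b": ((1.0,), (2.0,))})
        result = condense(net, pair, 1.0)
        assert result.n_scored == 1 and result.n_unscored == 1

    def test_no_scorable_links_is_an_error(self):
        net = two_node_net()
        pair = pair_of({"z": ((1.0,), (1.0,))})
        with pytest.raises(NoScorableLinksError):
            condense(net, pair, 0.5)

    def test_each_tail_keeps_at_least_one_when_signed_links_exist(self):
        net = two_node_net()
        pair = pair_of(
            {"a": ((1.0,), (2.0,)), "b": ((1.0,), (2.0,)), "c": ((3.0,), (1.0,))}
        )
        result = condense(net, pair, 0.01)  # floor(0.01*2) == 0
        assert len(result.startups) == 1 and len(result.shutdowns) == 1

    def test_ranks_are_dense_and_signs_match_class(self, make_network):
        net = make_network(40, 120, seed=8)
        planted = choose_planted(net, 6, seed=8)
        pair = simulate_expression(net, ExpressionGenParams(direction=planted, seed=8))
        result = condense(net, pair, 0.10)
        for records in (result.startups, result.shutdowns):
            assert [r.rank_within_class for r in records] == list(
                range(1, len(records) + 1)
            )
        assert all(r.score > 0 for r in result.startups)
        assert all(r.score < 0 for r in result.shutdowns)
        mags = [abs(r.score) for r in result.startups]
        assert mags == sorted(mags, reverse=True)

    def test_planted_strong_effects_fill_the_tail(self, make_network):
        net = make_network(80, 200, seed=4)
        planted = choose_planted(net, 10, seed=4)
        params = ExpressionGenParams(direction=planted, effect_size=4.0, seed=4)
        pair = simulate_expression(net, params)
        result = condense(net, pair, 0.05)
        retained = {r.link_key: r.link_class for r in result.retained}
        correct = sum(retained.get(k) == d for k, d in planted.items())
        assert correct == len(planted)

    def test_condition_swap_exchanges_tails_exactly(self, make_network):
        net = make_network(30, 80, seed=6)
        planted = choose_planted(net, 4, seed=6)
        pair = simulate_expression(net, ExpressionGenParams(direction=planted, seed=6))
        fwd = condense(net, pair, 0.10)
        rev = condense(net, pair.swapped(), 0.10)
        assert {r.link_key for r in fwd.startups} == {r.link_key for r in rev.shutdowns}
        assert {r.link_key for r in fwd.shutdowns} == {r.link_key for r in rev.startups}
        fwd_scores = {r.link_key: r.score for r in fwd.retained}
        for r in rev.retained:
            assert r.score == -fwd_scores[r.link_key]

    def test_positive_scaling_preserves_rankings(self, make_network):
        net = make_network(30, 80, seed=13)
        planted = choose_planted(net, 4, seed=13)
        pair = simulate_expression(net, ExpressionGenParams(direction=planted, seed=13))
        scaled = ConditionPair(
            values={
                g: (tuple(4.0 * x for x in v1), tuple(4.0 * x for x in v2))
                for g, (v1, v2) in pair.values.items()
            },
            transform="raw",
            scoring_mode="plain",
        )
        base = condense(net, pair, 0.10)
        scaled_result = condense(net, scaled, 0.10)
        assert [r.link_key for r in base.retained] == [
            r.link_key for r in scaled_result.retained
        ]
        for rb, rs in zip(base.retained, scaled_result.retained):
            assert rs.score == pytest.approx(16.0 * rb.score, rel=1e-12)


class TestOverlayColors:
    def test_median_gene_is_white_extremes_saturate(self):
        net = build_network([GeneNode(g) for g in "abcde"], [])
        values = {
            g: ((v,), (v,)) for g, v in zip("abcde", [1.0, 2.0, 3.0, 4.0, 5.0])
        }
        rows = {r.symbol: r for r in overlay_colors(net, pair_of(values))}
        assert rows["c"].slice1_color == 0.0 and rows["c"].slice2_color == 0.0
        assert rows["e"].slice2_color == 1.0
        assert rows["a"].slice1_color == -1.0

    def test_colors_monotone_in_expression(self):
        net = build_network([GeneNode(f"g{i}") for i in range(6)], [])
        vals = [3.0, 1.0, 7.0, 5.0, 9.0, 2.0]
        values = {f"g{i}": ((v,), (v,)) for i, v in enumerate(vals)}
        rows = overlay_colors(net, pair_of(values))
        order = sorted(range(6), key=lambda i: vals[i])
        colors = [
            {r.symbol: r.slice1_color for r in rows}[f"g{i}"] for i in order
        ]
        assert colors == sorted(colors)

    def test_unmeasured_gene_gets_sentinel(self):
        net = build_network([GeneNode("a"), GeneNode("x")], [])
        rows = {r.symbol: r for r in overlay_colors(net, pair_of({"a": ((1.0,), (2.0,))}))}
        assert math.isnan(rows["x"].slice1_color)
        assert not rows["x"].measured


class TestConditionPairIO:
    TSV = (
        "gene\ts1\ts2\ts3\ts4\n"
        "condition\t1\t1\t2\t2\n"
        "Pou5f1\t4.0\t6.0\t8.0\t10.0\n"
        "probeA\t1.0\t1.0\t2.0\t2.0\n"
        "probeA\t3.0\t3.0\t4.0\t4.0\n"
    )

    def test_two_line_header_and_probe_collapse(self):
        pair = ConditionPair.from_tsv(io.StringIO(self.TSV))
        assert pair.values["Pou5f1"] == ((4.0, 6.0), (8.0, 10.0))
        # duplicate probe rows collapse by per-sample mean
        assert pair.values["probeA"] == ((2.0, 2.0), (3.0, 3.0))

    def test_bad_condition_tag_rejected(self):
        bad = self.TSV.replace("condition\t1\t1\t2\t2", "condition\t1\tx\t2\t2")
        with pytest.raises(ParameterError):
            ConditionPair.from_tsv(io.StringIO(bad))

    def test_roundtrip_through_tsv(self):
        pair = ConditionPair.from_tsv(io.StringIO(self.TSV))
        back = ConditionPair.from_tsv(io.StringIO(pair.to_tsv()))
        assert back.values == pair.values
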