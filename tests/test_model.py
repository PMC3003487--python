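import random

import pytest

from oracles import links_equal
from signet.errors import (
    DanglingEndpointError,
    DuplicateLinkWarning,
    DuplicateNodeError,
    SelfLoopError,
    UnknownLinkTypeError,
)
from signet.model import (
    GeneNode,
    LinkType,
    Reference,
    RegLink,
    ValidationConfig,
    build_network,
    canonical_link_key,
    simple_projection,
    validate_link_record,
)


class TestLinkType:
    def test_sbo_mapping_is_fixed(self):
        assert LinkType.STIMULATION.sbo_id == "SBO:0000170"
        assert LinkType.INHIBITION.sbo_id == "SBO:0000169"
        assert LinkType.INTERACTION.sbo_id == "SBO:0000231"
        for lt in LinkType:
            assert LinkType.from_sbo(lt.sbo_id) is lt

    def test_directedness(self):
        assert LinkType.STIMULATION.directed
        assert LinkType.INHIBITION.directed
        assert not LinkType.INTERACTION.directed

    def test_unknown_name_raises(self):
        with pytest.raises(UnknownLinkTypeError):
            LinkType.from_name("binds")


class TestBuildNetwork:
    def test_curated_mini_network(self, mini_network):
        assert mini_network.n_nodes == 4
        assert mini_network.n_links == 3
        assert mini_network.nodes["Sall4"].entrez_id == "99377"

    def test_empty_network_is_valid(self):
        net = build_network([], [])
        assert net.n_nodes == 0 and net.n_links == 0

    def test_dangling_endpoint_names_missing_symbol(self):
        with pytest.raises(DanglingEndpointError, match="'Y'"):
            build_network(
                [GeneNode("X")], [RegLink("X", "Y", LinkType.STIMULATION)]
            )

    def test_duplicate_node_rejected(self):
        with pytest.raises(DuplicateNodeError):
            build_network([GeneNode("A"), GeneNode("A")], [])

    def test_self_loop_rejected_by_default_allowed_on_request(self):
        nodes = [GeneNode("A")]
        loop = [RegLink("A", "A", LinkType.STIMULATION)]
        with pytest.raises(SelfLoopError):
            build_network(nodes, loop)
        net = build_network([GeneNode("A")], [RegLink("A", "A", LinkType.STIMULATION)],
                            allow_self_loops=True)
        assert net.n_links == 1

    def test_exact_duplicates_merged_with_unioned_references(self):
        nodes = [GeneNode("A"), GeneNode("B")]
        links = [
            RegLink("A", "B", LinkType.STIMULATION, references=(Reference("1"),)),
            RegLink("A", "B", LinkType.STIMULATION, references=(Reference("2"),)),
            RegLink("B", "A", LinkType.INTERACTION),
            RegLink("A", "B", LinkType.INTERACTION),  # same undirected identity
        ]
        with pytest.warns(DuplicateLinkWarning):
            net = build_network(nodes, links)
        assert net.n_links == 2
        stim = [l for l in net.links if l.link_type is LinkType.STIMULATION][0]
        assert {r.pubmed_id for r in stim.references} == {"1", "2"}

    def test_parallel_links_differing_in_type_or_direction_allowed(self):
        nodes = [GeneNode("A"), GeneNode("B")]
        links = [
            RegLink("A", "B", LinkType.STIMULATION),
            RegLink("B", "A", LinkType.STIMULATION),
            RegLink("A", "B", LinkType.INHIBITION),
            RegLink("A", "B", LinkType.INTERACTION),
        ]
        net = build_network(nodes, links)
        assert net.n_links == 4


class TestCanonicalLinkKey:
    def test_interaction_ignores_endpoint_order(self):
        k1 = canonical_link_key(RegLink("Sall4", "Mta2", LinkType.INTERACTION))
        k2 = canonical_link_key(RegLink("Mta2", "Sall4", LinkType.INTERACTION))
        assert k1 == k2
        assert not k1.directed

    def test_stimulation_preserves_order_unless_ignored(self):
        link = RegLink("Sall4", "Pou5f1", LinkType.STIMULATION)
        key = canonical_link_key(link)
        assert (key.a, key.b, key.directed) == ("Sall4", "Pou5f1", True)
        rev = canonical_link_key(RegLink("Pou5f1", "Sall4", LinkType.STIMULATION))
        assert key != rev
        assert canonical_link_key(link, ignore_direction=True) == canonical_link_key(
            RegLink("Pou5f1", "Sall4", LinkType.STIMULATION), ignore_direction=True
        )

    def test_type_distinguishes_unless_ignored(self):
        stim = RegLink("A", "B", LinkType.STIMULATION)
        inhib = RegLink("A", "B", LinkType.INHIBITION)
        assert canonical_link_key(stim) != canonical_link_key(inhib)
        assert canonical_link_key(stim, ignore_type=True) == canonical_link_key(
            inhib, ignore_type=True
        )

    @pytest.mark.parametrize("ignore_type", [False, True])
    @pytest.mark.parametrize("ignore_direction", [False, True])
    def test_key_is_a_congruence_on_random_link_sets(self, ignore_type, ignore_direction):
        """Two links compare equal iff their canonical keys are equal."""
        rng = random.Random(42)
        symbols = [f"N{i}" for i in range(6)]
        links = []
        for _ in range(50):
            a, b = rng.sample(symbols, 2)
            links.append(RegLink(a, b, rng.choice(list(LinkType))))
        for l1 in links:
            k1 = canonical_link_key(l1, ignore_type, ignore_direction)
            for l2 in links:
                k2 = canonical_link_key(l2, ignore_type, ignore_direction)
                assert (k1 == k2) == links_equal(l1, l2, ignore_type, ignore_direction)


class TestSimpleProjection:
    def test_parallel_links_collapse_to_one_edge(self):
        net = build_network(
            [GeneNode("A"), GeneNode("B")],
            [
                RegLink("A", "B", LinkType.STIMULATION),
                RegLink("A", "B", LinkType.INTERACTION),
            ],
        )
        g = simple_projection(net)
        assert g.edges == frozenset({("A", "B")})

    def test_mini_network_projects_to_star(self, mini_network):
        g = simple_projection(mini_network)
        assert len(g.edges) == 3
        assert all("Sall4" in e for e in g.edges)

    def test_self_loop_dropped_node_kept(self):
        net = build_network(
            [GeneNode("A")],
            [RegLink("A", "A", LinkType.STIMULATION)],
            allow_self_loops=True,
        )
        g = simple_projection(net)
        assert g.edges == frozenset() and g.nodes == frozenset({"A"})

    def test_isolated_nodes_retained(self, make_network):
        net = build_network([GeneNode("A"), GeneNode("B")], [])
        assert simple_projection(net).nodes == frozenset({"A", "B"})

    def test_projection_idempotent_and_bounded(self, make_network):
        for seed in range(5):
            net = make_network(15, 40, seed=seed)
            g = simple_projection(net)
            assert len(g.edges) <= net.n_links
            # re-project the projection expressed as an interaction network
            net2 = build_network(
                [GeneNode(s) for s in g.nodes],
                [RegLink(a, b, LinkType.INTERACTION) for a, b in g.edges],
            )
            assert simple_projection(net2) == g


class TestValidateLinkRecord:
    def test_complete_curated_record_is_clean(self, mini_network):
        stim = [l for l in mini_network.links if l.link_type is LinkType.STIMULATION][0]
        assert validate_link_record(stim) == []

    def test_missing_reference_and_curator_flagged(self):
        link = RegLink("A", "B", LinkType.STIMULATION)
        codes = {f.code for f in validate_link_record(link)}
        assert codes == {"missing-reference", "missing-curator"}
        lenient = ValidationConfig(require_references=False, require_curator=False)
        assert validate_link_record(link, lenient) == []

    def test_unknown_type_and_self_loop_and_bad_pmid_are_findings_not_errors(self):
        link = RegLink("A", "A", "binds", references=(("PMID123", ""),), added_by="x")
        codes = {f.code for f in validate_link_record(link)}
        assert {"unknown-type", "self-loop", "bad-pubmed-id"} <= codes
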