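import datetime

import pytest

from signet.model import GeneNode, LinkType, Reference, RegLink, build_network
from signet.simulate import NetworkGenParams, simulate_network


@pytest.fixture
def mini_network():
    """The curated four-gene example: a star on Sall4 with one link of each type.

    Sall4--Mta2 interaction, Sall4->Pou5f1 stimulation, Sall4-|Sall1
    inhibition, each with its literature reference and curator record.
    """
    nodes = [
        GeneNode("Sall4", full_name="sal-like 4", entrez_id="99377",
                 unigene_id="Mm.389368", ensembl_id="ENSMUSG00000027547",
                 uniprot_id="Q6S7E9"),
        GeneNode("Mta2"),
        GeneNode("Pou5f1"),
        GeneNode("Sall1", full_name="sal-like 1", entrez_id="58198"),
    ]
    links = [
        RegLink("Sall4", "Mta2", LinkType.INTERACTION,
                references=(Reference("19440552", "Lu J, Jeong HW, Kong N, Yang Y"),),
                added_by="CH", added_on=datetime.date(2010, 5, 18)),
        RegLink("Sall4", "Pou5f1", LinkType.STIMULATION,
                references=(Reference("16980957", "Zhang J, Tam WL, Tong GQ, Wu Q"),),
                added_by="AS", added_on=datetime.date(2009, 7, 27)),
        RegLink("Sall4", "Sall1", LinkType.INHIBITION,
                references=(Reference("19440552", "Lu J, Jeong HW, Kong N, Yang Y"),),
                added_by="CH", added_on=datetime.date(2009, 8, 27)),
    ]
    return build_network(nodes, links, name="mini")


@pytest.fixture
def make_network():
    """Factory for seeded random typed networks."""

    def _make(n_nodes=20, n_links=40, seed=0, attachment="uniform"):
        return simulate_network(
            NetworkGenParams(
                n_nodes=n_nodes, n_links=n_links, seed=seed, attachment=attachment
            )
        )

    return _make
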