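"""Masking, haplotype collapse and median-joining networks."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridzone import haplonet
from hybridzone.haplonet import (
    HaplonetError,
    collapse,
    hamming,
    mask_and_trim,
    median_joining,
)
from hybridzone.seqio import SequenceRecord, SpecimenMeta


def _records(strings, locus="cytb"):
    return [SequenceRecord(f"s{i}", locus, s) for i, s in enumerate(strings)]


# ---------------------------------------------------------------- masking

def test_mask_identity_without_missing_data():
    seqs = _records(["ACGT", "ACGA"])
    used, masked = mask_and_trim(seqs)
    assert used == (1, 2, 3, 4)
    assert [m.bases for m in masked] == ["ACGT", "ACGA"]


def test_mask_drops_column_for_all():
    seqs = _records(["ACGTA", "ACGNA", "ACGTA"])
    used, masked = mask_and_trim(seqs)
    assert used == (1, 2, 3, 5)
    assert all(len(m.bases) == 4 for m in masked)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACGTN-", min_size=6, max_size=6),
        min_size=1,
        max_size=5,
    )
)
def test_mask_equals_complement_of_missing_union(seq_strings):
    """Retained columns are exactly the complement of the union of
    missing/ambiguous columns (brute-force column check)."""
    seqs = _records(seq_strings)
    expected = tuple(
        col + 1
        for col in range(6)
        if all(s[col] in "ACGT" for s in seq_strings)
    )
    if not expected:
        with pytest.raises(HaplonetError):
            mask_and_trim(seqs)
        return
    used, masked = mask_and_trim(seqs)
    assert used == expected


# ---------------------------------------------------------------- collapse

def test_identical_sequences_one_haplotype():
    seqs = _records(["ACGT"] * 5)
    table = collapse(seqs)
    assert len(table) == 1
    assert table.haplotypes[0].total_count == 5


def test_collapse_matches_dictionary_oracle():
    strings = ["AAAA", "AAAT", "AAAA", "TTTT", "AAAT", "AAAA"]
    table = collapse(_records(strings))
    oracle = {s: strings.count(s) for s in set(strings)}
    assert {h.core_sequence: h.total_count for h in table.haplotypes} == oracle
    total = sum(h.total_count for h in table.haplotypes)
    assert total == len(strings)
    members = [m for h in table.haplotypes for m in h.members]
    assert len(members) == len(set(members)) == len(strings)


def test_collapse_counts_by_year_and_label_determinism():
    strings = ["AAAA", "AAAA", "TTTT"]
    metas = [
        SpecimenMeta("s0", 1, "matsumoto", 2010),
        SpecimenMeta("s1", 1, "matsumoto", 2020),
        SpecimenMeta("s2", 1, "matsumoto", 2020),
    ]
    table = collapse(_records(strings), metas)
    top = table.by_label("h1")
    assert top.count_by_year == {2010: 1, 2020: 1}
    # input order must not change labels or counts
    reordered = collapse(list(reversed(_records(strings))), metas)
    assert {
        (h.label, h.core_sequence, h.total_count) for h in table.haplotypes
    } == {
        (h.label, h.core_sequence, h.total_count) for h in reordered.haplotypes
    }


def test_collapse_haplogroup_prefixed_labels():
    refs = {
        "nigromaculatus": [SequenceRecord("nr", "cytb", "AAAAAA")],
        "porosus": [SequenceRecord("pr", "cytb", "TTTTTT")],
    }
    strings = ["AAAAAA", "AAAAAT", "TTTTTT"]
    used, masked = mask_and_trim(_records(strings))
    table = collapse(masked, [], refs=refs, used_positions=used)
    labels = {h.core_sequence: h.label for h in table.haplotypes}
    assert labels["AAAAAA"] == "n1"
    assert labels["AAAAAT"] == "n2"
    assert labels["TTTTTT"] == "p1"


# ---------------------------------------------------------- median joining

def test_two_haplotypes_single_edge():
    table = collapse(_records(["AAAA", "TTAA"]))
    net = median_joining(table)
    assert net.edges == (("h1", "h2", 2),)
    assert net.median_labels == frozenset()


def test_triangle_gains_median_vector():
    """Three haplotypes pairwise distance 2 whose consensus differs from
    all three: one median node, three unit edges, length 3 < MST's 4."""
    table = collapse(_records(["AAT", "ATA", "TAA"]))
    net = median_joining(table)
    assert len(net.median_labels) == 1
    (mv,) = net.median_labels
    assert net.nodes[mv] == "AAA"
    assert sorted(w for _, _, w in net.edges) == [1, 1, 1]
    assert net.total_length == 3


def test_epsilon_negative_rejected():
    table = collapse(_records(["AAAA"]))
    with pytest.raises(HaplonetError):
        median_joining(table, epsilon=-1)


def _brute_msn_edges(seqs):
    """Independent minimum-spanning-network oracle: an edge is included
    iff its endpoints are not connected by strictly shorter edges."""
    labels = sorted(seqs)
    edges = []
    for a, b in itertools.combinations(labels, 2):
        d = hamming(seqs[a], seqs[b])
        shorter = nx.Graph()
        shorter.add_nodes_from(labels)
        for u, v in itertools.combinations(labels, 2):
            if hamming(seqs[u], seqs[v]) < d:
                shorter.add_edge(u, v)
        if not nx.has_path(shorter, a, b):
            edges.append((a, b, d))
    return sorted(edges)


def test_path_instance_equals_minimum_spanning_network():
    """On collinear haplotypes every triplet consensus is an existing
    node (no applicable medians), so the network is exactly the MSN."""
    strings = ["AAAA", "AAAT", "AATT", "ATTT", "TTTT"]
    table = collapse(_records(strings))
    net = median_joining(table, epsilon=0)
    assert net.median_labels == frozenset()
    seqs = {h.label: h.core_sequence for h in table.haplotypes}
    assert sorted(net.edges) == _brute_msn_edges(seqs)


@pytest.mark.parametrize("seed", [3, 7])
def test_msn_oracle_on_random_instances(seed):
    """With epsilon=0 and no medians added, the final network over the
    final node set equals the brute-force MSN over those nodes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    strings = sorted(
        {"".join(rng.choice(list("AT"), size=6)) for _ in range(8)}
    )
    table = collapse(_records(strings))
    net = median_joining(table, epsilon=0)
    assert sorted(net.edges) == _brute_msn_edges(dict(net.nodes))


def test_three_haplogroup_clusters():
    """Deep between-group divergence, shallow within-group variation:
    the network splits into three clusters whose between-cluster edges
    outweigh every within-cluster edge."""
    core = {
        "n": "AAAAAAAAAAAAAAAA",
        "p": "TTTTTTTTAAAAAAAA",
        "b": "TTTTTTTTCCCCCCCC",
    }
    strings = []
    for central in core.values():
        strings.append(central)
        for pos in (14, 15):
            variant = list(central)
            variant[pos] = "G"
            strings.append("".join(variant))
    table = collapse(_records(strings))
    net = median_joining(table)
    graph = net.to_networkx()
    within = [
        (u, v) for u, v, d in graph.edges(data=True) if d["weight"] <= 2
    ]
    between = [
        d["weight"] for _, _, d in graph.edges(data=True) if d["weight"] > 2
    ]
    clusters = list(nx.connected_components(graph.edge_subgraph(within)))
    observed_clusters = [
        {n for n in c if n in net.nodes and not n.startswith("mv")}
        for c in clusters
    ]
    assert len([c for c in observed_clusters if c]) == 3
    assert min(between) > max(
        graph[u][v]["weight"] for u, v in within
    )


def test_network_contains_all_observed_and_total_length_bound():
    strings = ["AATT", "ATAT", "TAAT", "TTTT", "AAAA"]
    table = collapse(_records(strings))
    net = median_joining(table)
    for h in table.haplotypes:
        assert h.label in net.nodes
    # Steiner augmentation can only shorten the spanning length
    mst = nx.Graph()
    for a, b in itertools.combinations(range(len(strings)), 2):
        mst.add_edge(a, b, weight=hamming(strings[a], strings[b]))
    mst_weight = int(
        nx.minimum_spanning_tree(mst).size(weight="weight")
    )
    assert net.total_length <= mst_weight


def test_exports(tmp_path):
    table = collapse(_records(["AAT", "ATA", "TAA"]))
    net = median_joining(table)
    haplonet.write_table(table, tmp_path / "t.tsv")
    haplonet.write_gml(net, tmp_path / "n.gml")
    haplonet.write_edgelist(net, tmp_path / "e.tsv")
    reread = nx.read_gml(str(tmp_path / "n.gml"))
    assert set(reread.nodes) == set(net.nodes)
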