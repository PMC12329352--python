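"""mtDNA haplotype collapsing and median-joining networks.

``mask_and_trim`` applies the complete-deletion convention: any alignment
column containing a gap, an ``N`` or an ambiguity code in *any* sequence
is dropped for all sequences, leaving the unambiguous core region on
which haplotypes are compared (this is how a sequenced fragment reduces
to a shorter "available" region).

``collapse`` groups identical core sequences into haplotypes with
per-year counts and haplogroup-prefixed labels (``n1, n2, …`` for
*nigromaculatus*, ``p…``/``b…`` for the two *porosus* subspecies),
numbered by descending frequency.

``median_joining`` builds the haplotype network: starting from the
minimum spanning network (with relaxation ``epsilon``), consensus
(median/Steiner) vectors of mutually linked triplets are added whenever
they shorten the network, and median vectors that end up with fewer than
three links are pruned, iterating to a fixed point.  Median nodes stand
for unsampled intermediate haplotypes.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from hybridzone.genotype import assign_haplogroup
from hybridzone.seqio import SequenceRecord, SpecimenMeta

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "HaploNetwork",
    "HaplonetError",
    "hamming",
    "mask_and_trim",
    "collapse",
    "median_joining",
    "write_table",
    "write_gml",
    "write_edgelist",
]

_UNAMBIGUOUS = frozenset("ACGT")


class HaplonetError(ValueError):
    """Input cannot yield a haplotype table or network."""


def hamming(a: str, b: str) -> int:
    """Nucleotide differences between two equal-length core sequences."""
    if len(a) != len(b):
        raise HaplonetError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


@dataclasses.dataclass(frozen=True)
class Haplotype:
    label: str
    core_sequence: str
    members: tuple[str, ...]
    count_by_year: Mapping[int, int]
    haplogroup: str | None

    @property
    def total_count(self) -> int:
        return len(self.members)


@dataclasses.dataclass(frozen=True)
class HaplotypeTable:
    """Collapsed haplotypes over the retained (masked) positions."""

    used_positions: tuple[int, ...]
    haplotypes: tuple[Haplotype, ...]

    def __len__(self) -> int:
        return len(self.haplotypes)

    def by_label(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)


@dataclasses.dataclass(frozen=True)
class HaploNetwork:
    """Median-joining network: observed haplotypes plus inferred medians.

    ``nodes`` maps node label to core sequence; labels starting with the
    median prefix (``mv``) are inferred, unobserved intermediates.
    ``edges`` are (label_a, label_b, mutations) with labels sorted within
    each edge.  ``total_length`` is the parsimony length of the network —
    the weight of a spanning tree over all nodes (observed + medians),
    the quantity median vectors exist to minimise.
    """

    nodes: Mapping[str, str]
    median_labels: frozenset
    edges: tuple[tuple[str, str, int], ...]
    epsilon: int

    @property
    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.edges)

    @property
    def total_length(self) -> int:
        graph = self.to_networkx()
        mst = nx.minimum_spanning_tree(graph, weight="weight")
        return int(mst.size(weight="weight"))

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph(epsilon=self.epsilon)
        for label, seq in self.nodes.items():
            graph.add_node(
                label, sequence=seq, is_median=int(label in self.median_labels)
            )
        for a, b, w in self.edges:
            graph.add_edge(a, b, weight=w)
        return graph


def mask_and_trim(
    seqs: Sequence[SequenceRecord],
) -> tuple[tuple[int, ...], list[SequenceRecord]]:
    """Complete deletion: retain exactly the columns where every sequence
    has an unambiguous base.  Returns the retained 1-based positions and
    the masked sequences (in input order)."""
    if not seqs:
        raise HaplonetError("no sequences to mask")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise HaplonetError(f"unequal sequence lengths: {sorted(lengths)}")
    (length,) = lengths
    used = tuple(
        col + 1
        for col in range(length)
        if all(s.bases[col] in _UNAMBIGUOUS for s in seqs)
    )
    if not used:
        raise HaplonetError("no columns free of missing/ambiguous data")
    masked = [
        SequenceRecord(
            specimen_id=s.specimen_id,
            locus=s.locus,
            bases="".join(s.bases[p - 1] for p in used),
        )
        for s in seqs
    ]
    return used, masked


def _mask_to(seq: SequenceRecord, used: Sequence[int]) -> SequenceRecord:
    return SequenceRecord(
        specimen_id=seq.specimen_id,
        locus=seq.locus,
        bases="".join(seq.bases[p - 1] for p in used),
    )


def collapse(
    masked: Sequence[SequenceRecord],
    metas: Iterable[SpecimenMeta] = (),
    refs: Mapping[str, Sequence[SequenceRecord]] | None = None,
    used_positions: Sequence[int] | None = None,
) -> HaplotypeTable:
    """Collapse masked sequences into a haplotype table.

    Identical core sequences share one haplotype.  When mtDNA references
    are supplied (full-length; they are masked to ``used_positions``),
    each haplotype is assigned to the haplogroup of its nearest reference
    and labelled with the haplogroup's initial; otherwise labels use the
    neutral prefix ``h``.  Within a prefix, numbering is by descending
    total count, ties broken by the lexicographically smallest member id,
    so labels are independent of input order.
    """
    if not masked:
        raise HaplonetError("no sequences to collapse")
    year_of = {m.specimen_id: m.year for m in metas}
    groups: dict[str, list[str]] = {}
    for seq in masked:
        groups.setdefault(seq.bases, []).append(seq.specimen_id)

    masked_refs = None
    if refs is not None:
        if used_positions is None:
            raise HaplonetError("used_positions required to mask references")
        masked_refs = {
            taxon: [_mask_to(r, used_positions) for r in taxon_refs]
            for taxon, taxon_refs in refs.items()
        }

    entries = []
    for core, members in groups.items():
        haplogroup = None
        if masked_refs is not None:
            probe = SequenceRecord(
                specimen_id=min(members), locus=masked[0].locus, bases=core
            )
            haplogroup = assign_haplogroup(probe, masked_refs).haplogroup
        entries.append((core, sorted(members), haplogroup))

    # frequency order then smallest member id, numbered within each prefix
    entries.sort(key=lambda e: (-len(e[1]), e[1][0]))
    counters: dict[str, int] = {}
    haplotypes = []
    for core, members, haplogroup in entries:
        prefix = haplogroup[0] if haplogroup else "h"
        counters[prefix] = counters.get(prefix, 0) + 1
        count_by_year: dict[int, int] = {}
        for member in members:
            year = year_of.get(member)
            if year is not None:
                count_by_year[year] = count_by_year.get(year, 0) + 1
        haplotypes.append(
            Haplotype(
                label=f"{prefix}{counters[prefix]}",
                core_sequence=core,
                members=tuple(members),
                count_by_year=count_by_year,
                haplogroup=haplogroup,
            )
        )
    return HaplotypeTable(
        used_positions=tuple(used_positions or range(1, len(masked[0]) + 1)),
        haplotypes=tuple(haplotypes),
    )


def _msn_edges(
    nodes: Mapping[str, str], epsilon: int
) -> list[tuple[str, str, int]]:
    """Minimum spanning network with relaxation epsilon: an edge (u, v) is
    included iff d(u, v) <= bottleneck(u, v) + epsilon, where bottleneck is
    the minimax path distance (largest MST edge on the u-v path).  With
    epsilon 0 this is the union of all minimum spanning trees."""
    labels = sorted(nodes)
    if len(labels) == 1:
        return []
    complete = nx.Graph()
    for a, b in itertools.combinations(labels, 2):
        complete.add_edge(a, b, weight=hamming(nodes[a], nodes[b]))
    mst = nx.minimum_spanning_tree(complete, weight="weight")
    edges = []
    for a, b in itertools.combinations(labels, 2):
        d = complete[a][b]["weight"]
        path = nx.shortest_path(mst, a, b)
        bottleneck = max(
            mst[u][v]["weight"] for u, v in zip(path, path[1:])
        )
        if d <= bottleneck + epsilon:
            edges.append((a, b, d))
    return edges


def _median_sequence(seqs: tuple[str, str, str], order: tuple[str, ...]) -> str:
    """Per-column majority consensus of three sequences; a three-way tie
    takes the base of the first sequence in ``order`` (deterministic)."""
    out = []
    for column in zip(*seqs):
        counts: dict[str, int] = {}
        for base in column:
            counts[base] = counts.get(base, 0) + 1
        best = max(counts.values())
        if best >= 2:
            out.append(next(b for b in column if counts[b] == best))
        else:
            out.append(column[0])
    return "".join(out)


def median_joining(table: HaplotypeTable, epsilon: int = 0) -> HaploNetwork:
    """Build the median-joining network of a haplotype table.

    Iterates: (1) form the minimum spanning network over the current
    nodes with relaxation ``epsilon``; (2) for every mutually linked
    triplet, compute its consensus (median) vector and add it if doing so
    shortens the network's spanning-tree length; (3) prune median nodes
    with fewer than three links; until nothing changes.  Edge weights are
    nucleotide differences.
    """
    if epsilon < 0:
        raise HaplonetError("epsilon must be >= 0")
    if not table.haplotypes:
        raise HaplonetError("empty haplotype table")
    nodes: dict[str, str] = {
        h.label: h.core_sequence for h in table.haplotypes
    }
    observed = set(nodes)
    mv_count = 0

    def spanning_length(node_map: Mapping[str, str]) -> int:
        if len(node_map) == 1:
            return 0
        g = nx.Graph()
        for a, b in itertools.combinations(sorted(node_map), 2):
            g.add_edge(a, b, weight=hamming(node_map[a], node_map[b]))
        return int(
            nx.minimum_spanning_tree(g, weight="weight").size(weight="weight")
        )

    for _ in range(100):
        changed = False
        edges = _msn_edges(nodes, epsilon)
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        graph.add_weighted_edges_from(edges)

        # candidate medians from mutually linked triplets, deterministic order
        existing = set(nodes.values())
        candidates: list[tuple[str, str]] = []
        for u, v, w in (
            t for t in itertools.combinations(sorted(nodes), 3)
        ):
            if not (
                graph.has_edge(u, v)
                and graph.has_edge(v, w)
                and graph.has_edge(u, w)
            ):
                continue
            median = _median_sequence(
                (nodes[u], nodes[v], nodes[w]), (u, v, w)
            )
            if median not in existing:
                candidates.append((median, f"{u}|{v}|{w}"))
        candidates.sort(key=lambda c: (c[1], c[0]))

        base_length = spanning_length(nodes)
        for median, _origin in candidates:
            if median in set(nodes.values()):
                continue
            trial = dict(nodes)
            trial[f"mv{mv_count + 1}"] = median
            if spanning_length(trial) < base_length:
                mv_count += 1
                nodes[f"mv{mv_count}"] = median
                base_length = spanning_length(nodes)
                changed = True

        # prune medians with fewer than three links (cascade)
        while True:
            edges = _msn_edges(nodes, epsilon)
            degree: dict[str, int] = {label: 0 for label in nodes}
            for a, b, _ in edges:
                degree[a] += 1
                degree[b] += 1
            prune = [
                label
                for label in sorted(nodes)
                if label not in observed and degree[label] < 3
            ]
            if not prune:
                break
            for label in prune:
                del nodes[label]
            changed = True

        if not changed:
            break

    final_edges = tuple(
        (a, b, w) for a, b, w in sorted(_msn_edges(nodes, epsilon))
    )
    return HaploNetwork(
        nodes=dict(sorted(nodes.items())),
        median_labels=frozenset(set(nodes) - observed),
        edges=final_edges,
        epsilon=epsilon,
    )


def write_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write the haplotype table as tab-separated text."""
    years = sorted({y for h in table.haplotypes for y in h.count_by_year})
    rows = []
    for h in table.haplotypes:
        rows.append(
            {
                "label": h.label,
                "haplogroup": h.haplogroup or "unassigned",
                "total": h.total_count,
                **{f"n_{y}": h.count_by_year.get(y, 0) for y in years},
                "members": ",".join(h.members),
                "core_sequence": h.core_sequence,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gml(network: HaploNetwork, path: str | Path) -> None:
    """Export the network as GML."""
    nx.write_gml(network.to_networkx(), str(path))


def write_edgelist(network: HaploNetwork, path: str | Path) -> None:
    """Export the network as a plain edge list with median flags."""
    rows = [
        {
            "node_a": a,
            "node_b": b,
            "mutations": w,
            "a_is_median": int(a in network.median_labels),
            "b_is_median": int(b in network.median_labels),
        }
        for a, b, w in network.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
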