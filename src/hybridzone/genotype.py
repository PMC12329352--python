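"""Per-specimen genotype calling.

Nuclear calls decode each diagnostic-panel position of a Tyrosinase
sequence: an unambiguous base is a homozygote, a two-base IUPAC code
(Sanger double peak) is a heterozygote, and N/gap/three-four-base codes
are missing.  The per-site genotypes are then summarised against the
panel's taxon alleles:

``hom``
    every informative site carries one taxon's allele homozygously (the
    summary lists every taxon compatible with the observed sites — more
    than one only when the readable sites cannot separate subspecies);
``het``
    at least one diagnostic site is heterozygous with the two bases
    matching two different taxa — the double-peak signature of mixed
    ancestry; the reported pair is the two-taxon model most consistent
    with all informative sites;
``novel``
    some informative base matches no taxon's allele (likely sequencing
    artifact — never counted as hybrid evidence), or the homozygous
    site pattern fits no single taxon and no heterozygous pair;
``insufficient``
    fewer than ``min_informative`` panel sites are readable.

mtDNA haplogroup assignment is nearest-reference Hamming distance over
mutually unambiguous positions, left unassigned on ties across taxa.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from hybridzone.seqio import IUPAC_DOUBLE, SequenceRecord
from hybridzone.panel import DiagnosticPanel

__all__ = [
    "Genotype",
    "CallSummary",
    "NuclearCall",
    "MtAssignment",
    "GenotypeError",
    "species_of",
    "decode_symbol",
    "call_nuclear",
    "assign_haplogroup",
    "write_calls",
]

_UNAMBIGUOUS = frozenset("ACGT")

#: an unordered base pair (homozygous pairs repeat the base), or None when
#: the position is missing
Genotype = tuple


class GenotypeError(ValueError):
    """Sequence cannot be genotyped against the given panel/references."""


def species_of(taxon: str) -> str:
    """Collapse subspecies to their species: the two *porosus* subspecies
    map to ``porosus``; every other label maps to itself."""
    return "porosus" if taxon in ("porosus", "brevipodus") else taxon


def decode_symbol(symbol: str) -> Genotype | None:
    """Decode one IUPAC symbol into an unordered base pair, or None if the
    symbol carries no genotype (N, gap, three/four-base codes)."""
    if symbol in _UNAMBIGUOUS:
        return (symbol, symbol)
    pair = IUPAC_DOUBLE.get(symbol)
    if pair is not None:
        return tuple(sorted(pair))
    return None


@dataclasses.dataclass(frozen=True)
class CallSummary:
    """Summary genotype class plus the taxa it implicates."""

    kind: str  # hom | het | novel | insufficient
    taxa: tuple[str, ...] = ()

    @property
    def is_het(self) -> bool:
        return self.kind == "het"

    @property
    def is_species_level_het(self) -> bool:
        """True when the heterozygous pair spans the two species (as
        opposed to the two subspecies of one species)."""
        return self.kind == "het" and len({species_of(t) for t in self.taxa}) > 1

    def __str__(self) -> str:
        if self.taxa:
            return f"{self.kind}({','.join(self.taxa)})"
        return self.kind


@dataclasses.dataclass(frozen=True)
class NuclearCall:
    """Genotype call of one specimen's nuclear sequence against a panel."""

    specimen_id: str
    site_genotypes: Mapping[int, Genotype | None]
    summary: CallSummary
    n_informative: int


@dataclasses.dataclass(frozen=True)
class MtAssignment:
    """Nearest-haplogroup assignment of one mtDNA sequence."""

    specimen_id: str
    haplogroup: str | None
    nearest_distance: int
    margin: int


def _pair_consistent(
    genotype: Genotype, allele_a: str, allele_b: str
) -> bool:
    """Would an individual carrying one ``allele_a``-taxon copy and one
    ``allele_b``-taxon copy show this genotype at the site?"""
    return tuple(sorted((allele_a, allele_b))) == genotype


def call_nuclear(
    seq: SequenceRecord,
    panel: DiagnosticPanel,
    min_informative: int = 5,
) -> NuclearCall:
    """Call a nuclear sequence at every panel position and summarise.

    ``min_informative`` is the minimum number of readable (non-missing)
    panel sites required before any call is made; below it the summary is
    ``insufficient``.
    """
    if len(seq) != panel.locus_length:
        raise GenotypeError(
            f"sequence {seq.specimen_id!r} length {len(seq)} != panel locus "
            f"length {panel.locus_length}"
        )
    genotypes: dict[int, Genotype | None] = {
        site.position: decode_symbol(seq.bases[site.position - 1])
        for site in panel.sites
    }
    informative = {p: g for p, g in genotypes.items() if g is not None}
    n_inf = len(informative)

    def call(summary: CallSummary) -> NuclearCall:
        return NuclearCall(
            specimen_id=seq.specimen_id,
            site_genotypes=genotypes,
            summary=summary,
            n_informative=n_inf,
        )

    if n_inf < min_informative:
        return call(CallSummary("insufficient"))

    # any observed base outside the site's allele set -> novel, never het
    for pos, genotype in informative.items():
        allowed = set(panel.alleles_at(pos).values())
        if not set(genotype) <= allowed:
            return call(CallSummary("novel"))

    het_sites = [p for p, g in informative.items() if g[0] != g[1]]
    if het_sites:
        # two distinct bases at a diagnostic site always separate two taxa
        # (each taxon is fixed for a single base there); report the
        # two-taxon model consistent with the most informative sites
        best_pair, best_score = None, -1
        for a, b in itertools.combinations(panel.taxa, 2):
            score = sum(
                _pair_consistent(
                    g, panel.alleles_at(p)[a], panel.alleles_at(p)[b]
                )
                for p, g in informative.items()
            )
            het_support = any(
                _pair_consistent(
                    informative[p], panel.alleles_at(p)[a], panel.alleles_at(p)[b]
                )
                and informative[p][0] != informative[p][1]
                for p in het_sites
            )
            if het_support and score > best_score:
                best_pair, best_score = (a, b), score
        if best_pair is None:
            return call(CallSummary("novel"))
        return call(CallSummary("het", best_pair))

    matching = tuple(
        t
        for t in panel.taxa
        if all(
            g == (panel.alleles_at(p)[t],) * 2 for p, g in informative.items()
        )
    )
    if not matching:
        # homozygous mosaic: each base known, but no single taxon fits
        return call(CallSummary("novel"))
    return call(CallSummary("hom", matching))


def assign_haplogroup(
    seq: SequenceRecord,
    refs: Mapping[str, Sequence[SequenceRecord]],
) -> MtAssignment:
    """Assign an mtDNA sequence to the taxon of its nearest reference.

    Distance is the Hamming count over positions where both query and
    reference are unambiguous (A/C/G/T).  The margin is the distance to
    the closest *other* taxon minus the nearest distance; on a tie across
    taxa (margin 0) the haplogroup is left unassigned.
    """
    if not refs or not any(refs.values()):
        raise GenotypeError("no mtDNA references supplied")
    per_taxon: dict[str, int] = {}
    for taxon, records in refs.items():
        best = None
        for ref in records:
            if len(ref) != len(seq):
                raise GenotypeError(
                    f"reference {ref.specimen_id!r} length {len(ref)} != "
                    f"query length {len(seq)}"
                )
            comparable = 0
            mismatches = 0
            for q, r in zip(seq.bases, ref.bases):
                if q in _UNAMBIGUOUS and r in _UNAMBIGUOUS:
                    comparable += 1
                    if q != r:
                        mismatches += 1
            if comparable == 0:
                raise GenotypeError(
                    f"no comparable positions between {seq.specimen_id!r} "
                    f"and reference {ref.specimen_id!r}"
                )
            if best is None or mismatches < best:
                best = mismatches
        if best is not None:
            per_taxon[taxon] = best
    ranked = sorted(per_taxon.items(), key=lambda item: (item[1], item[0]))
    nearest_taxon, nearest = ranked[0]
    margin = (ranked[1][1] - nearest) if len(ranked) > 1 else 0
    return MtAssignment(
        specimen_id=seq.specimen_id,
        haplogroup=nearest_taxon if margin > 0 else None,
        nearest_distance=nearest,
        margin=margin,
    )


def write_calls(calls: Iterable[NuclearCall], path: str | Path) -> None:
    """Write nuclear calls as a tab-separated table, one specimen per row."""
    rows = []
    for c in calls:
        rows.append(
            {
                "specimen_id": c.specimen_id,
                "locus": "tyr",
                "summary": str(c.summary),
                "n_informative": c.n_informative,
                **{
                    f"pos{p}": ("/".join(g) if g else ".")
                    for p, g in sorted(c.site_genotypes.items())
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
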