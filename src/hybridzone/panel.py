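"""Discovery of species/subspecies-diagnostic nucleotide sites.

A site is *diagnostic* when every reference sequence within each taxon
carries the same unambiguous base and at least two taxa differ.  Reference
sequences must be free of ambiguity codes (no Sanger double peaks): a
heterozygous reference cannot certify within-taxon fixation, so such input
is rejected rather than silently skipped.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from hybridzone.seqio import (
    MISSING_SYMBOLS,
    AlignmentError,
    SequenceRecord,
)

__all__ = [
    "DiagnosticSite",
    "DiagnosticPanel",
    "PanelError",
    "find_diagnostic_sites",
    "pairwise_diff_positions",
    "read_panel",
    "write_panel",
]

_UNAMBIGUOUS = frozenset("ACGT")


class PanelError(ValueError):
    """Reference input cannot support diagnostic-site discovery."""


@dataclasses.dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic alignment column: 1-based position and the fixed base
    of every taxon there."""

    position: int
    alleles: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.alleles.values())) < 2:
            raise PanelError(
                f"site {self.position}: all taxa share one base; not diagnostic"
            )
        for taxon, base in self.alleles.items():
            if base not in _UNAMBIGUOUS:
                raise PanelError(
                    f"site {self.position}: taxon {taxon!r} has non-ACGT "
                    f"allele {base!r}"
                )


@dataclasses.dataclass(frozen=True)
class DiagnosticPanel:
    """Ordered collection of diagnostic sites for one locus."""

    locus: str
    locus_length: int
    taxa: tuple[str, ...]
    sites: tuple[DiagnosticSite, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(
            self, "sites", tuple(sorted(self.sites, key=lambda s: s.position))
        )
        for site in self.sites:
            if not 1 <= site.position <= self.locus_length:
                raise PanelError(
                    f"site position {site.position} outside locus length "
                    f"{self.locus_length}"
                )
            if set(site.alleles) != set(self.taxa):
                raise PanelError(
                    f"site {site.position}: allele map taxa "
                    f"{sorted(site.alleles)} != panel taxa {sorted(self.taxa)}"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(site.position for site in self.sites)

    def alleles_at(self, position: int) -> Mapping[str, str]:
        for site in self.sites:
            if site.position == position:
                return site.alleles
        raise KeyError(position)


def find_diagnostic_sites(
    refs: Mapping[str, Sequence[SequenceRecord]],
    min_per_taxon: int = 2,
    locus: str = "tyr",
) -> DiagnosticPanel:
    """Scan reference alignments per taxon for diagnostic sites.

    Parameters
    ----------
    refs
        Map taxon label -> reference sequences without ambiguity codes.
        All sequences (across taxa) must share one length.
    min_per_taxon
        Minimum number of references per taxon; a single sequence cannot
        demonstrate within-taxon fixation, hence the default of 2.

    Returns the panel of positions where (a) each taxon is internally
    fixed for one unambiguous base and (b) at least two taxa differ.
    Columns with any gap/N (missing data cannot certify fixation) or any
    within-taxon polymorphism are excluded.
    """
    if not refs:
        raise PanelError("no reference taxa supplied")
    taxa = tuple(refs)
    all_records: list[SequenceRecord] = []
    for taxon, records in refs.items():
        if len(records) < min_per_taxon:
            raise PanelError(
                f"taxon {taxon!r}: {len(records)} reference(s) < "
                f"min_per_taxon={min_per_taxon}"
            )
        for rec in records:
            bad = [
                (i + 1, c)
                for i, c in enumerate(rec.bases)
                if c not in _UNAMBIGUOUS
            ]
            if bad:
                pos, sym = bad[0]
                raise PanelError(
                    f"reference {rec.specimen_id!r} ({taxon}) carries "
                    f"ambiguity/missing symbol {sym!r} at position {pos}; "
                    "references must be free of double peaks"
                )
        all_records.extend(records)
    lengths = {len(rec) for rec in all_records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"reference sequences have unequal lengths: {sorted(lengths)}"
        )
    (length,) = lengths

    sites: list[DiagnosticSite] = []
    for col in range(length):
        fixed: dict[str, str] = {}
        for taxon in taxa:
            bases = {rec.bases[col] for rec in refs[taxon]}
            if len(bases) != 1:
                break  # within-taxon polymorphism: never diagnostic
            fixed[taxon] = next(iter(bases))
        else:
            if len(set(fixed.values())) >= 2:
                sites.append(DiagnosticSite(position=col + 1, alleles=fixed))
    return DiagnosticPanel(
        locus=locus, locus_length=length, taxa=taxa, sites=tuple(sites)
    )


def pairwise_diff_positions(
    panel: DiagnosticPanel, taxon_a: str, taxon_b: str
) -> tuple[int, ...]:
    """Positions where two taxa's panel alleles differ, in ascending order."""
    for taxon in (taxon_a, taxon_b):
        if taxon not in panel.taxa:
            raise PanelError(f"taxon {taxon!r} not in panel taxa {panel.taxa}")
    return tuple(
        site.position
        for site in panel.sites
        if site.alleles[taxon_a] != site.alleles[taxon_b]
    )


def write_panel(panel: DiagnosticPanel, path: str | Path) -> None:
    """Serialise a panel as a tab-separated table (position, one column
    per taxon), with locus and length on comment lines."""
    frame = pd.DataFrame(
        [
            {"position": site.position, **{t: site.alleles[t] for t in panel.taxa}}
            for site in panel.sites
        ],
        columns=["position", *panel.taxa],
    )
    with open(path, "w") as handle:
        handle.write(f"# locus={panel.locus}\tlength={panel.locus_length}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_panel(path: str | Path) -> DiagnosticPanel:
    """Read a panel written by :func:`write_panel`."""
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#"):
            raise PanelError("panel file missing '# locus=...' header line")
        fields = dict(
            part.split("=", 1) for part in header.lstrip("# ").strip().split("\t")
        )
        frame = pd.read_csv(handle, sep="\t")
    taxa = tuple(c for c in frame.columns if c != "position")
    sites = tuple(
        DiagnosticSite(
            position=int(row["position"]),
            alleles={t: str(row[t]) for t in taxa},
        )
        for _, row in frame.iterrows()
    )
    return DiagnosticPanel(
        locus=fields["locus"],
        locus_length=int(fields["length"]),
        taxa=taxa,
        sites=sites,
    )
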