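"""Integrative pure-bred/hybrid classification.

A specimen is classified from up to three evidence channels — morphology
(field identification), mtDNA haplogroup (maternal lineage) and the
nuclear diagnostic-site genotype — applying, in order:

1. a species-level heterozygous nuclear call (double peaks pairing the
   two species' alleles) is direct hybrid evidence;
2. a homozygous nuclear call whose species disagrees with the mtDNA
   species is mito-nuclear discordance, hence hybrid ancestry;
3. hybrid morphology, or morphology contradicting the genetic species,
   is likewise discordance;
4. otherwise, if every available channel names the same single species,
   the specimen is pure-bred (the subspecies of pure *porosus* specimens
   is taken from the nuclear subspecies-diagnostic sites first, falling
   back to the mtDNA haplogroup);
5. anything else is unresolved.

The rule set is deliberately conservative: classification as hybrid
requires positive evidence (heterozygosity or discordance), so hybrid
counts are under- rather than over-estimates.  Heterozygosity between
the two *porosus* subspecies is species-concordant and never enters the
hybrid class; it is surfaced via the ``subspecies_het`` flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from hybridzone.genotype import (
    MtAssignment,
    NuclearCall,
    assign_haplogroup,
    call_nuclear,
    species_of,
)
from hybridzone.panel import DiagnosticPanel
from hybridzone.seqio import Dataset, SequenceRecord, SpecimenMeta

__all__ = [
    "ClassifiedSpecimen",
    "classify_specimen",
    "classify_dataset",
    "write_classification",
    "marginal_summary",
]

#: morphology code -> species it names (H and missing name none)
_MORPH_SPECIES = {"N": "nigromaculatus", "P": "porosus", "B": "porosus"}

#: morphology code -> the subspecies-level taxon it suggests
_MORPH_TAXON = {"N": "nigromaculatus", "P": "porosus", "B": "brevipodus"}

_PURE_CLASS = {"nigromaculatus": "pure_N", "porosus": "pure_P", "brevipodus": "pure_B"}


@dataclasses.dataclass(frozen=True)
class ClassifiedSpecimen:
    specimen_id: str
    morphology: str
    mt_taxon: str | None
    nuclear_summary: str
    final_class: str  # pure_N | pure_P | pure_B | hybrid | unresolved
    evidence: str  # heterozygous | discordant | concordant | incomplete
    subspecies_het: bool = False
    site_id: int | None = None
    basin: str | None = None
    year: int | None = None


def classify_specimen(
    morphology: str,
    mt: MtAssignment | None,
    nuc: NuclearCall | None,
    meta: SpecimenMeta | None = None,
) -> ClassifiedSpecimen:
    """Apply the integrative classification rules to one specimen.

    At least one genetic channel (``mt`` or ``nuc``) must be supplied;
    degenerate inputs route to ``unresolved`` rather than raising.
    """
    specimen_id = (
        meta.specimen_id
        if meta is not None
        else (mt.specimen_id if mt else nuc.specimen_id)  # type: ignore[union-attr]
    )

    def result(final_class: str, evidence: str, subspecies_het: bool = False):
        return ClassifiedSpecimen(
            specimen_id=specimen_id,
            morphology=morphology,
            mt_taxon=mt.haplogroup if mt else None,
            nuclear_summary=str(nuc.summary) if nuc else "absent",
            final_class=final_class,
            evidence=evidence,
            subspecies_het=subspecies_het,
            site_id=meta.site_id if meta else None,
            basin=meta.basin if meta else None,
            year=meta.year if meta else None,
        )

    summary = nuc.summary if nuc is not None else None
    nuclear_usable = summary is not None and summary.kind in ("hom", "het")
    subspecies_het = bool(
        summary is not None and summary.is_het and not summary.is_species_level_het
    )

    # nuclear species: single species implied by hom taxa, or the shared
    # species of a subspecies-level het pair
    nuc_species: str | None = None
    if nuclear_usable:
        species_set = {species_of(t) for t in summary.taxa}
        if len(species_set) == 1:
            nuc_species = next(iter(species_set))

    mt_taxon = mt.haplogroup if mt is not None else None
    mt_species = species_of(mt_taxon) if mt_taxon else None
    morph_species = _MORPH_SPECIES.get(morphology)

    # 1. species-level double peaks
    if summary is not None and summary.is_species_level_het:
        return result("hybrid", "heterozygous")

    # 2. mito-nuclear discordance
    if (
        summary is not None
        and summary.kind == "hom"
        and nuc_species is not None
        and mt_species is not None
        and nuc_species != mt_species
    ):
        return result("hybrid", "discordant")

    # 3. morphology-based discordance
    genetic_species = [s for s in (nuc_species, mt_species) if s is not None]
    if morphology == "H" and genetic_species:
        return result("hybrid", "discordant")
    if morph_species is not None and any(
        morph_species != s for s in genetic_species
    ):
        return result("hybrid", "discordant")

    # 4. full concordance on one species
    available = set(genetic_species)
    if morph_species is not None:
        available.add(morph_species)
    if len(available) == 1 and genetic_species:
        species = next(iter(available))
        if species != "porosus":
            return result(
                _PURE_CLASS.get(species, "unresolved"),
                "concordant" if species in _PURE_CLASS else "incomplete",
            )
        # resolve the porosus subspecies: nuclear first, then mtDNA
        subspecies: str | None = None
        if summary is not None and summary.kind == "hom":
            sub_taxa = [t for t in summary.taxa if t in ("porosus", "brevipodus")]
            if len(sub_taxa) == 1:
                subspecies = sub_taxa[0]
        if subspecies is None and mt_taxon in ("porosus", "brevipodus"):
            subspecies = mt_taxon
        if subspecies is None and morphology in ("P", "B"):
            subspecies = _MORPH_TAXON[morphology]
        if subspecies is None:
            return result("unresolved", "incomplete", subspecies_het)
        return result(_PURE_CLASS[subspecies], "concordant", subspecies_het)

    # 5. insufficient or conflicting-but-unusable evidence
    return result("unresolved", "incomplete", subspecies_het)


def classify_dataset(
    dataset: Dataset,
    panel: DiagnosticPanel,
    refs: Mapping[str, Sequence[SequenceRecord]],
    min_informative: int = 5,
) -> list[ClassifiedSpecimen]:
    """Genotype and classify every specimen of a joined dataset.

    ``refs`` are the full-length mtDNA reference haplotypes per taxon.
    Specimens lacking a locus are classified from the remaining channels.
    """
    classified = []
    for bundle in dataset.values():
        nuc = (
            call_nuclear(bundle.tyr, panel, min_informative=min_informative)
            if bundle.tyr is not None
            else None
        )
        mt = (
            assign_haplogroup(bundle.cytb, refs)
            if bundle.cytb is not None
            else None
        )
        classified.append(
            classify_specimen(bundle.meta.morphology, mt, nuc, meta=bundle.meta)
        )
    return classified


def write_classification(
    classified: Iterable[ClassifiedSpecimen], path: str | Path
) -> None:
    """Write the per-specimen classification as tab-separated text."""
    frame = pd.DataFrame([dataclasses.asdict(c) for c in classified])
    frame.to_csv(path, sep="\t", index=False)


def marginal_summary(
    classified: Sequence[ClassifiedSpecimen],
) -> pd.DataFrame:
    """Per-site marginal counts in the survey-table layout: morphology
    N/P/B/H, mtDNA N/P/B, nuclear N/P/B/H (nuclear H = species-level
    heterozygote)."""
    rows: dict[tuple, dict[str, int]] = {}
    for c in classified:
        key = (c.basin, c.site_id)
        row = rows.setdefault(
            key,
            {
                "basin": c.basin,
                "site_id": c.site_id,
                "n": 0,
                **{f"morph_{x}": 0 for x in "NPBH"},
                **{f"mt_{x}": 0 for x in "NPB"},
                **{f"nuc_{x}": 0 for x in "NPBH"},
            },
        )
        row["n"] += 1
        if c.morphology in "NPBH":
            row[f"morph_{c.morphology}"] += 1
        if c.mt_taxon:
            row[f"mt_{c.mt_taxon[0].upper()}"] += 1
        if c.nuclear_summary.startswith("hom(") and "," not in c.nuclear_summary:
            row[f"nuc_{c.nuclear_summary[4].upper()}"] += 1
        elif c.nuclear_summary.startswith("het(") and c.evidence == "heterozygous":
            row["nuc_H"] += 1
    return pd.DataFrame(
        sorted(rows.values(), key=lambda r: (str(r["basin"]), r["site_id"] or 0))
    )
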