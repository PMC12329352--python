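"""Aligned-sequence and specimen-metadata IO.

Sequences are pre-aligned, equal-length nucleotide strings per locus
(mtDNA Cyt-b, nuclear Tyrosinase) over the IUPAC alphabet.  Two-base
ambiguity codes (R/Y/S/W/K/M) are the textual encoding of Sanger
chromatogram double peaks, i.e. heterozygous positions; three/four-base
codes, ``N`` and the gap symbol carry no genotype information and are
treated as missing data downstream.

Metadata is a tab-separated table with a header and the columns
``specimen_id``, ``site_id``, ``basin``, ``year``, ``morphology``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "SpecimenMeta",
    "SpecimenBundle",
    "Dataset",
    "AlignmentError",
    "AlphabetError",
    "MetadataError",
    "IUPAC_DOUBLE",
    "IUPAC_TO_BASES",
    "MISSING_SYMBOLS",
    "LOCI",
    "BASINS",
    "MORPHOLOGY_CODES",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "join_dataset",
]

#: canonical locus names
LOCI = ("cytb", "tyr")

#: recognised basin labels for study data (synthetic data may add more)
BASINS = ("matsumoto", "ina", "saigawa")

#: morphology field codes: the two species, the two subspecies of the second,
#: morphological hybrid, or not recorded
MORPHOLOGY_CODES = ("N", "P", "B", "H", "missing")

#: two-base IUPAC ambiguity codes — the encoding of Sanger double peaks
IUPAC_DOUBLE: Mapping[str, frozenset] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

#: every IUPAC nucleotide symbol mapped to its base set
IUPAC_TO_BASES: Mapping[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    **IUPAC_DOUBLE,
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

#: symbols that never carry genotype information at a site
MISSING_SYMBOLS = frozenset("BDHVN-")

_VALID_SYMBOLS = frozenset(IUPAC_TO_BASES)


class AlignmentError(ValueError):
    """Records of one locus do not form an equal-length alignment."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


class MetadataError(ValueError):
    """The specimen metadata table violates its contract."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence of one specimen at one locus."""

    specimen_id: str
    locus: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = [
            (i + 1, c) for i, c in enumerate(self.bases) if c not in _VALID_SYMBOLS
        ]
        if bad:
            pos, sym = bad[0]
            raise AlphabetError(
                f"record {self.specimen_id!r} ({self.locus}): illegal symbol "
                f"{sym!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass(frozen=True)
class SpecimenMeta:
    """Per-specimen metadata row."""

    specimen_id: str
    site_id: int
    basin: str
    year: int
    morphology: str = "missing"

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGY_CODES:
            object.__setattr__(self, "morphology", "missing")


@dataclasses.dataclass(frozen=True)
class SpecimenBundle:
    """A specimen's metadata joined with its (optional) sequences per locus."""

    meta: SpecimenMeta
    cytb: SequenceRecord | None = None
    tyr: SequenceRecord | None = None

    @property
    def missing_loci(self) -> tuple[str, ...]:
        return tuple(
            locus for locus in LOCI if getattr(self, locus) is None
        )


#: a joined dataset: specimen id -> bundle, insertion-ordered by metadata
Dataset = dict


def _check_equal_lengths(records: Sequence[SequenceRecord]) -> None:
    if not records:
        return
    ref_len = len(records[0])
    for rec in records[1:]:
        if len(rec) != ref_len:
            raise AlignmentError(
                f"record {rec.specimen_id!r}: length {len(rec)} differs from "
                f"alignment length {ref_len}"
            )


def read_alignment(path: str | Path, locus: str) -> list[SequenceRecord]:
    """Read an aligned FASTA file into validated :class:`SequenceRecord`s.

    All sequences must share one length; order is preserved.  Raises
    :class:`AlignmentError` on a length mismatch (naming the offending
    record) and :class:`AlphabetError` on an illegal symbol.
    """
    records = [
        SequenceRecord(specimen_id=rec.id, locus=locus, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_equal_lengths(records)
    return records


def write_alignment(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    seq_records = [
        SeqRecord(Seq(rec.bases), id=rec.specimen_id, description="")
        for rec in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(seq_records)


_META_COLUMNS = ["specimen_id", "site_id", "basin", "year", "morphology"]


def read_metadata(path: str | Path) -> list[SpecimenMeta]:
    """Read the tab-separated specimen metadata table.

    Unknown morphology strings are coded ``missing``.  Raises
    :class:`MetadataError` on duplicated specimen ids, on a missing
    required column, or when one site id maps to more than one basin.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("missing")
    missing_cols = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise MetadataError(f"missing required columns: {missing_cols}")
    dupes = frame["specimen_id"][frame["specimen_id"].duplicated()].tolist()
    if dupes:
        raise MetadataError(f"duplicate specimen ids: {sorted(set(dupes))}")
    site_basins: dict[int, str] = {}
    metas = []
    for row in frame.itertuples(index=False):
        try:
            site_id = int(row.site_id)
            year = int(row.year)
        except ValueError as exc:
            raise MetadataError(
                f"specimen {row.specimen_id!r}: non-integer site_id/year"
            ) from exc
        prev = site_basins.setdefault(site_id, row.basin)
        if prev != row.basin:
            raise MetadataError(
                f"site {site_id} mapped to two basins: {prev!r} and {row.basin!r}"
            )
        metas.append(
            SpecimenMeta(
                specimen_id=row.specimen_id,
                site_id=site_id,
                basin=row.basin,
                year=year,
                morphology=row.morphology,
            )
        )
    return metas


def write_metadata(metas: Iterable[SpecimenMeta], path: str | Path) -> None:
    """Write metadata as the canonical tab-separated table."""
    frame = pd.DataFrame(
        [dataclasses.asdict(m) for m in metas], columns=_META_COLUMNS
    )
    frame.to_csv(path, sep="\t", index=False)


def join_dataset(
    seqs: Iterable[SequenceRecord], metas: Iterable[SpecimenMeta]
) -> Dataset:
    """Join sequences to metadata into per-specimen bundles.

    Every sequence's specimen id must appear in the metadata; orphan
    sequences raise :class:`MetadataError` listing the ids.  Specimens may
    lack either locus — the bundle's ``missing_loci`` records which.
    """
    metas = list(metas)
    by_id = {m.specimen_id: {"meta": m} for m in metas}
    if len(by_id) != len(metas):
        raise MetadataError("duplicate specimen ids in metadata")
    orphans = []
    for rec in seqs:
        slot = by_id.get(rec.specimen_id)
        if slot is None:
            orphans.append(rec.specimen_id)
            continue
        if rec.locus not in LOCI:
            raise AlignmentError(f"unknown locus {rec.locus!r}")
        slot[rec.locus] = rec
    if orphans:
        raise MetadataError(f"sequences without metadata: {sorted(set(orphans))}")
    return {
        sid: SpecimenBundle(
            meta=slot["meta"],
            cytb=slot.get("cytb"),
            tyr=slot.get("tyr"),
        )
        for sid, slot in by_id.items()
    }
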