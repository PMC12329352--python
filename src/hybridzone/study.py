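"""Published reference values for the central-Japan pond-frog hybrid zone.

Two small constants that downstream analyses take as inputs:

* :data:`TYR_PANEL` — the ten species/subspecies-diagnostic sites of the
  747-bp nuclear Tyrosinase alignment, with each taxon's fixed base
  (positions are 1-based from the 5' end);
* :data:`SURVEY_COUNTS` — genetically classified specimen counts per
  basin and survey year (pure *P. nigromaculatus*, pure *P. p. porosus*,
  pure *P. p. brevipodus*, hybrid), as published for the 2010 and 2020
  surveys, including the alternative 2020 row compositions (with/without
  the Sai-gawa downstream sites in the Matsumoto aggregate; with/without
  the two sites newly added to the Ina survey).
"""

from __future__ import annotations

from hybridzone.panel import DiagnosticPanel, DiagnosticSite

__all__ = ["TAXA", "TYR_PANEL", "TYR_LENGTH", "SURVEY_COUNTS", "build_panel_references"]

#: taxon labels used throughout: one species plus the two subspecies of the
#: other, always in this order
TAXA = ("nigromaculatus", "porosus", "brevipodus")

TYR_LENGTH = 747

_PANEL_ROWS: dict[int, dict[str, str]] = {
    13: {"nigromaculatus": "A", "porosus": "A", "brevipodus": "G"},
    32: {"nigromaculatus": "T", "porosus": "C", "brevipodus": "C"},
    46: {"nigromaculatus": "A", "porosus": "G", "brevipodus": "G"},
    74: {"nigromaculatus": "C", "porosus": "T", "brevipodus": "T"},
    81: {"nigromaculatus": "C", "porosus": "T", "brevipodus": "T"},
    219: {"nigromaculatus": "C", "porosus": "G", "brevipodus": "G"},
    397: {"nigromaculatus": "A", "porosus": "T", "brevipodus": "A"},
    532: {"nigromaculatus": "G", "porosus": "G", "brevipodus": "A"},
    636: {"nigromaculatus": "T", "porosus": "C", "brevipodus": "C"},
    708: {"nigromaculatus": "A", "porosus": "G", "brevipodus": "G"},
}

TYR_PANEL = DiagnosticPanel(
    locus="tyr",
    locus_length=TYR_LENGTH,
    taxa=TAXA,
    sites=tuple(
        DiagnosticSite(position=pos, alleles=dict(alleles))
        for pos, alleles in sorted(_PANEL_ROWS.items())
    ),
)

#: class counts per (basin, year, row variant); classes are
#: (pure_N, pure_P, pure_B, hybrid)
SURVEY_COUNTS: dict[tuple, dict[str, int]] = {
    ("matsumoto", 2010, "basin"): {
        "pure_N": 49, "pure_P": 36, "pure_B": 0, "hybrid": 34,
    },
    ("matsumoto", 2020, "excluding_saigawa"): {
        "pure_N": 55, "pure_P": 17, "pure_B": 0, "hybrid": 80,
    },
    ("matsumoto", 2020, "including_saigawa"): {
        "pure_N": 61, "pure_P": 17, "pure_B": 0, "hybrid": 87,
    },
    ("ina", 2010, "basin"): {
        "pure_N": 44, "pure_P": 0, "pure_B": 9, "hybrid": 51,
    },
    ("ina", 2020, "excluding_new_sites"): {
        "pure_N": 50, "pure_P": 0, "pure_B": 20, "hybrid": 41,
    },
    ("ina", 2020, "including_new_sites"): {
        "pure_N": 62, "pure_P": 0, "pure_B": 20, "hybrid": 47,
    },
}


def build_panel_references(n_per_taxon: int = 2) -> dict[str, list]:
    """Construct unambiguous Tyrosinase reference sequences per taxon.

    Builds ``n_per_taxon`` identical full-length sequences per taxon that
    carry each taxon's diagnostic base at the panel positions and a shared
    background base elsewhere — the input from which diagnostic-site
    discovery must recover :data:`TYR_PANEL` exactly.
    """
    from hybridzone.seqio import SequenceRecord

    refs: dict[str, list] = {}
    for taxon in TAXA:
        bases = ["A"] * TYR_LENGTH
        for pos, alleles in _PANEL_ROWS.items():
            bases[pos - 1] = alleles[taxon]
        seq = "".join(bases)
        refs[taxon] = [
            SequenceRecord(specimen_id=f"{taxon}_ref{i + 1}", locus="tyr", bases=seq)
            for i in range(n_per_taxon)
        ]
    return refs
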