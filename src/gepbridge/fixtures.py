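"""Published-assay constants shared across modules.

The published KD assay measures 15 qRT-PCR targets: 13 classifier genes
plus two reference genes.  The microarray model addresses the classifier
genes through Illumina HumanHT-12 v4 probe identifiers; the map below pairs
each probe with its cognate gene symbol.
"""

from __future__ import annotations

#: Microarray probe id -> gene symbol for the 13 classifier genes.
PROBE_TO_GENE: dict[str, str] = {
    "ILMN_1664047": "CACNA1E",
    "ILMN_1790100": "DDIAS",
    "ILMN_1701837": "KLHL2",
    "ILMN_1684497": "PYROXD2",
    "ILMN_1775380": "SMOX",
    "ILMN_1802888": "ZNF185",
    "ILMN_3236239": "LINC02035",
    "ILMN_1796423": "CLIC3",
    "ILMN_1801216": "S100P",
    "ILMN_2058782": "IFI27",
    "ILMN_1898691": "TIGIT",
    "ILMN_2379599": "CD163",
    "ILMN_1756928": "RTN1",
}

GENE_TO_PROBE: dict[str, str] = {g: p for p, g in PROBE_TO_GENE.items()}

#: The 13 classifier gene symbols in published-table order.
CLASSIFIER_GENES: tuple[str, ...] = tuple(PROBE_TO_GENE.values())

#: Reference (housekeeping) genes selected for the qRT-PCR assay.
REFERENCE_GENES: tuple[str, str] = ("AURKAIP1", "SSU72")

#: Classifier gene whose qRT-PCR construct proved unstable (undetermined
#: Cts) and was excluded as an explanatory term when bridging.
UNSTABLE_GENE = "DDIAS"

#: Intronless classifier gene whose construct is susceptible to genomic-DNA
#: contamination in low-RIN samples.
INTRONLESS_GENE = "LINC02035"
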