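"""Curated catalogue of reported STAT-motif occurrences in six human
tight-junction genes (GRCh38/hg38 transcript anchors).

Each entry is one table cell: a gene, its anchoring transcript accession, the
region the occurrence was reported in, and the raw motif string.  Cells may
hold several abutting motifs as one string; the scanner splits them.  Spacer
classes are never stored — they are recomputed from the strings — and the
intron entries carry the reported intron-1 / intron-2 membership.

Region assignment of a few cells is reconstructed from a typeset table whose
column boundaries are ambiguous; the per-gene counts of N4 motifs within the
first two introns (CLDN7 = 1, CLDN12 = 2, TJP1 = 7, TJP2 = 11) and the
per-gene minimum counts are the anchoring constraints.
"""

from __future__ import annotations

import pandas as pd

from .motifs import MotifHit, hits_to_frame, scan_motifs

TJ_GENE_TRANSCRIPTS = {
    "CLDN4": "ENST00000435050.1",
    "CLDN7": "ENST00000397317.8",
    "CLDN12": "ENST00000400011.6",
    "CLDN15": "ENST00000287916.8",
    "TJP1": "ENST00000401528.5",
    "TJP2": "ENST00000377245.9",
}

# (gene, region, cell string); regions: upstream5k | intron1 | intron2 | downstream5k
PUBLISHED_MOTIF_CELLS: tuple[tuple[str, str, str], ...] = (
    # CLDN4
    ("CLDN4", "upstream5k", "TTCAGGAA"),
    ("CLDN4", "upstream5k", "TTCCAGAA"),
    ("CLDN4", "upstream5k", "TTCCCAGAA"),
    ("CLDN4", "upstream5k", "TTCCTTAGAA"),
    ("CLDN4", "downstream5k", "TTCTGGAA"),
    # CLDN7
    ("CLDN7", "upstream5k", "TTCATGAA"),
    ("CLDN7", "upstream5k", "TTCAAGAA"),
    ("CLDN7", "intron2", "TTCACCGAA"),
    ("CLDN7", "intron1", "TTCGAGGGAA"),
    ("CLDN7", "downstream5k", "TTCTGGAA"),
    # CLDN12
    ("CLDN12", "upstream5k", "TTCAAGAA"),
    ("CLDN12", "upstream5k", "TTCAGGAA"),
    ("CLDN12", "upstream5k", "TTCTGGGAA"),
    ("CLDN12", "upstream5k", "TTCAGAGGAA"),
    ("CLDN12", "intron2", "TTCTAGAA"),
    ("CLDN12", "intron2", "TTCACAGAA"),
    ("CLDN12", "intron2", "TTCAGAGAA"),
    ("CLDN12", "intron2", "TTCAATGAA"),
    ("CLDN12", "intron2", "TTCTTTGAA"),
    ("CLDN12", "intron2", "TTCTTAAGAA"),
    ("CLDN12", "intron2", "TTCTAAAGAA"),
    ("CLDN12", "downstream5k", "TTCCAGAA"),
    ("CLDN12", "downstream5k", "TTCTAAGAA"),
    ("CLDN12", "downstream5k", "TTCAAGGAA"),
    ("CLDN12", "downstream5k", "TTCCCTGAA"),
    ("CLDN12", "downstream5k", "TTCTATAGAA"),
    # CLDN15
    ("CLDN15", "upstream5k", "TTCCTGAA"),
    ("CLDN15", "upstream5k", "TTCTAGGAA"),
    ("CLDN15", "upstream5k", "TTCGTTGAA"),
    ("CLDN15", "upstream5k", "TTCGGGGAA"),
    ("CLDN15", "downstream5k", "TTCCAGAA"),
    ("CLDN15", "downstream5k", "TTCAGGAA"),
    ("CLDN15", "downstream5k", "TTCTAGAA"),
    ("CLDN15", "downstream5k", "TTCCCAGAA"),
    # TJP1
    ("TJP1", "upstream5k", "TTCGAGGAA"),
    ("TJP1", "upstream5k", "TTCCCGGGAA"),
    ("TJP1", "intron1", "TTCCTGAA"),
    ("TJP1", "intron1", "TTCCTACGAA"),
    ("TJP1", "intron1", "TTCAGCCGAA"),
    ("TJP1", "intron2", "TTCAGGAA"),
    ("TJP1", "intron2", "TTCCTGAA"),
    ("TJP1", "intron2", "TTCATGAA"),
    ("TJP1", "intron2", "TTCTTGAA"),
    ("TJP1", "intron2", "TTCTTGGAA"),
    ("TJP1", "intron2", "TTCTAAGAA"),
    ("TJP1", "intron2", "TTCTTGGAA"),
    ("TJP1", "intron2", "TTCAGAGAA"),
    ("TJP1", "intron2", "TTCCAAGAA"),
    ("TJP1", "intron2", "TTCATTGAA"),
    ("TJP1", "intron2", "TTCACTGAA"),
    ("TJP1", "intron2", "TTCCTTGAA"),
    ("TJP1", "intron2", "TTCTCCTGAA"),
    ("TJP1", "intron2", "TTCGGGAGAA"),
    ("TJP1", "intron2", "TTCAGAGGAA"),
    ("TJP1", "intron2", "TTCATTGGAA"),
    ("TJP1", "intron2", "TTCATTGGAA"),
    ("TJP1", "downstream5k", "TTCTGAGAA"),
    ("TJP1", "downstream5k", "TTCCAAGGAA"),
    ("TJP1", "downstream5k", "TTCCTTGGAA"),
    # TJP2
    ("TJP2", "upstream5k", "TTCATGAATTCCTGAA"),
    ("TJP2", "upstream5k", "TTCCACGAA"),
    ("TJP2", "upstream5k", "TTCTTGAGAATTCCATTGAA"),
    ("TJP2", "intron1", "TTCTTGAA"),
    ("TJP2", "intron1", "TTCATGAA"),
    ("TJP2", "intron1", "TTCAAGAA"),
    ("TJP2", "intron1", "TTCCAGAA"),
    ("TJP2", "intron1", "TTCTGGAA"),
    ("TJP2", "intron1", "TTCCCTGAA"),
    ("TJP2", "intron1", "TTCTTAGAA"),
    ("TJP2", "intron1", "TTCCATGAA"),
    ("TJP2", "intron1", "TTCCATGAA"),
    ("TJP2", "intron1", "TTCGTTGAA"),
    ("TJP2", "intron1", "TTCTTTGAA"),
    ("TJP2", "intron1", "TTCTCAGAA"),
    ("TJP2", "intron1", "TTCTCAGAA"),
    ("TJP2", "intron1", "TTCAGGGAA"),
    ("TJP2", "intron1", "TTCATAGAA"),
    ("TJP2", "intron1", "TTCATTGAA"),
    ("TJP2", "intron1", "TTCCAGAGAA"),
    ("TJP2", "intron1", "TTCGTAGGAA"),
    ("TJP2", "intron1", "TTCTTGAGAA"),
    ("TJP2", "intron1", "TTCTTTAGAA"),
    ("TJP2", "intron1", "TTCCCAGGAA"),
    ("TJP2", "intron1", "TTCAGTGGAA"),
    ("TJP2", "intron1", "TTCATGGGAA"),
    ("TJP2", "intron1", "TTCAAAGGAA"),
    ("TJP2", "intron1", "TTCTATGGAA"),
    ("TJP2", "intron1", "TTCACCTGAA"),
    ("TJP2", "intron2", "TTCCCGAA"),
    ("TJP2", "intron2", "TTCCTGAA"),
    ("TJP2", "intron2", "TTCTATGAA"),
    ("TJP2", "intron2", "TTCCTTGGAA"),
    ("TJP2", "downstream5k", "TTCTTGAATTCTTGAATTCCAGAA"),
    ("TJP2", "downstream5k", "TTCTCAGAATTCCTAGAATTCTGGGAA"),
    ("TJP2", "downstream5k", "TTCCTCAGAA"),
)

# Figure-level cohort counts: sensitization of 30 AR patients to the three
# house-dust-mite allergens (D. pteronyssinus, D. farinae, B. tropicalis).
HDM_SENSITIZATION_COUNTS = {"one_allergen": 3, "two_allergens": 7, "three_allergens": 20}
HDM_COHORT_SIZE = 30


def published_motif_table() -> pd.DataFrame:
    """Scan the catalogue's cell strings into a per-hit motif table.

    Every cell string is run through the motif scanner, so abutting motifs in
    one cell come out as separate hits and every spacer class is computed,
    not transcribed.  Genomic positions are not part of the catalogue and are
    reported as -1.
    """
    hits = []
    for gene, region, cell in PUBLISHED_MOTIF_CELLS:
        found = scan_motifs(cell)
        consumed = sum(len(seq) for _, seq, _ in found)
        if consumed != len(cell):
            raise ValueError(f"catalogue cell {cell!r} is not a run of motifs")
        for offset, seq, spacer in found:
            hits.append(
                MotifHit(
                    transcript_id=gene,
                    region=region,
                    offset=offset,
                    genomic_pos=-1,
                    sequence=seq,
                    spacer=spacer,
                )
            )
    return hits_to_frame(hits)
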