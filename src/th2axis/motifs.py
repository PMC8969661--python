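"""STAT consensus motif scanning over defined gene regions.

STAT transcription factors bind the palindromic GAS-like element
5'-TTC(N)kGAA-3' with a spacer of k = 2, 3 or 4 unambiguous nucleotides.
STAT6 accepts only the N3/N4 spacers and favours N4 sites, preferentially
within the first two introns of a gene.  This module extracts, for one
transcript model, the four regions of interest — 5 kb upstream of the first
exon, introns 1 and 2, and 5 kb downstream of the last exon, all in
transcript orientation — scans each for the motif family, and tabulates hits
per gene / region / spacer class.

The motif family is closed under reverse complement
(revcomp(TTC·s·GAA) = TTC·revcomp(s)·GAA), so hit counts are strand
invariant; sequences are scanned transcript-sense only and spacers are
reported in the gene's reading orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneModel

REGION_LABELS = ("upstream5k", "intron1", "intron2", "downstream5k")
FLANK = 5_000
_MOTIF_RE = re.compile(r"(?=(TTC([ACGT]{2,4})GAA))")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Region:
    """One scanned region: genomic slice plus its transcript-sense sequence."""

    chrom: str
    start: int  # 0-based half-open, genomic
    end: int
    strand: str
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    transcript_id: str
    regions: dict[str, Region]


@dataclass
class MotifHit:
    transcript_id: str
    region: str
    offset: int  # 0-based within the transcript-sense region sequence
    genomic_pos: int  # 1-based genomic start of the matched sequence
    sequence: str
    spacer: str

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)

    @property
    def stat6_compatible(self) -> bool:
        return self.spacer_len in (3, 4)

    @property
    def stat6_preferred(self) -> bool:
        return self.spacer_len == 4 and self.region in ("intron1", "intron2")


def extract_regions(model: GeneModel, genome: Mapping[str, str]) -> RegionSet:
    """The four scanned regions of ``model``, clipped at chromosome ends.

    First exon / intron 1 / intron 2 / last exon are taken in TRANSCRIPT
    orientation: on the minus strand the first exon is the one with the
    highest genomic coordinates.  Intron regions exist only when the
    transcript has enough exons.  Sequences are reverse-complemented for
    minus-strand transcripts so every region reads transcript-sense.
    """
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} absent from genome")
    chrom_seq = genome[model.chrom]
    L = len(chrom_seq)
    lo, hi = model.span
    if hi > L:
        raise ValueError(f"{model.transcript_id}: exons exceed chromosome length")

    # genomic introns in ascending order
    introns = [
        (model.exons[i][1], model.exons[i + 1][0])
        for i in range(model.n_exons - 1)
        if model.exons[i + 1][0] > model.exons[i][1]
    ]
    regions: dict[str, tuple[int, int]] = {}
    if model.strand == "+":
        regions["upstream5k"] = (max(0, lo - FLANK), lo)
        regions["downstream5k"] = (hi, min(L, hi + FLANK))
        for i, iv in enumerate(introns[:2], start=1):
            regions[f"intron{i}"] = iv
    else:
        regions["upstream5k"] = (hi, min(L, hi + FLANK))
        regions["downstream5k"] = (max(0, lo - FLANK), lo)
        for i, iv in enumerate(reversed(introns[-2:] if introns else []), start=1):
            regions[f"intron{i}"] = iv

    out: dict[str, Region] = {}
    for label, (start, end) in regions.items():
        seq = chrom_seq[start:end]
        if model.strand == "-":
            seq = reverse_complement(seq)
        out[label] = Region(model.chrom, start, end, model.strand, seq)
    return RegionSet(transcript_id=model.transcript_id, regions=out)


def scan_motifs(sequence: str, spacer_range: Iterable[int] = (2, 3, 4)) -> list[tuple[int, str, str]]:
    """All TTC(N)kGAA occurrences in ``sequence`` for k in ``spacer_range``.

    Returns (offset, matched sequence, spacer) triples in ascending offset
    order.  Overlapping occurrences at distinct starts are all reported; the
    fixed TTC/GAA flanks make at most one spacer length match per start.
    Ambiguity codes (N etc.) never match any position.
    """
    allowed = set(spacer_range)
    if not allowed <= {2, 3, 4}:
        raise ValueError("spacer lengths must be within {2, 3, 4}")
    hits = []
    for m in _MOTIF_RE.finditer(sequence.upper()):
        spacer = m.group(2)
        if len(spacer) in allowed:
            hits.append((m.start(), m.group(1), spacer))
    return hits


def classify_spacer(sequence: str) -> int:
    """Spacer length of a sequence that is exactly one motif; error otherwise."""
    hits = scan_motifs(sequence)
    if len(hits) != 1 or hits[0][0] != 0 or len(hits[0][1]) != len(sequence):
        raise ValueError(f"{sequence!r} is not a single TTC(N)2-4GAA motif")
    return len(hits[0][2])


def scan_region_set(region_set: RegionSet) -> list[MotifHit]:
    """Scan every region of a RegionSet, attaching genomic coordinates."""
    hits: list[MotifHit] = []
    for label in REGION_LABELS:
        region = region_set.regions.get(label)
        if region is None:
            continue
        for offset, seq, spacer in scan_motifs(region.sequence):
            if region.strand == "+":
                gpos = region.start + offset + 1
            else:
                gpos = region.end - offset - len(seq) + 1
            hits.append(
                MotifHit(
                    transcript_id=region_set.transcript_id,
                    region=label,
                    offset=offset,
                    genomic_pos=gpos,
                    sequence=seq,
                    spacer=spacer,
                )
            )
    return hits


def scan_gene(model: GeneModel, genome: Mapping[str, str]) -> pd.DataFrame:
    """Motif table for one transcript: one row per hit with STAT6 flags."""
    hits = scan_region_set(extract_regions(model, genome))
    return hits_to_frame(hits)


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": h.transcript_id,
            "region": h.region,
            "offset": h.offset,
            "genomic_pos": h.genomic_pos,
            "sequence": h.sequence,
            "spacer": h.spacer,
            "spacer_len": h.spacer_len,
            "stat6_compatible": h.stat6_compatible,
            "stat6_preferred": h.stat6_preferred,
            "in_intron1": h.region == "intron1",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "region", "offset", "genomic_pos", "sequence",
            "spacer", "spacer_len", "stat6_compatible", "stat6_preferred",
            "in_intron1",
        ],
    )


def tabulate_motifs(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-gene motif tables into a long report and summary counts.

    The long table maps the two intron labels onto a single ``introns1-2``
    report column (intron-1 membership is kept as a flag).  The summary has
    one row per transcript with total motif count, N2/N3/N4 totals, the
    STAT6-compatible (N3+N4) total, and the count of N4 motifs inside the
    first two introns (the STAT6-preferred configuration).
    """
    if not tables:
        raise ValueError("need at least one motif table")
    combined = pd.concat(tables, ignore_index=True)
    long = combined.copy()
    long["report_region"] = long["region"].map(
        {
            "upstream5k": "upstream",
            "intron1": "introns1-2",
            "intron2": "introns1-2",
            "downstream5k": "downstream",
        }
    )
    summaries = []
    for tid, grp in long.groupby("transcript_id", sort=True):
        in_introns = grp["report_region"] == "introns1-2"
        summaries.append(
            {
                "transcript_id": tid,
                "total": len(grp),
                "n2": int((grp["spacer_len"] == 2).sum()),
                "n3": int((grp["spacer_len"] == 3).sum()),
                "n4": int((grp["spacer_len"] == 4).sum()),
                "stat6_compatible": int(grp["stat6_compatible"].sum()),
                "n4_in_first_two_introns": int(
                    ((grp["spacer_len"] == 4) & in_introns).sum()
                ),
            }
        )
    summary = pd.DataFrame(
        summaries,
        columns=[
            "transcript_id", "total", "n2", "n3", "n4",
            "stat6_compatible", "n4_in_first_two_introns",
        ],
    )
    return long, summary
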