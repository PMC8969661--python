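"""Readers and writers for the external formats the pipeline touches.

Expression matrices (plain TSV or the GEO series-matrix dialect), probe
annotation tables, gene models (BED12 / GFF3), FASTA genomes and GMT gene-set
collections.  All genomic coordinates are 0-based half-open internally;
1-based inclusive coordinates appear only in reports.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Malformed input file or violated container invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of (log-scale) intensities with group labels.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns;
    ``sample_groups`` maps every sample id to its group label (e.g. ``"AR"``,
    ``"control"``).  Missing values are NaN and are handled pairwise
    downstream.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe id(s): {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample id(s)")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise FormatError(f"no group label for sample(s): {missing}")
        if not np.issubdtype(self.values.values.dtype, np.floating):
            raise FormatError("expression values must be numeric")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_groups[s] == group]


def _coerce_numeric(table: pd.DataFrame) -> pd.DataFrame:
    out = table.apply(pd.to_numeric, errors="coerce")
    # report the first offending cell by name, not just NaN-ify it
    stripped = table.astype(str).apply(lambda col: col.str.strip())
    bad = out.isna() & table.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {table.iat[r, c]!r} at probe "
            f"{table.index[r]!r}, sample {table.columns[c]!r}"
        )
    return out.astype(float)


def read_expression_matrix(
    path: str | Path,
    sample_groups: Mapping[str, str],
    dialect: str = "tsv",
) -> ExpressionMatrix:
    """Read a probe x sample expression table.

    ``dialect="tsv"`` expects a header row of sample ids and a probe-id first
    column.  ``dialect="series_matrix"`` accepts the GEO series-matrix layout:
    ``!``-prefixed metadata lines with the numeric table fenced by
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end``.  Group
    labels always come from ``sample_groups`` (a config mapping); series-matrix
    metadata is never trusted for grouping.
    """
    path = Path(path)
    if dialect == "tsv":
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "series_matrix":
        lines: list[str] = []
        inside = False
        for line in path.read_text().splitlines():
            if line.startswith("!series_matrix_table_begin"):
                inside = True
            elif line.startswith("!series_matrix_table_end"):
                inside = False
            elif inside and line.strip():
                lines.append(line)
        if not lines:
            raise FormatError(f"{path}: no series_matrix table fence found")
        table = pd.read_csv(
            _io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str
        )
        table.index = table.index.str.strip('"')
        table.columns = table.columns.str.strip('"')
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate probe id(s): {dupes[:5]}")
    table.index = table.index.astype(str)
    table.index.name = "probe_id"
    values = _coerce_numeric(table)
    return ExpressionMatrix(values=values, sample_groups=dict(sample_groups))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """Two-column TSV probe_id -> gene symbol; symbols upper-cased on ingest.

    An empty symbol means the probe is unannotated.
    """
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, header=0
    )
    if table.shape[1] < 2:
        raise FormatError(f"{path}: annotation needs >= 2 columns")
    probes = table.iloc[:, 0].astype(str)
    if probes.duplicated().any():
        raise FormatError(f"{path}: duplicate probe id in annotation")
    return dict(zip(probes, table.iloc[:, 1].str.strip().str.upper()))


def write_probe_annotation(annot: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(annot), "gene_symbol": list(annot.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript: chromosome, strand and its exons.

    Exons are 0-based half-open intervals in ascending genomic order,
    non-overlapping, regardless of strand.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"{self.transcript_id}: needs >= 1 exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise FormatError(
                    f"{self.transcript_id}: zero/negative-length exon ({start},{end})"
                )
            if start < 0:
                raise FormatError(f"{self.transcript_id}: negative coordinate")
            if start < prev_end:
                raise FormatError(f"{self.transcript_id}: overlapping exons")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read transcript models from BED12 or GFF3.

    Exon coordinates come out 0-based half-open for both dialects (GFF3
    1-based starts are decremented).  GFF3 exon features are grouped by their
    ``Parent`` (falling back to ``transcript_id``) attribute.
    """
    path = Path(path)
    if format == "bed12":
        return _read_bed12(path)
    if format == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise FormatError(f"{path}:{ln}: BED12 needs 12 fields")
        chrom, start, _end, name, _score, strand = fields[:6]
        start = int(start)
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(f"{path}:{ln}: blockCount mismatch")
        exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
        models.append(GeneModel(name, chrom, strand, exons))
    return models


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent") or exon.attributes.get(
            "transcript_id"
        )
        if not parents:
            raise FormatError(f"exon without Parent/transcript_id in {path}")
        for tid in parents:
            rec = grouped.setdefault(
                tid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []}
            )
            rec["exons"].append((exon.start - 1, exon.end))  # GFF3 is 1-based
    return [
        GeneModel(tid, rec["chrom"], rec["strand"], rec["exons"])
        for tid, rec in grouped.items()
    ]


def write_gene_models_bed12(models: list[GeneModel], path: str | Path) -> None:
    lines = []
    for m in models:
        start, end = m.span
        sizes = ",".join(str(b - a) for a, b in m.exons)
        offsets = ",".join(str(a - start) for a, _ in m.exons)
        lines.append(
            "\t".join(
                [
                    m.chrom, str(start), str(end), m.transcript_id, "0",
                    m.strand, str(start), str(end), "0", str(m.n_exons),
                    sizes, offsets,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into {name: uppercased sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"{path}: empty or non-FASTA file")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member [<tab> member ...].

    Members are upper-cased and deduplicated per set.
    """
    sets: dict[str, set[str]] = {}
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: GMT line needs >= 3 fields")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{ln}: duplicate set name {name!r}")
        sets[name] = {g.strip().upper() for g in fields[2:] if g.strip()}
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")
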