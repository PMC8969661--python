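"""Synthetic-data generators with ground truth.

Three generators emulate the statistical structure the analysis assumes:

* ``gen_expression`` — a two-group expression matrix in which a per-sample
  latent factor drives the two receptor-subunit probes and a set of planted
  positively / negatively loaded target genes, on top of independent null
  probes.  This is the co-expression structure the heterodimer screen is
  designed to detect.
* ``gen_cohort`` — lognormal serum-cytokine levels with a group shift, and
  per-gene qPCR Ct values (target and reference) drawn normal per group.
* ``gen_genome`` — synthetic chromosomes carrying multi-exon gene models with
  TTC(N)kGAA motifs written at requested offsets inside named regions.  The
  emitted truth is a brute-force oracle scan of the final sequence, so
  spontaneous background motifs are part of the truth, not suppressed.

Each generator is bit-reproducible from (spec, seed); substreams are derived
from the single integer seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModel
from .motifs import FLANK, MotifHit, extract_regions, reverse_complement

_STREAM_EXPRESSION = 0
_STREAM_COHORT = 1
_STREAM_GENOME = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Expression matrix with planted co-expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Latent-factor model: subunits = a*z + e, planted gene = ±b*z + e."""

    n_group_a: int = 12
    n_group_b: int = 6
    n_null_probes: int = 500
    planted_positive: list[tuple[str, float]] = field(default_factory=list)
    planted_negative: list[tuple[str, float]] = field(default_factory=list)
    subunit_loading: float = 0.9
    noise_sd: float = 0.5
    group_a_label: str = "AR"
    group_b_label: str = "control"
    baseline: float = 8.0  # log2-intensity offset, cosmetic only

    def validate(self) -> None:
        if self.n_group_a < 0 or self.n_group_b < 0 or self.n_null_probes < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.subunit_loading <= 1:
            raise ValueError("subunit_loading must be in (0, 1]")
        for name, b in self.planted_positive + self.planted_negative:
            if not 0 < b <= 1:
                raise ValueError(f"loading for {name!r} must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


SUBUNIT_A_PROBE = "SUBUNIT_A_at"
SUBUNIT_B_PROBE = "SUBUNIT_B_at"


def gen_expression(
    spec: ExpressionSimSpec, seed: int
) -> tuple[ExpressionMatrix, dict[str, str], dict[str, list[str]]]:
    """Two-group matrix with a latent factor behind subunits and planted genes.

    Returns the matrix, a probe->gene annotation (null probes unannotated),
    and the ground truth ``{"positive": [...], "negative": [...]}`` listing
    the planted gene symbols.  One latent value z is drawn per sample; the
    screen subsets to one group, so its effective sample size is that
    group's n.
    """
    spec.validate()
    rng = _rng(seed, _STREAM_EXPRESSION)
    n_a, n_b = spec.n_group_a, spec.n_group_b
    n_samples = n_a + n_b
    sample_ids = [f"A{i+1:02d}" for i in range(n_a)] + [
        f"B{i+1:02d}" for i in range(n_b)
    ]
    groups = dict(
        zip(
            sample_ids,
            [spec.group_a_label] * n_a + [spec.group_b_label] * n_b,
        )
    )
    z = rng.standard_normal(n_samples)

    def signal(loading: float, sign: float = 1.0) -> np.ndarray:
        noise = rng.standard_normal(n_samples) * spec.noise_sd
        return spec.baseline + sign * loading * z + noise

    probe_ids, rows, annot = [], [], {}
    probe_ids += [SUBUNIT_A_PROBE, SUBUNIT_B_PROBE]
    rows += [signal(spec.subunit_loading), signal(spec.subunit_loading)]
    annot[SUBUNIT_A_PROBE] = "IL4R"
    annot[SUBUNIT_B_PROBE] = "IL13RA1"
    truth = {"positive": [], "negative": []}
    for sign, key, planted in (
        (1.0, "positive", spec.planted_positive),
        (-1.0, "negative", spec.planted_negative),
    ):
        for gene, b in planted:
            pid = f"{gene}_at"
            probe_ids.append(pid)
            rows.append(signal(b, sign))
            annot[pid] = gene.upper()
            truth[key].append(gene.upper())
    for i in range(spec.n_null_probes):
        pid = f"NULL{i+1:05d}_at"
        probe_ids.append(pid)
        rows.append(rng.standard_normal(n_samples) * spec.noise_sd + spec.baseline)
        annot[pid] = ""
    values = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=sample_ids)
    values.index.name = "probe_id"
    return ExpressionMatrix(values=values, sample_groups=groups), annot, truth


# ---------------------------------------------------------------------------
# Cohort: cytokines + qPCR Ct values
# ---------------------------------------------------------------------------

@dataclass
class AnalyteSpec:
    """Lognormal serum analyte: value = 2**N(log2_mean, log2_sd) pg/ml."""

    log2_mean_control: float
    log2_mean_case: float
    log2_sd: float = 1.0


@dataclass
class CtSpec:
    """qPCR Ct pair: target Ct mean per group, shared reference Ct mean."""

    ct_target_control: float
    ct_target_case: float
    ct_reference: float = 18.0
    sd: float = 0.4


@dataclass
class CohortSimSpec:
    """Two-group cohort emulating serum Th2 cytokines and receptor qPCR.

    Defaults give an AR-like case group: IL-4/IL-5/IL-6/IL-13 elevated about
    one log2 unit over controls, receptor transcripts near-null except a mild
    IL13RA1 shift.
    """

    n_per_group: int = 30
    analytes: dict[str, AnalyteSpec] = field(
        default_factory=lambda: {
            "IL4": AnalyteSpec(3.0, 4.0, 0.8),
            "IL5": AnalyteSpec(3.5, 4.3, 0.9),
            "IL6": AnalyteSpec(4.0, 4.6, 1.0),
            "IL13": AnalyteSpec(3.0, 4.2, 0.8),
        }
    )
    ct_genes: dict[str, CtSpec] = field(
        default_factory=lambda: {
            "IL4R": CtSpec(24.0, 24.0),
            "IL5RA": CtSpec(26.0, 26.0),
            "IL6R": CtSpec(23.0, 23.0),
            "IL13RA1": CtSpec(25.0, 24.6),
        }
    )
    case_label: str = "case"
    control_label: str = "control"

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        for name, a in self.analytes.items():
            if a.log2_sd <= 0:
                raise ValueError(f"{name}: log2_sd must be > 0")
        for name, c in self.ct_genes.items():
            if c.sd <= 0:
                raise ValueError(f"{name}: sd must be > 0")


def gen_cohort(spec: CohortSimSpec, seed: int) -> pd.DataFrame:
    """Cohort table: one row per subject with group, analytes and Ct values."""
    spec.validate()
    rng = _rng(seed, _STREAM_COHORT)
    n = spec.n_per_group
    rows: dict[str, list] = {
        "subject_id": [f"S{i+1:03d}" for i in range(2 * n)],
        "group": [spec.control_label] * n + [spec.case_label] * n,
    }
    for name, a in spec.analytes.items():
        log2_means = np.r_[
            np.full(n, a.log2_mean_control), np.full(n, a.log2_mean_case)
        ]
        rows[name] = 2.0 ** (log2_means + rng.standard_normal(2 * n) * a.log2_sd)
    ref_done = False
    for name, c in spec.ct_genes.items():
        ct_means = np.r_[
            np.full(n, c.ct_target_control), np.full(n, c.ct_target_case)
        ]
        rows[f"Ct_{name}"] = ct_means + rng.standard_normal(2 * n) * c.sd
        if not ref_done:
            rows["Ct_ref"] = c.ct_reference + rng.standard_normal(2 * n) * c.sd
            ref_done = True
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome with planted motifs
# ---------------------------------------------------------------------------

@dataclass
class GeneSimSpec:
    transcript_id: str
    chrom: str
    strand: str = "+"
    tss: int = 6_000  # genomic start of the first (lowest-coordinate) exon
    exon_lengths: tuple[int, ...] = (200, 200, 200)
    intron_lengths: tuple[int, ...] = (400, 400)


@dataclass
class PlantedMotif:
    transcript_id: str
    region: str  # upstream5k | intron1 | intron2 | downstream5k
    offset: int  # 0-based within the transcript-sense region sequence
    spacer: str  # 2-4 unambiguous bases

    def motif(self) -> str:
        return f"TTC{self.spacer.upper()}GAA"


@dataclass
class GenomeSimSpec:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS": 20_000})
    genes: list[GeneSimSpec] = field(default_factory=list)
    planted: list[PlantedMotif] = field(default_factory=list)
    gc_fraction: float = 0.41

    def validate(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        for p in self.planted:
            if len(p.spacer) not in (2, 3, 4):
                raise ValueError(f"spacer length must be 2-4, got {p.spacer!r}")
            if set(p.spacer.upper()) - set("ACGT"):
                raise ValueError(f"spacer must be unambiguous: {p.spacer!r}")


def _build_models(spec: GenomeSimSpec) -> list[GeneModel]:
    models = []
    for g in spec.genes:
        if len(g.intron_lengths) != len(g.exon_lengths) - 1:
            raise ValueError(f"{g.transcript_id}: need n_exons - 1 intron lengths")
        exons, pos = [], g.tss
        for i, elen in enumerate(g.exon_lengths):
            exons.append((pos, pos + elen))
            pos += elen
            if i < len(g.intron_lengths):
                pos += g.intron_lengths[i]
        models.append(GeneModel(g.transcript_id, g.chrom, g.strand, exons))
    return models


def oracle_scan(sequence: str) -> list[tuple[int, str, str]]:
    """Brute-force motif oracle: test every start for TTC + k bases + GAA.

    Independent of the regex-based scanner in :mod:`th2axis.motifs`.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq)):
        for k in (2, 3, 4):
            end = i + 6 + k
            if end > len(seq):
                continue
            window = seq[i:end]
            spacer = window[3 : 3 + k]
            if (
                window.startswith("TTC")
                and window.endswith("GAA")
                and all(c in "ACGT" for c in spacer)
            ):
                hits.append((i, window, spacer))
    return hits


def gen_genome(
    spec: GenomeSimSpec, seed: int
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Synthesize chromosomes, gene models and planted motifs, with truth.

    Background bases are drawn i.i.d. at the requested GC fraction; each
    planted motif is written into the transcript-sense sequence of its region
    at the requested offset (reverse-complemented into the genome for minus
    strands).  The returned truth table is the brute-force oracle scan of
    every region of the FINAL sequence, so background motifs that arise by
    chance are included.
    """
    spec.validate()
    rng = _rng(seed, _STREAM_GENOME)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genome = {
        chrom: rng.choice(list("ACGT"), size=length, p=probs)
        for chrom, length in spec.chrom_lengths.items()
    }
    models = _build_models(spec)
    by_id = {m.transcript_id: m for m in models}

    # write planted motifs through region coordinates into the genome arrays
    occupied: dict[str, set[int]] = {c: set() for c in genome}
    for p in spec.planted:
        model = by_id.get(p.transcript_id)
        if model is None:
            raise ValueError(f"unknown transcript {p.transcript_id!r}")
        region_set = extract_regions(
            model, {c: "".join(arr) for c, arr in genome.items()}
        )
        region = region_set.regions.get(p.region)
        if region is None:
            raise ValueError(f"{p.transcript_id} has no region {p.region!r}")
        motif = p.motif()
        if p.offset < 0 or p.offset + len(motif) > len(region):
            raise ValueError(
                f"planted motif outside {p.region} bounds for {p.transcript_id}"
            )
        if region.strand == "+":
            gstart = region.start + p.offset
            written = motif
        else:
            gstart = region.end - p.offset - len(motif)
            written = reverse_complement(motif)
        span = set(range(gstart, gstart + len(motif)))
        if span & occupied[model.chrom]:
            raise ValueError(f"planted motifs overlap at {model.chrom}:{gstart}")
        occupied[model.chrom] |= span
        genome[model.chrom][gstart : gstart + len(motif)] = list(written)

    genome_str = {c: "".join(arr) for c, arr in genome.items()}

    truth_hits: list[MotifHit] = []
    for model in models:
        region_set = extract_regions(model, genome_str)
        for label, region in region_set.regions.items():
            for offset, seq, spacer in oracle_scan(region.sequence):
                if region.strand == "+":
                    gpos = region.start + offset + 1
                else:
                    gpos = region.end - offset - len(seq) + 1
                truth_hits.append(
                    MotifHit(
                        transcript_id=model.transcript_id,
                        region=label,
                        offset=offset,
                        genomic_pos=gpos,
                        sequence=seq,
                        spacer=spacer,
                    )
                )
    from .motifs import hits_to_frame

    truth = hits_to_frame(truth_hits).sort_values(
        ["transcript_id", "region", "offset"], kind="stable"
    ).reset_index(drop=True)
    return genome_str, models, truth
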