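"""Generate the synthetic study inputs.

Writes, under scratch/data/: a two-group cohort table (serum cytokines +
qPCR Ct values), a two-group expression matrix whose latent factor drives
the two receptor-subunit probes and twenty planted target genes, and a
synthetic genome with two multi-exon gene models carrying planted STAT
motifs.  Ground truth accompanies each dataset.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd
import yaml

from th2axis import io as tio
from th2axis import simulate as sim

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("scratch/data")
DATA.mkdir(parents=True, exist_ok=True)

# --- cohort: 30 vs 30 subjects, four cytokines, four receptor transcripts
cohort = sim.gen_cohort(sim.CohortSimSpec(n_per_group=30), seed=SEED)
cohort.to_csv(DATA / "cohort.tsv", sep="\t", index=False, float_format="%.6g")
print(f"cohort: {len(cohort)} subjects, analytes IL4/IL5/IL6/IL13, "
      f"Ct values for IL4R/IL5RA/IL6R/IL13RA1 -> {DATA/'cohort.tsv'}")

# --- expression: 12 AR + 6 control samples, 10 planted genes per sign
expr_spec = sim.ExpressionSimSpec(
    n_group_a=12, n_group_b=6, n_null_probes=500,
    planted_positive=[(f"POS{i:02d}", 0.9) for i in range(10)],
    planted_negative=[(f"NEG{i:02d}", 0.9) for i in range(10)],
    noise_sd=0.3,
)
matrix, annot, truth = sim.gen_expression(expr_spec, seed=SEED)
tio.write_expression_matrix(matrix, DATA / "expression.tsv")
tio.write_probe_annotation(annot, DATA / "annotation.tsv")
yaml.safe_dump({"sample_groups": matrix.sample_groups},
               (DATA / "config.yaml").open("w"))
pd.DataFrame(
    [(g, s) for s, genes in truth.items() for g in genes],
    columns=["gene_symbol", "planted_sign"],
).to_csv(DATA / "expression_truth.tsv", sep="\t", index=False)
print(f"expression: {matrix.values.shape[0]} probes x "
      f"{matrix.values.shape[1]} samples (12 AR / 6 control), "
      f"20 planted genes -> {DATA/'expression.tsv'}")

# --- genome: one chromosome, a plus- and a minus-strand gene, planted motifs
genome_spec = sim.GenomeSimSpec(
    chrom_lengths={"chrS": 30_000},
    genes=[sim.GeneSimSpec("TX1", "chrS", "+", tss=6_000),
           sim.GeneSimSpec("TX2", "chrS", "-", tss=20_000)],
    planted=[sim.PlantedMotif("TX1", "intron1", 50, "AGGG"),
             sim.PlantedMotif("TX1", "upstream5k", 200, "CT"),
             sim.PlantedMotif("TX2", "intron2", 30, "TACA")],
)
genome, models, motif_truth = sim.gen_genome(genome_spec, seed=SEED)
tio.write_fasta(genome, DATA / "genome.fa")
tio.write_gene_models_bed12(models, DATA / "models.bed")
motif_truth.to_csv(DATA / "motif_truth.tsv", sep="\t", index=False)
print(f"genome: chrS ({len(genome['chrS']):,} bp), 2 gene models, "
      f"{len(motif_truth)} true motif hits (3 planted + background) "
      f"-> {DATA/'genome.fa'}")
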