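# th2axis

Analysis pipeline linking the IL-4/IL-13 cytokine axis to tight-junction
(TJ) gene suppression in allergic rhinitis (AR) transcriptomics. Both IL-4
and IL-13 signal through the type II IL-4 receptor — the IL-4Rα/IL-13Rα1
heterodimer (transcripts *IL4R* and *IL13RA1*) — activating STAT6, which can
repress transcription by binding GAS-like elements in introns and flanking
regions. The package implements the computational arm of that hypothesis:

1. **Cohort statistics** (`th2axis.cohort`) — Livak 2^−ΔΔCt relative qPCR
   quantification against a control-group calibrator; two-group comparison
   gated on Shapiro–Wilk normality (Welch *t* when both groups pass,
   Mann–Whitney *U* otherwise); Pearson correlation with the *t*-transform
   p-value; and the critical correlation threshold
   r\* = t\*/√(t\*² + n−2) — the smallest |r| significant two-tailed at α
   for sample size *n* (r\* = 0.811 for n = 6, 0.576 for n = 12 at α = 0.05).
2. **Heterodimer co-correlation screen** (`th2axis.screen`) — every probe on
   an expression matrix is correlated, within one sample group, against the
   two receptor-subunit probes; probes beyond r\* against **both** subunits
   are categorized by sign pattern (`both_positive`, `both_negative`,
   `a_only`, `b_only`, `discordant`, `none`) and collapsed to unique
   annotated gene symbols, with TJ/desmosomal/JAK-STAT genes flagged.
3. **Gene-set enrichment** (`th2axis.enrich`) — upper-tail hypergeometric
   over-representation against an explicit universe with Benjamini–Hochberg
   FDR.
4. **STAT motif scan** (`th2axis.motifs`) — extraction of 5 kb upstream of
   the first exon, introns 1–2 and 5 kb downstream of the last exon (in
   transcript orientation, strand-aware), scanning for the palindromic STAT
   consensus 5′-TTC(N)₂₋₄GAA-3′, and flagging STAT6-compatible (N3/N4) and
   STAT6-preferred (N4 within the first two introns) sites.
5. **Synthetic data** (`th2axis.simulate`) — generators with ground truth
   for all three input kinds: a latent-factor expression matrix with planted
   co-expressed genes, a lognormal cytokine/qPCR cohort, and a genome with
   motifs planted in known regions.

It is written for researchers reanalysing microarray/expression cohorts
(e.g. GEO series matrices) alongside their own qPCR/serology panels.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on synthetic
data (outputs land in `results/`, intermediate data in `scratch/data/`):

```
python analysis/01_simulate.py 1
python analysis/02_cohort_stats.py
python analysis/03_screen.py
python analysis/04_enrichment.py
python analysis/05_motifs.py
```

`03_screen.py` prints, for the simulated 12-sample AR group:

```
AR: n = 12, |r| threshold = 0.576
  both-positive probes 18, genes 10 (planted positives recovered 10/10)
  both-negative probes 18, genes 10 (planted negatives recovered 10/10)
control: n = 6, |r| threshold = 0.811
  ...
```

i.e. at the n = 12 critical threshold every planted co-expressed gene is
found with the correct sign, while the 6-sample control screen, with its
much stricter threshold (0.811), recovers only a fraction — the same
asymmetry the screen is designed to expose in real case/control cohorts.
`05_motifs.py` prints the per-gene motif summary for the six TJ genes
(total, N2/N3/N4, STAT6-compatible and N4-within-introns-1–2 counts); four
of the six genes — CLDN7 (n = 1), CLDN12 (n = 2), TJP1 (n = 7), TJP2
(n = 11) — carry at least one STAT6-preferred site.

A `th2axis` CLI exposes the same stages
(`th2axis simulate|screen|cohort-stats|enrich|motifs --help`).

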