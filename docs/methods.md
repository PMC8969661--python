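# Methods

## Cohort statistics

**Relative qPCR quantification.** For a target gene with cycle thresholds
Ct_target and a reference gene Ct_ref, ΔCt = Ct_target − Ct_ref per subject;
the calibrator is the arithmetic mean ΔCt of the control group;
ΔΔCt = ΔCt − calibrator and fold = 2^−ΔΔCt (Livak method). Using the mean
control ΔCt as calibrator forces the geometric mean of control-group folds
to 1, which is the invariant the implementation checks. Subjects missing
either Ct are dropped with a warning; absence of any control subject is an
error because the calibrator is undefined.

**Normality-gated two-group test.** Each group is tested with Shapiro–Wilk
at α = 0.05; only if **both** groups pass is a two-sample *t*-test used,
otherwise Mann–Whitney *U* (two-tailed throughout). The *t*-test is Welch's
(unequal variance) by default — the safer choice when the variant is
unspecified — and the variant is overridable. A constant group makes the
Shapiro statistic undefined, so such comparisons fall through to
Mann–Whitney with a warning. The Mann–Whitney p is exact for small,
tie-free samples and normal-approximated with tie correction otherwise
(scipy's `method="auto"`). The gate's cost is mild conservatism: under a
lognormal null with n = 15 per group, its measured type-I error is ≈ 0.05
(the acceptance script recomputes this over 2,000 simulations).

**Critical correlation threshold.** For sample Pearson r,
t = r√((n−2)/(1−r²)) is Student-t with n−2 df under the null, so the
smallest two-tailed-significant |r| is r\* = t\*/√(t\*² + n−2) with t\* the
α/2 critical value. At α = 0.05 this gives 0.8114 for n = 6 (df = 4,
t\* = 2.7764) and 0.5760 for n = 12 (df = 10, t\* = 2.2281). Screens that
must reproduce a previously published cutoff verbatim can override the
threshold explicitly (`r_threshold` / `--r-threshold`) instead of deriving
it from (n, α); the df = n−2 form is what the package computes.

## Heterodimer co-correlation screen

Within one sample group, every probe except the two subunit probes is
Pearson-correlated against each subunit probe using pairwise complete cases
(probes with fewer than three complete pairs are left unscored as `none`).
The category is a function of (r_a, r_b) against r\*: both above → 
`both_positive`; both below −r\* → `both_negative`; both beyond |r\*| with
opposite signs → `discordant`; exactly one beyond → `a_only`/`b_only`; else
`none`. The subunit probes themselves are excluded because their
self-correlation is degenerate and the screen's object is their *targets*.
Probe→gene collapsing drops unannotated probes and uses the "any probe"
rule — a gene enters a category as soon as one of its probes does — which
is why probe counts exceed gene counts on multi-probe platforms.
Properties the tests enforce: the categories partition scored probes;
raising r\* can only shrink the both-significant sets; swapping subunits
maps a_only↔b_only and fixes both_\*; and the whole computation agrees
exactly (r to 1e−12, categories identically) with an independent
direct-formula recomputation on small matrices.

## Enrichment

Upper-tail hypergeometric over-representation: drawing n query genes from a
universe of N genes containing K set members, p = P(X ≥ k) for the observed
overlap k, identical to one-sided Fisher exact on the corresponding 2×2
table (asserted to 12 significant digits). The universe is always explicit
— the natural default is all annotated genes on the expression platform —
because enrichment p/q values are meaningless without it and
database-backed tools rarely expose theirs; results against different
universes are not comparable. BH FDR is applied across the supplied
collection with ties broken by a stable (p, set_name) sort for determinism.

## Region extraction and motif scanning

Coordinates are 0-based half-open internally (1-based only in reports).
"First exon", "intron 1/2" and "last exon" are defined on the specific
transcript in *transcript orientation*: for minus-strand genes the first
exon is the one with the highest genomic coordinates. Upstream/downstream
regions are 5 kb on the transcript's 5′/3′ side of the first/last exon,
clipped (not discarded) at chromosome ends so short toy contigs degrade
gracefully; intron regions exist only when the transcript has enough exons.
Region sequences are reverse-complemented for minus-strand transcripts so
every scan reads transcript-sense.

The scanner reports **every** start offset matching TTC + k unambiguous
bases + GAA for k ∈ {2,3,4}, including overlapping/abutting occurrences —
adjacent sites do occur in real promoters and greedy consumption would hide
them. The fixed flanks make spacer lengths structurally exclusive at one
start (if TTC·N₂·GAA matches, position 6 is A, so neither the N3 nor N4
frame can close with GAA there), a property the tests check on random
10-mers. Ambiguity codes never match any motif position (conservative).
Only the transcript-sense strand is scanned: the motif family is closed
under reverse complement (revcomp(TTC·s·GAA) = TTC·revcomp(s)·GAA), so hit
*counts* are strand-invariant and spacers are reported in the gene's
reading orientation. STAT6 flags follow its binding preferences: compatible
⇔ spacer N3/N4; preferred ⇔ N4 *and* located in intron 1 or 2.

**Published catalogue.** `th2axis.published` carries the reported motif
occurrences for six human TJ genes (CLDN4/7/12/15, TJP1/2, anchored to
GRCh38 transcript accessions) as raw cell strings plus region labels.
Spacer classes are never stored — every cell is re-scanned, which also
splits cells holding several abutting motifs. The typeset source table's
column boundaries are ambiguous for a few cells; region assignment was
curated so that the authoritative per-gene counts (N4 within the first two
introns: CLDN7 = 1, CLDN12 = 2, TJP1 = 7, TJP2 = 11; every gene ≥ 5 motifs
total and ≥ 2 N3/N4) hold, and those counts are what the acceptance script
recomputes.

## Synthetic-data generators

All generators derive independent substreams from one integer seed by fixed
spawn keys and are bit-reproducible.

**Expression.** Per sample a latent factor z ~ N(0,1); each subunit probe
is a·z + ε and each planted gene ±b·z + ε with ε ~ N(0, σ²) i.i.d.; null
probes are pure noise; a constant log2-scale baseline (8.0) is added for
realism of magnitude. The induced probe–subunit correlation is
ρ = ab/√((a²+σ²)(b²+σ²)). Defaults mirror a small case/control microarray
cohort: 12 + 6 samples, a = 0.9, σ = 0.5, 500 null probes. The screen's
recovery condition is exercised at b = 0.9, σ = 0.3, n = 12 (ρ ≈ 0.9,
comfortably above r\* = 0.576), where recovery of 20 planted genes is
complete. Because z itself is sampled, a group's realized latent variance
fluctuates (χ²ₙ₋₁/(n−1)); at higher noise or unlucky seeds recovery is
partial — which is the realistic regime, not a defect. Not modelled:
probe-level affinity effects, batch structure, heavy-tailed microarray
noise; passing tests therefore show the screen's statistical behaviour, not
robustness to platform artefacts.

**Cohort.** Analyte levels are 2^N(μ_g, σ) pg/ml per group g (lognormal,
right-skewed like serum cytokines); defaults give the case group ≈ 0.6–1.2
log2 units higher IL-4/IL-5/IL-6/IL-13 with n = 30 per group. Ct values
are normal per group (sd 0.4 cycles, a typical qPCR technical spread) with
a shared reference gene at Ct 18; the only planted receptor shift is a mild
IL13RA1 increase in cases (−0.4 cycles).

**Genome.** Background bases are i.i.d. at a configurable GC fraction
(default 0.41, human-like). Planted motifs are written into the
transcript-sense region sequence at the requested offset (an error if the
offset leaves the region, or if plants overlap). The emitted truth is a
brute-force oracle scan — implemented independently of the production
scanner, with explicit substring tests — applied to the final sequence, so
motifs arising spontaneously in the background are part of the truth rather
than rejection-sampled away; this keeps the generator simple and the truth
exact. No haplotype structure, repeats or isochores are modelled.

## Problem sizes and numerical choices

The acceptance script uses 2,000 null cohorts for type-I calibration, ten
≤ 20-probe matrices for screen/oracle equivalence, ten 10-kb sequences for
scanner/oracle equivalence and 1,000 random tables for the
hypergeometric/Fisher check — sizes at which the Monte-Carlo error of the
calibration estimate (binomial sd ≈ 0.005) is well inside the ±0.01 band
and the exact checks are exhaustive for their inputs. Oracle comparisons
use absolute tolerance 1e−12 on correlations and exact equality on
categories and hit lists. Degenerate inputs are defined, not patched
around: constant vectors are errors for Pearson, warnings + Mann-Whitney
for the gate; empty sequences scan to empty hit lists; empty record sets
collapse to empty gene sets.

## Known limitations

- The screen thresholds per-probe |r| only; it does not control FDR across
  probes, and the package deliberately leaves multiple-testing across
  analytes/probes to the caller where the original design did not apply it.
- Gene-level counts depend on the probe annotation supplied; annotation
  vintage shifts them.
- Enrichment results are only as meaningful as the chosen universe.
- The GEO series-matrix reader trusts the numeric table but never the
  metadata for grouping; the sample→group mapping must be supplied
  explicitly.
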