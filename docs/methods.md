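# Methods

## Overview

`enhancerstate` implements an integrative chromatin analysis around one
central object: the **silenced enhancer** — a distal TF binding site (TFBS)
enriched for 5-hydroxymethylcytosine (5hmC) and 5-formylcytosine (5fC) but
lacking the activating histone marks H3K4me1/H3K27ac, enhancer RNA (eRNA)
and nascent transcription, that can later gain activating marks and
upregulate its target genes in a lineage-specific way. The pipeline has
five computational stages (signal matrices → clustering → signature
labeling → transcription quantification → target mapping) plus a
synthetic-data generator that plants every phenomenon the pipeline is
supposed to detect, with ground truth written alongside.

## Coordinates and signal model

All coordinates are 0-based half-open (BED convention); gene tables are
read with explicit strand-oriented TSS/TTS columns. The "position" of a
region for all distance and profile computations is its integer midpoint.
Coverage is held in fixed-width bins (default 100 bp) per chromosome;
raw tracks store read counts per bin, and bedGraph input is rasterized by
length-weighted averaging so total mass (Σ bin value × bin width) is
conserved. Window queries treat the binned signal as a per-base step
function and pad with zeros beyond chromosome ends, so windows overhanging
a boundary are well defined. Chromosome names match by exact string
equality; regions on chromosomes missing from a track produce zero rows
and a warning.

RPKM normalization is the standard reads / (kb × million mapped reads)
on bin values. An optional cap (`compute_matrix(..., cap=...)`) clips
matrix values at a ceiling, emulating the saturated heat-map scale often
applied before clustering real data (10 RPKM at mammalian-genome library
scales). The analyses in this repository run **uncapped**: on a miniature
genome the RPKM floor scales inversely with genome size (background here
sits at tens of RPKM), so any fixed absolute ceiling meaningful for a
mammalian genome would saturate everything. The correlation-based
clustering distance is scale-free, so this choice does not affect cluster
recovery; capping remains available and is idempotent.

## Gene windows and transcription quantification

From a gene's TSS/TTS the standard run-on-sequencing windows are derived
(mirrored on the minus strand, clipped at 0):

* promoter: TSS − 1000 to TSS + 500
* gene body: TSS + 500 to TTS − 500
* 3′ end: TTS ± 500
* quantification window: TSS + 500 to TTS

Gene-level nascent transcription is RPKM of **sense-strand** reads in the
quantification window; the first 500 bp are excluded so promoter-proximal
polymerase pausing does not inflate gene-body estimates. Genes too short
for a positive-width window carry a missing value (NaN), never zero.
The eRNA readout at a region is the strand-summed GRO-seq signal in the
±2 kb window, since eRNAs are transcribed bidirectionally.

## Sorted trend analysis

To relate 5hmC to transcription without binning artifacts, regions are
sorted by 5hmC core signal (descending; ties broken by region name for
determinism) and the companion quantity is smoothed with a length-100
sliding window along that ordering (step 1, so n − 99 output points). The
reported statistic is the Spearman correlation between the smoothed key
and the smoothed companion. A sliding window rather than disjoint bins
matches the smooth trend curves conventionally drawn beside sorted
heat maps.

## Clustering

Distal TFBSs (> 2 kb from every annotated TSS) are clustered on the
column-concatenation of their ±2 kb / 100 bp signal matrices for
H3K4me1, H3K4me2, H3K4me3, H3K27ac, H3K27me3 and 5hmC. All other marks
(5mC, 5fC, Tet1, PolII, GRO-seq) are excluded from the feature space and
used only to characterize the resulting clusters.

The distance is the classic microarray-clustering "Pearson correlation,
absolute distance": d(x, y) = 1 − |r(x, y)|. Zero-variance profiles have
no defined correlation; a pair involving one is maximally distant (1)
unless both are constant and equal (0). This keeps all-zero "signal
desert" rows in the analysis with deterministic behavior instead of
dropping them.

Lloyd iteration assigns rows to the nearest centroid under this distance
and updates centroids as arithmetic means of members (the behavior of the
classic MeV implementation; a true correlation-optimal "K-profiles" update
is deliberately not used). Numerical choices:

* **Initialization** is k-means++-style: the first centroid is a random
  row, each next one is drawn with probability ∝ squared distance to the
  nearest chosen centroid. Uniform row sampling was tried first and
  regularly produced merge-one-archetype/split-another local optima at
  K = 10 because ten uniform draws rarely cover ten archetypes; D²
  seeding removed these failures entirely.
* An empty cluster is re-seeded with the point farthest from its current
  centroid (logged implicitly through determinism: the rule is exact).
* The mean update is not guaranteed to decrease a correlation-based
  objective, so a restart stops (keeping its previous state) if inertia
  would rise; inertia is therefore non-increasing within every restart.
* 10 restarts, max 100 iterations; the best restart by inertia (sum of
  member-to-centroid distances) wins. Everything is a pure function of
  (data, seed), and repeated runs are bit-identical.

## Cluster signatures and labels

Each cluster is summarized per mark by the mean core signal (±1 kb of the
region centers) over members. Flags are computed on a background-adjusted,
robust scale:

* the per-mark background is the median (across regions) of the signal in
  the outermost profile bins, where site-specific enrichment has decayed;
* the per-cluster summary used for flagging is the **median** member core
  mean, which one or two misassigned regions cannot drag (RPKM is heavy
  tailed); the reported `core_means` stay plain means;
* the per-mark reference scale is the median background excess across
  clusters, floored at half the background so marks present in only a few
  clusters still get a usable noise scale;
* enriched: excess ≥ 2.0 × scale; depleted: excess ≤ 0.5 × scale
  (both thresholds configurable).

A first design compared raw core means to their cross-cluster median; it
cannot work when a mark's Poisson background dominates, because a cluster
with zero true signal still sits at the background level and can never
fall below half the median. Background subtraction fixes this and changes
nothing in the low-background regime.

Labels are assigned by explicit rules — promoter-like (H3K4me3 ∧ GRO-seq
enriched), active-enhancer (H3K4me1 ∧ H3K27ac enriched), polycomb
(H3K27me3 enriched ∧ H3K27ac depleted), silenced-enhancer (5hmC enriched ∧
H3K4me1, H3K27ac and GRO-seq depleted), otherwise "other". At most one
cluster per run is labeled silenced-enhancer: among qualifying clusters
the one with the highest 5hmC-to-activating-signal contrast
(5hmC excess / mean activating excess) wins and the rest fall through to
the remaining rules. Label assignment is invariant to cluster numbering.

## Target mapping and the expression-change test

Nearest-gene assignment maps each region to the gene with the closest TSS
(ties to the lexicographically smaller gene id). ChIA-PET assignment calls
gene g a target of region r when one interaction anchor overlaps r by
≥ 1 bp and the mate anchor overlaps the promoter window TSS ± 2.5 kb
(configurable); anchors are stored in canonical order so the rule is
symmetric. "Gained" targets between two cell states are genes targeted in
state B by no region in state A.

The expression-change test compares per-gene log2((RPKM_B + 1)/(RPKM_A + 1))
(pseudocount configurable) of the target set against a background set
(default: all genes with valid expression in both states, minus targets)
with a one-sided Wilcoxon rank-sum test — chosen for robustness to the
skew of RPKM values; no distributional model of expression is assumed.
The reported statistic is the centered Mann–Whitney U (U − n₁n₂/2) so its
sign carries the direction, which keeps direction and statistic consistent
by construction. Genes with a missing value in either state are dropped
before testing; at least 3 valid targets and a non-empty background are
required.

Lineage activation fractions use first-activation accounting: lineages are
processed in order and a region counts only for the first lineage calling
it active, so a later lineage reports the *additional* activated fraction.

## Synthetic-data generator

The generator emulates, on a deliberately small scale, the data classes of
a multi-mark ESC chromatin study: one 5 Mb chromosome, 60 non-overlapping
genes (5–30 kb, one per layout slot, 80% expressed with lognormal
gene-body rates), and 600 TFBSs of width 200 bp drawn from ten archetypes
of 60 regions each. One archetype (promoter-like) is placed within 1.8 kb
of TSSs; the other nine are placed intergenically, > 3 kb from every TSS
and ≥ ~4 kb apart so the ±2 kb profile windows stay essentially
independent, which makes the "distal" filter recover exactly the planted
distal set.

Tracks are Poisson counts per 100 bp bin: a uniform background rate
(0.2 reads/bin) plus archetype-specific Gaussian bumps (sd 300 bp;
"bimodal" marks as two bumps at ±500 bp; "broad" domains at sd 900 bp)
whose peak heights carry lognormal jitter (σ = 0.3 — the generator's
noise-level parameter). Peak amplitudes (8–40 reads/bin for strong marks)
were chosen so peak-to-background ratios resemble saturated real ChIP-seq
heat maps; at much lower amplitudes Poisson noise makes profile
correlations within an archetype as weak as those between archetypes and
no clustering method could recover the planted states. 5mC is modeled as
a genome-wide plateau with a dip at every TFBS core. GRO-seq is
strand-split: sense-strand gene-body signal over each expressed gene's
quantification window, a promoter-pausing bump at the TSS, and divergent
bidirectional eRNA bumps only at archetypes with nonzero eRNA amplitude.
The silenced-enhancer archetype is validated at construction: 5hmC and
5fC amplitudes > 0, H3K4me1 = H3K27ac = eRNA = 0. Each track's declared
library size equals its realized total read count, so mass consistency is
exact.

Interactions wire a configurable fraction (default 0.5) of silenced
enhancers to the promoter (TSS ± 1 kb anchor) of a designated expressed
target gene; the differentiated ("NPC") state adds gained interactions for
the lineage-activated subset. Activation draws 9% (NPC) and an additional
20% (endomesoderm) of distal TFBSs, preferentially from the silenced
archetype, and the differentiated H3K4me1/2 tracks receive activating
bumps at those regions. Post-differentiation expression multiplies the
genes targeted by activated, newly wired enhancers by 4× (lognormal noise
σ = 0.15 on everything); all other genes jitter around no change.

Everything derives from one integer seed through tagged, independent
`numpy` Generator streams, and all writers use fixed formatting, so a
config + seed reproduces every output file byte-identically.

### What the generator does not emulate

Read-level artifacts (mappability, GC bias, fragment-length effects,
duplicates), peak-shape diversity, inter-chromosomal structure, copy
number, and any coupling between marks beyond the archetype means.
Passing tests therefore demonstrate that the operators are implemented
correctly and that the pipeline recovers planted structure at realistic
signal-to-noise — not that real datasets of any particular study would
yield the same clusters or p-values.

## Problem sizes and calibration checks

The default study (600 regions × 6 clustering marks × 40 bins, K = 10,
10 restarts) clusters in well under a second; a full pipeline run
(simulate → write → read back → matrices → cluster → characterize →
transcribe → targets → test) takes about a second. The statistical
calibration uses 1,000 null datasets (type-I error must land in
[0.03, 0.07] at α = 0.05) and 200 one-log2-shift datasets
(power ≥ 0.9 with 50 targets vs 500 background); the inverse
5hmC–transcription trend is required to be negative in 20/20 simulated
studies. These sizes keep the whole suite fast while leaving the checks
statistically meaningful.

## Known limitations

* The enrichment/depletion thresholds (2×, 0.5×) are explicit stand-ins
  for by-eye heat-map judgement; different thresholds shift which clusters
  get named, though the silenced-enhancer contrast rule is insensitive to
  moderate changes.
* The Wilcoxon test treats genes as independent; co-regulated gene sets
  violate this and real-data p-values should be read accordingly.
* K is fixed by the caller (default 10); no model selection is provided.
* bigWig tracks are not read directly; convert to bedGraph first.
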