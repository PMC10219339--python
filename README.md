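# fur-regulon

Reconstruction of a transcription-factor regulon from ChIP-seq binding and
RNA-seq differential expression, built around the ferric uptake regulator
(Fur) of *Escherichia coli*. Fur, loaded with Fe²⁺, represses iron-uptake
genes by occluding promoters near the −35/−10 elements and activates other
genes from sites further upstream; its regulon is therefore best read as a
set of *transcriptional units* (operons) whose promoter occupancy and
first-gene expression response are judged together.

The package is aimed at bacterial regulatory genomicists who have
condition-specific peak tables and differential-expression tables in hand
and want the integration logic — not the upstream read processing — as a
tested, reusable library.

## What it computes

Given a genome annotation (GFF3 + optional operon/TSS tables), two
condition-specific peak tables (±Fe, narrowPeak), and the four
transcriptome comparisons (wild type vs *fur* knockout, each ±Fe):

1. **Peak merging** — peaks overlapping across the two iron conditions
   become one peak with the *mean* fold enrichment `FE = (FE₊ + FE₋)/2`.
2. **Assignment** — each peak anchor (summit, else midpoint) is classed
   PROMOTER (inside the window upstream of a start codon, 300 bp by
   default), CDS (inside a gene body), or intergenic; one anchor covered by
   the windows of two divergently transcribed genes targets both units.
3. **Direct-target calling** — a bound unit is DIRECT iff its *first gene*
   (5′-most member) is a DEG (q < 0.01) in the wild-type vs knockout
   comparison in at least one iron condition. The sign of
   log2(knockout/wild-type) classifies the mode: positive → REPRESSED,
   negative → ACTIVATED.
4. **Motif discovery** — a ZOOPS (zero-or-one occurrence per sequence) EM
   finder fits a position weight matrix to the promoters of each mode
   group, with MEME-style starting-point search, register refinement, and
   a shuffled-sequence significance guard; promoters are then scanned for
   the best log₂-odds site and site centres are reported relative to the
   TSS.
5. **Comparative statistics** — Student/Welch t contrasts of binding
   strength (promoter vs CDS, repressed vs activated), mean ± SEM of
   absolute fold changes per mode, the iron-sensitivity sign test on
   paired ±Fe fold changes, the |FC|–binding-strength regression, and
   functional-category tallies. Small closed-form assay helpers (RPKM,
   ΔΔCt, soft-agar plate speed as the slope of diameter vs time,
   single-cell speed as path length / duration) live in the same module.

A forward simulator (`fur_regulon.simulate`) generates a complete toy
dataset with a planted regulon — known direct targets, modes, binding-site
positions, fold enrichments, and effect sizes — so that every stage can be
scored against truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic benchmark (200 transcriptional units, fixed seed):

```bash
python analysis/01_simulate.py
python analysis/02_reconstruct_regulon.py
python analysis/03_score_recovery.py
python analysis/04_motif_geometry.py
python analysis/05_comparative_stats.py
python analysis/06_worked_identities.py
```

which prints:

```
planted regulon: 58 direct of 90 bound TUs (44 repressed / 14 activated) across 200 TUs, 339 genes
peaks: 135 merged (80 promoter of which 10 divergent, 55 CDS) -> 90 candidate TUs
direct regulon: 58 TUs (44 repressed / 14 activated); 58 with iron, 19 without, 19 in both
recovery: precision 1.000, recall 1.000, mode accuracy 1.000 (58 TP / 0 FP / 0 FN)
REPRESSED: consensus GATAATGATTATCATTATC (30.5 bits, palindromicity 0.898), site median -20 bp vs TSS (n=44)
ACTIVATED: consensus TATTATTCAA (14.85 bits, palindromicity 0.474), site median -72 bp vs TSS (n=14)
binding strength promoter vs CDS: 7.37 vs 2.24 (p=9.30e-19)
binding strength repressed vs activated: 9.53 vs 4.59 (p=2.51e-06)
iron sensitivity REPRESSED: 1.00 of 13 genes respond more strongly with iron (sign test p=0.000244)
|fold change| vs binding strength: r=0.33 (p=0.0105, n=58)
```

Reading this: all 58 planted direct units are recovered with the correct
mode and no false calls; the repressed-site motif comes back as the
planted AT-rich near-palindrome centred ~20 bp upstream of the TSS while
activated sites sit ~72 bp upstream; promoter peaks are ~3× stronger than
CDS peaks and repressed-unit peaks ~2× stronger than activated-unit peaks;
repressed targets respond more strongly to the knockout when iron is
present, and the degree of regulation correlates weakly but positively
with binding strength. Summaries land in `results/`, bulky intermediates
in `scratch/`.

The same stages are scriptable from a shell via the `fur-regulon` CLI
(`simulate`, `merge-peaks`, `annotate`, `integrate`, `motif`, `run-all`,
`report`), each a thin wrapper over the library.

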