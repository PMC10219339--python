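# Methods

## The integration model

The unit of regulation is the transcriptional unit (TU): one or more
contiguous same-strand genes sharing a promoter. All calling logic anchors
on the *first gene* — the 5′-most member in transcription direction,
re-derived from coordinates rather than trusted from input order — because
a bacterial promoter controls the whole downstream operon and the first
gene is the member whose expression most directly reports promoter
activity.

A TU enters the candidate set when a merged ChIP peak is assigned to the
promoter of any of its genes. It is called DIRECT when its first gene
passes the DEG filter (adjusted p, i.e. q, strictly < 0.01) in the
wild-type versus knockout comparison in at least one iron condition; the
conditions supplying evidence are recorded separately so per-condition
counts, their intersection, and the union regulon are all available. The
union obeys |A ∪ B| = |A| + |B| − |A ∩ B| and this identity is asserted at
run time.

Fold-change direction is normalised at the I/O boundary: tables are stored
as log2(knockout / wild-type) and a `fc_direction` flag flips incoming
tables written the other way. Under this convention a positive first-gene
fold change (expression rises when the regulator is deleted) means
REPRESSED, negative means ACTIVATED. When both iron conditions carry
evidence with conflicting signs, the iron-replete value wins — the
regulator is fully cofactor-loaded there — and the conflict is logged,
never silently resolved.

DEG membership of the direct regulon counts *all* member genes of DIRECT
units, not only first genes: a multi-gene operon legitimately contributes
several DEGs to the direct fraction.

## Peak handling

Cross-condition merging pairs peaks that overlap by ≥ 1 bp (configurable);
each input peak joins at most one merged peak, best overlap first. The
merged fold enrichment is the arithmetic mean of the two condition values,
so it always lies between them, and evidence is conserved:
n(out) = n(in) − n(matched pairs).

Assignment anchors on the summit when the caller provided one, else the
interval midpoint; the summit is the sharper estimate of the binding
position. Promoter takes precedence over CDS when both apply, keeping the
two classes disjoint. The promoter window defaults to 300 bp upstream of
the start codon — wide enough to cover activator sites reported up to
~240 bp upstream — and is truncated, never failed, at contig edges. A peak
matching neither a window nor a gene body is retained with an INTERGENIC
class but excluded from the promoter/CDS tallies. Divergent-promoter
peaks (anchor between a leftward minus-strand gene and a rightward
plus-strand gene, inside both windows) target both TUs; same-strand
multi-window overlaps go to the gene with the nearest start codon.

Signed site/peak positions are reported relative to the TSS when a TSS
table is supplied and otherwise relative to the start codon, and outputs
are labelled accordingly; negative is upstream in both conventions.

## Motif discovery

The finder fits a ZOOPS mixture: a sequence carries no site with
probability 1 − γ, or exactly one site at a uniform position/strand. The
E-step computes exact posteriors over (presence, offset, strand) under the
current PWM against a 0-order background estimated from the input set; the
M-step re-estimates the PWM from posterior-weighted counts with a
pseudocount of 0.25 per base per column and updates γ (initialised at
0.8). The per-iteration objective (log likelihood plus the Dirichlet log
prior implied by the pseudocounts) is non-decreasing by EM theory and
asserted so in tests; the likelihood reported to users is relative to the
background-only model, whose per-base terms cancel inside the mixture.

Three design layers make the search reliable at bacterial-promoter scale:

* **starting-point search** — candidate w-mer seeds are taken at a
  deterministic stride across every input sequence, scored with a single
  E-step, and only the best few run to convergence (the classic
  subsequence-seeding strategy);
* **register refinement** — the winner is challenged by ±1–2 column
  shifts seeded from its MAP alignment, repeated in sweeps until no shift
  improves the likelihood, which removes the off-by-one phase optima that
  plain EM converges to;
* **significance guard** — the same fit is run on per-sequence shuffles;
  a winning likelihood not exceeding 1.5× that chance level means the
  input carries no consistent motif, and the returned matrix is flattened
  to the background composition (information content ≈ 0) with
  `significant=False`. This replaces an analytical E-value, which is
  deliberately out of scope; genuinely weak motifs near the chance level
  may be suppressed, which is the intended conservative behaviour.

Default widths are 19 for the repressed set (the classical extended
dyad-symmetric box) and 10 for the activated set (a much shorter,
asymmetric element); both are configurable. Scanning reports the maximum
log₂-odds window over offsets and strands, ties broken to the smallest
offset with + before −, and the site "position" is the centre of the hit
window relative to the anchor. Palindromicity is 1 minus the mean
per-column total-variation distance between the PWM and its reverse
complement (1 = perfectly dyad-symmetric). Because both strands are
searched, a motif is recovered in an arbitrary orientation; consensus
comparisons accept either.

## Statistics

Group contrasts default to Student's pooled-variance t-test (two-sided)
with Welch behind a flag; Welch is the safer choice when group variances
differ visibly, and both are reported with n, mean and SEM (sd/√n) per
group. The degenerate all-equal case returns t = 0, p = 1; zero variance
with unequal means is an error rather than an infinite statistic. Fold
changes entering the mode comparisons are linear ratios 2^|log2fc| with
the sign carried separately; log-scale summaries are emitted alongside.
The iron-sensitivity asymmetry uses a two-sided binomial sign test on
paired |fold changes| (±Fe), with exact ties counting for neither side.
The fold-change–binding relationship is ordinary least squares with
Pearson r and its two-sided p. No multiple-testing correction is applied
across this handful of descriptive contrasts. The assay helpers are pure
closed forms: RPKM = 10⁹·count/(length·depth); ΔΔCt relative expression
2^−ΔΔCt; plate swimming speed as the OLS slope of zone diameter vs time
(a radius mode halves it, since migration speed is conventionally radial);
single-cell speed as path length / duration.

## The synthetic benchmark

The generator lays out ~200 TUs (1–4 genes each, 600–1800 bp genes,
intergenic gaps 400–800 bp, plus ten divergent pairs sharing a 150–250 bp
intergenic region) on a single contig, assigns ~45% of TUs as bound and
~65% of bound ones as direct at a 3:1 repressed:activated ratio — within
a factor of two of the scale the integration is meant for, while running
in well under a minute. Every number drawn is recorded in a truth
manifest, and every output is a pure function of (config, seed).

Planted structure, chosen to mirror the contrasts the statistics must
detect: promoter-peak fold enrichments are lognormal (median ≈ 4) with a
2× multiplier on repressed targets; CDS decoy peaks are weaker (median
≈ 2) and planted deep in the 3′-most gene of a unit so no promoter window
can reach them; 20% of peaks appear in only one iron condition. Repressed
sites are a 19-bp AT-rich near-palindrome centred at −20 ± 10 bp from the
TSS; activated sites a 10-bp asymmetric element at −74 ± 15 bp; instances
are planted with 5% per-base mutation. Both motif strings are synthetic
fixtures chosen for shape (length, AT-richness, dyad symmetry), not
measured consensus sequences. Effect sizes are truncated normals —
|log2FC| ≈ 3 for repressed targets with iron, attenuated by ×0.3–0.6
without iron; ≈ 1.6 for activated targets, equal across conditions up to
small jitter — so repressed targets are the iron-sensitive group by
construction. The knockout's own ±Fe comparison is pure null (no DEGs).
About 30% of direct units also pass the DEG filter without iron,
reproducing the asymmetric per-condition call counts. Unbound "indirect"
units supply extra DEGs, a fraction of which (plus a fraction of direct
DEGs) populate the external small-RNA regulon list. q-values are drawn
directly from planted effect status through a monotone two-band model
rather than simulated from counts: the differential-expression engine is
an upstream producer whose output format, not internals, matters here.

Divergent pairs are generated bound-but-not-direct so each direct unit has
one unambiguous planted site position relative to its own TSS; divergent
*calling* is exercised by the classifier tests and the planted divergent
peaks themselves.

What the benchmark does **not** emulate: read-level noise, peak-caller
boundary jitter beyond a few bp of summit jitter, replicate structure,
correlated condition effects, operon-internal promoters, or any real
genome composition. Passing recovery tests therefore demonstrates the
integration logic is correct on clean inputs with known truth, not that
the thresholds are optimal for any particular real dataset.

## Numerical choices and degenerate inputs

EM convergence: objective change < 1e-6 or 200 iterations; five restarts
after the starting-point search. Likelihood computations are done in log
space with the max-subtraction trick. Non-ACGT characters are treated as
N: scored as background, excluded from counts. Empty motif groups
(< 5 promoters) are skipped with a warning rather than fitted. A TU table
overrides gap-based operon inference (same-strand adjacency, gap ≤ 50 bp)
whenever supplied; inference is a fallback heuristic, not a claim about
any curated operon set. Promoter windows fully truncated away (a gene at
the contig edge) yield no window rather than an error. Peaks with
non-positive fold enrichment, q-values outside [0, 1], mixed-strand TU
tables, and intervals on unknown contigs all fail fast with named errors.

## Problem sizes used in the checked runs

The benchmark runs 200 TUs / ~340 genes on a 1.2 Mb contig; the
qualitative-structure suite draws 200 independent generator runs
(sequence generation skipped — truth-level draws plus real merge/classify
on each); the statistics oracles use 200 random cases per operation at
1e-9 relative tolerance. These sizes keep the default test suite and the
acceptance script in the minutes range on a single CPU while leaving the
statistical contrasts well-powered.

## Known limitations

Bound-but-silent promoters are reported, never interpreted — deciding
whether they are condition-specific regulation or non-functional binding
is outside the data. The merge step assumes the upstream caller removed
within-condition overlaps. The significance guard calibrates against
mononucleotide shuffles only, so low-complexity periodic signal could in
principle pass it. The first-gene criterion will miss operon-internal
promoters regulating downstream members independently.
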