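# Methods

This note documents the models, conventions and design choices behind
`xlsite`, in the order the pipeline applies them.

## Coordinates, orientation and records

All genomic coordinates are 0-based half-open; BED output is native, SAM
input is converted on read. Offsets in every profile are in **transcript
orientation** with the cross-link site at 0: negative offsets are 5'
(upstream) on the transcript. For minus-strand sites the reference is read
as its reverse complement and offsets are mirrored.

A mapped cDNA carries its chromosome, strand, interval, optional random
barcode and the genomic positions of single-nucleotide deletions. Deletions
are modelled as single-nucleotide events throughout — the dominant class in
UV-C cross-linking data; consecutive multi-nucleotide deletions (typical of
microsatellite variation rather than cross-linking) are out of scope.

## Site derivation and duplicate collapsing

The truncation site of a cDNA is the nucleotide 5'-adjacent to the read in
transcript orientation: `start − 1` on the plus strand, `end` on the minus
strand. Reads whose site would fall before the chromosome start are skipped
and tallied. Truncation-site lists use deletion-free cDNAs only, because
deletion-bearing cDNAs are predominantly read-through and their 3' ends do
not mark cross-link sites.

When a read has several deletions, only the one closest to the read's 5'
end is kept. Barcoded duplicates (same barcode, chromosome, strand and 5'
starting position) collapse to one molecule; the retained deletion is the
most frequent in the group, frequency ties resolved toward the read 5' end.
Barcode-free libraries are joined purely by starting position, equivalent to
giving every read the same barcode. Groups mixing deletion-free and
deletion-bearing reads are not covered by the published rules; they resolve
by majority with ties favouring deletion-free, the conservative choice for
truncation analysis (logged so users can audit).

Analyses refuse libraries with fewer than 10,000 unique cDNAs by default
(`min_library_size`, overridable), matching the working threshold for
usable libraries.

Deletion proportions are computed in a fixed read-relative window (default
25 nt from the 5' end) so that libraries sequenced to different lengths are
comparable; a window longer than every read reproduces the unwindowed
count.

## TTT re-definition of deletion sites

Reverse-transcriptase slippage makes one-base deletions concentrate in
homonucleotide runs, where the deleted base is ambiguous. Aligners resolve
the ambiguity systematically toward the highest genomic coordinate of the
run. In transcript terms this parks plus-strand deletions at the 3' end of
a uridine tract and minus-strand deletions at its 5' end, so the two
strands' motif profiles disagree by two nucleotides.

The correction inspects the 3-nt window at transcript offsets −2..0 for
plus-strand sites and 0..+2 for minus-strand sites. Both denote the genomic
window `[d−2, d]`; it reads TTT on the transcript when the genomic bases
are TTT (plus) or AAA (minus). If so, the site moves to the window middle,
`d − 1`. Note the alternative reading — treating the minus-strand window as
genomic `[d, d+2]` — would make the rule strand-symmetric in transcript
space and could neither produce nor correct the observed two-strand shift;
the transcript-orientation reading is the one under which the correction
works, and is what the package implements. Re-defined sites that collide
with existing sites merge with summed counts, so the total deletion count
is conserved.

The rule is applied once (matching the one-shot published procedure). It is
tested as literally written: the specific 3-nt window only, no re-centring
over longer runs. Inside runs longer than four bases repeated application
would keep shifting; the property tests therefore assert a fixed point
after at most two extra passes on sequences whose runs are ≤ 4 nt.

## Read-through mixture model

An iCLIP library is modelled as a two-component mixture: a fraction `f` of
read-through cDNAs with per-read deletion probability `p_RT`, and `1 − f`
truncated cDNAs with background probability `p_BG`. `p_RT` is estimated
from a CLIP library (which contains only read-through cDNAs), `p_BG` from
mRNA-Seq, assuming the shared reverse-transcription and sequencing protocol
gives the same deletion process — a modelling assumption that cannot be
verified internally. Solving `p_iCLIP = f·p_RT + (1−f)·p_BG` gives `f`; the
Bayes fraction `k = f·p_RT / (f·p_RT + (1−f)·p_BG)` is the read-through
share among deletion-bearing cDNAs; removing those from the read-through
pool gives the read-through share among deletion-free cDNAs,
`(N·f − n_del·k)/(N − n_del)`, where `n_del` counts cDNAs with a deletion
anywhere in the read.

All three formulas use the 25-nt windowed proportions, which is the
combination that reproduces the published numbers exactly. Proportions are
carried as exact rationals (`fractions.Fraction`) until the final division,
so count-table reproductions are bit-stable. Inputs violating the ordering
`p_BG ≤ p_iCLIP ≤ p_RT` clip the result into [0, 1] with a warning;
`p_RT = p_BG` is rejected as unidentifiable. Printed percentages follow the
source-table convention: one decimal below 10%, whole percents above.

## Motif profiles and the randomized background

Motifs are IUPAC strings matched with overlaps counted (YCAY instances can
overlap by one base). A motif "at offset o" has its transcript 5' base o
nucleotides from the site; `closest_motif` keeps, per site, the instance
minimising |o|, with exact ties resolved upstream (negative offset). The
motif **start** is the distance anchor — the recorded quantity is the
starting position — rather than the nearest motif edge; this is a
documented choice where both readings are defensible.

Sites in unstranded (intergenic) context are evaluated on both strands at
half weight each. The background model re-positions each site uniformly
within its containing annotated segment (same strand, original position
redrawable), recomputes the occurrence profile, and averages over
`n = 100` randomizations in a ±50 nt window. Enrichment is the per-offset
observed/background ratio; a smoothed track averaging offsets −2..+2 damps
fluctuations before reporting the longest contiguous region above a
threshold (two-fold by default). Offsets with zero background are reported
missing rather than infinite.

Profile windows default to ±30 for display and ±50 for the background,
both configurable. Windows truncated by chromosome ends simply contribute
nothing at the affected offsets (tallied in logs).

## YCAY score and cluster segmentation

The YCAY score of a position counts motif instances completely contained in
the 41-nt window centred on it (20 nt each side; positions within 20 nt of
a chromosome end use the truncated window). Genomic tracks count instances
on both strands by default, since transcripts may lie on either; scoring a
known sense sequence uses one strand.

Segmentation follows a five-step peak-joining rule: find local maxima;
zero-score valleys terminate clusters where the score reaches zero;
otherwise a valley below 0.9× the smaller flanking maximum splits the
cluster at the middle of the minimal-value run, and a valley at or above
that bound joins the peaks. Three conventions the rule leaves open are
fixed as: a plateau of equal values flanked by strictly smaller ones is a
single maximum anchored at its midpoint; maxima are processed left to
right, re-comparing after each join, which makes the result deterministic;
and a valley exactly at 0.9× the smaller maximum joins (the split applies
only when the valley is strictly smaller). Clusters are disjoint and cover
every positive-score position.

Each cluster's score is its maximum track score; clusters containing at
least one cross-link site (three or more are required) enter a Spearman
rank correlation between cluster score and the highest site cDNA count in
the cluster, with average ranks for ties and an asymptotic two-sided t
p-value (via `scipy.stats.spearmanr`; the test suite checks it against an
independent rank-formula computation).

## Synthetic data

The generator builds chromosomes of uniform ACGT sequence with planted
features: YCAY clusters (per cluster: a motif count and spacing; spacers
are drawn from A/G so planting cannot create accidental YCAY or TTT
instances) and TTT runs with non-T flanks so each run has exactly its
requested length. Segments alternate genic/intergenic blocks — enough
structure for segment randomization without a gene model. Each chromosome
draws from a deterministic sub-stream of the seed, so adding chromosomes
never perturbs earlier ones, and identical configs give byte-identical
outputs.

One cross-link site is planted one nucleotide transcript-upstream of every
motif, so the motif sits at offset +1, matching the dominant UV-C
truncation mode (a `truncation_offset` of 0 gives the alternative mode in
which cDNAs truncate directly at the site). Site occupancy weights equal
the local YCAY score of the realized sequence, so planted cDNA counts track
motif density — the regime in which score/count correlation is expected to
be high.

Each simulated cDNA picks a site by occupancy, becomes read-through with
probability `f` (5' end overshooting the site by 1–15 nt) or truncated
(starting one nucleotide 3' of the site), and carries at most one deletion:
read-through reads delete with probability 0.11, truncated reads with
0.004 (the study-scale rates), placed within the first 25 nt of the read.
Read-through deletions are weighted 10× toward homonucleotide runs (≥3 nt)
and 5× toward the ±2 nt around the site; any in-run deletion is then
shifted to the run's highest genomic coordinate, emulating the aligner
ambiguity that the TTT re-definition corrects. Random barcodes
(9 nt default) are attached per molecule and PCR duplicates appended with a
geometric copy count (rate 0.2 default). Read lengths are normal around
50 nt (sd 8, minimum 30) — the published protocols target ~50 nt cDNAs but
state no length distribution, so this is a package choice, not a claim
about the data.

What the generator does **not** emulate: sequencing errors and quality
scores, alignment artefacts beyond the homopolymer shift, gene-expression
heterogeneity between transcripts, multi-nucleotide deletions, and genomic
variation. Passing recovery tests therefore show the estimators are
correct under the stated generative model, not that real libraries satisfy
that model.

## Problem sizes used in the test suite

The parameter-recovery study uses libraries of 50,000 cDNAs (iCLIP at
planted f ∈ {0.05, 0.18, 0.5, 0.9}, plus CLIP and mRNA-Seq companions) on a
50 kb genome with 15 planted clusters, over a five-seed panel; recovery is
judged against three delta-method standard errors with all three
proportions estimated. On a toy genome, joining barcode-free reads purely
by position is lossy (start-position collisions between distinct molecules
are unavoidable at these densities), so the recovery study collapses all
libraries by barcode; `join_no_barcode` is exercised separately at
collision-free scale. The score/count recovery uses a 40 kb genome with
twelve clusters spanning density levels 1–12 and 20,000 truncation-only
cDNAs, giving a rank correlation ≥ 0.9 across seeds. Oracle-equivalence
checks run the brute-force window counter over 200 random 300-nt sequences.

## Known limitations

* Real-data quantities that depend on the original sequencing libraries
  (absolute enrichment factors, per-gene correlations, motif-variant
  percentages at real sites) are covered qualitatively by the recovery
  tests, not numerically.
* The mixture model ignores overdispersion: cDNAs are treated as
  independent Bernoulli trials, so no confidence interval is attached to f.
* Cluster segmentation processes maxima left to right; a right-to-left pass
  could split differently in rare symmetric configurations.
* The background model assumes each site lies in exactly one segment;
  overlapping annotations should be flattened first.
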