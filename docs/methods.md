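# Methods

`methylselex` analyses HT-SELEX experiments run in parallel on unmodified
and fully 5mC-methylated DNA libraries, with the goal of resolving how
methylation reshapes a transcription factor's monomeric versus homodimeric
binding and, within the homodimers, the preferred half-site orientation and
spacing. Because the statistics involved (k-mer enrichment, E-MI,
seed-based PWMs, half-site grammar, peak statistics) are easiest to trust
when they can be exercised against a known truth, the package includes a
generative SELEX model; every analysis stage is validated against libraries
simulated from explicit binding parameters.

## The binding model and simulator

A ligand (read) is scored by a linear-occupancy model:

    weight(read) = w_mono * sum_windows exp(E(window))
                 + sum_pairs gamma(orientation, spacing) * exp(E(w1) + E(w2))
                 + 1e-9

where the windows run over both strands of the read, `E` is an additive
per-position log-affinity over the half-site frame (consensus bases 0,
deviations negative, in natural-log units), and ordered window pairs are
classified by strand combination — (+,+)/(−,−) direct repeat, (+,−)
head-to-head inverted repeat, (−,+) tail-to-tail everted repeat — and by
the gap in bases between the two spans. Windows below an energy floor
(default −10) contribute nothing; the pseudo-weight 1e-9 keeps weights
positive. There is no saturation: linear occupancy is the simplest model
that produces the exponential per-cycle enrichment the analysis stages
assume.

Methylation is a library-level state (the amplification chemistry converts
every C on both strands), not a per-base mark, so the model carries:

* `methyl_delta`: per-position energy increments applied to a C or G (the
  5mC on either strand) in the half-site frame, with keys −1 and L
  addressing the two flanking positions;
* `gamma_methylated`: an optional cooperativity map used when the library
  is methylated.

The second knob exists because a position-additive delta provably cannot
re-rank an abutting dimer above a spaced one: any flank/spacer bonus the
spacing-0 configuration can realize (its junction bases are fixed by the
half-site) is also realizable by the spacing-1 configuration, whose spacer
base is free. Methylation effects that depend on the spacing of the dimer —
precisely the phenomenon of interest — therefore require
methylation-dependent cooperativity.

One selection cycle draws `round(selection_fraction * N)` reads
multinomially with probabilities proportional to weight, then resamples
with replacement back to the library size (PCR without an error model —
substitutions would blur the ground truth without serving any tested
claim). Cycle 0 is i.i.d. uniform over ACGT in the random region, with
fixed flanks; a consensus sequence can be planted into a chosen fraction of
cycle-0 reads for enrichment-trajectory experiments.

### Reference ground truth and its calibration

`default_binding_model()` encodes the study conditions used by the
simulation tests: half-site `YAATYA` preferring C at both Y positions
(T tolerated at a penalty of 0.8), mismatch penalty 1.5, monomer weight 2,
cooperativity peaked at ER1 (150) without methylation and at ER0 (150) with
it, a 25 : 150 ratio between the two ER peaks, mid-strength DR3–5/IR6–8
configurations over a 0.05 baseline, and methyl deltas of −0.3 at the two
Y positions (weakening every cytosine-containing site and hence the
monomeric path, without flipping the C preference). The default selection
fraction is 0.35 per cycle; harsher bottlenecks lose too many of the rare
one-mismatch carrier reads to drift at desk scale.

Two constraints shaped these numbers, both consequences of desk scale. At
the default library size of 1e4 reads x 40-nt random regions, an exact
12-bp dimeric arrangement is expected in ~0.3 reads — effectively absent —
so the configurational signal must be carried by one-mismatch arrangements,
which requires soft mismatch penalties. At the same time a chance
exact-consensus arrangement of a *non-peak* configuration (present in a
quarter of libraries) must not outweigh the peak configuration's
one-mismatch carriers, which requires the cooperativity gap between the
peak and every other configuration to exceed e^penalty. The frozen defaults
satisfy both (150/25 = 6 > e^1.5 ≈ 4.5). These parameters are simulator
settings chosen once to place the simulation in the regime the analysis is
meant to detect; they are not estimates of any real TF's biochemistry.

## K-mer statistics

K-mers are counted over every window of the random region, forward strand
of the read only (the merged-read orientation is arbitrary but consistent;
double-counting both strands would distort totals), so
`total = n_reads * (L - k + 1)` exactly. Enrichment of a k-mer is its
final-cycle frequency over its cycle-0 frequency, both pseudocounted by
`0.5/total`; cross-library comparison takes the union of the top-n most
abundant k-mers of each library (default n = 100) and reports a sign test
plus the mean log2 enrichment difference. The mean difference is reported
because at desk scale each library's top-abundance list is dominated by
windows of its own amplified winner reads, so the per-k-mer sign count
splits evenly even when the enrichment magnitudes clearly favor one
library.

Log-linearity of a trajectory is an OLS fit of log2(freq + pseudo) on the
cycle index; an all-zero trajectory reports R² = NaN rather than 0.

### E-MI

E-MI quantifies dependence between 3-mers at two non-overlapping positions
(j ≥ i + 3): the joint 64 x 64 table over reads is pseudocounted (1 per
cell) and the statistic sums `f(a,b) * log2(f(a,b)/(f(a) f(b)))` over the
ten most frequent cells. Cell *selection* uses the first half of the reads
and frequency *estimation* the second half: ranking and scoring the same
counts inflates the statistic by ~0.01 bits at 1e4 reads even under perfect
independence (the top order statistics of ~Poisson(2.4) cells are
necessarily above expectation), whereas the held-out estimate is unbiased
under the null (measured null maximum ~0.003 bits) and leaves planted
dependence and the symmetry E-MI(i,j) = E-MI(j,i) intact. The definition is
recorded in the pipeline's output metadata so results are self-describing.

## Motif construction and matching

PWMs are built from IUPAC seeds by multinomial counting: column c counts
base frequencies over random-region windows (both strands; reverse-strand
windows contribute complemented bases) that match the seed at every
position except up to `multinomial_level` positions including c (default
level 1; level 2 is used for the long dimeric seeds, whose exact instances
are rare at desk scale). Counts are pseudocounted (1 per cell); with a
background library (cycle 0), its counts scaled to equal per-column match
totals are subtracted, floored at the pseudocount, before normalization.

Match significance is exact: log-odds scores against a background (uniform
by default — SELEX random regions are near-uniform) are discretized to an
integer lattice of ≥ 1e4 levels, the distribution of the lattice score of
a random background w-mer is computed by column-wise convolution, and the
threshold is the smallest lattice score whose tail probability is ≤ the
requested p (reported alongside as `p_actual`). Matching uses the same
lattice, so the threshold's tail probability is exactly the match
probability of a background window; the DP distribution is verified against
brute-force enumeration over all 4^w sequences in the test suite. Motif
enrichment divides hits in a library by hits in its mononucleotide-shuffled
version (+1), at p = 1e-5 by default.

The methyl-vs-normal positional comparison aligns two PWMs from column 1
over the narrower width and calls each position "+" when the C+G
probability rises by more than τ = 0.05 upon methylation, "−" when it falls
by more than τ, and "·" otherwise; comparisons are made per configuration
pair (ER0 with methyl-ER0, ER1 with methyl-ER1) — cross-configuration
column alignment is not attempted, and positions are numbered from the
first PWM column.

## Half-site grammar

`YAATYA` is the default half-site (6 nt): it is the definition that
reproduces the printed names of the validation probes (the ER0 probe core
GATTG|CAATCA scans to a − strand match abutting a + strand match; the
5-nt alternative does not), and the shorter variant remains available as a
parameter. Orientation follows nuclear-receptor-style convention: (+,+) or
(−,−) DR, (+,−) IR (head-to-head), (−,+) ER (tail-to-tail); spacing is the
gap in bases between the half-site spans, and overlapping spans are
excluded from dimer calls (the smallest named spacing is 0). Probe
classification picks, among valid pairs, the one with fewest total
mismatches, then smallest spacing, then orientation (DR < ER < IR), then
leftmost position. The orientation key is deliberately placed before the
positional tie-break: a pure leftmost rule would make the call depend on
which end of the molecule is written first, breaking reverse-complement
invariance when two pairs of different orientation tie on mismatches and
spacing.

## Ranking dimeric configurations of a selected library

Every orientation x spacing seed up to the maximal spacing (default 10) is
used as a detector: windows on both strands of the *full* reads matching
the seed with at most one mismatch are counted (full reads because binding
sites may straddle the random-region/flank junction — selection sees the
whole ligand). Configurations are ranked by this count; the ratio to the
count in a shuffled copy of the library is reported per configuration but
is not the ranking key, for two desk-scale reasons: per-configuration
shuffled counts are tiny Poisson draws whose noise flips near-ties, and a
PWM trained on a post-selection, PCR-collapsed pool degenerates into a
detector of the dominant duplicated reads regardless of which seed it was
built from. The tolerant count is comparable across configurations because
every seed carries the same twelve informative positions.

## Genomic statistics

All coordinates are 0-based half-open. TSS density profiles place each
match at the strand-oriented offset of its 5'-most base relative to the TSS
(upstream negative), count matches on both strands for models passing the
mean-IC > 0.3 filter, and normalize per offset by the number of genes whose
offset lies inside the contig. Promoter target assignment gives a match to
every gene whose window [TSS − 1000, TSS + 200] (strand-oriented,
configurable) contains the match midpoint.

Peak-set overlap counts peaks sharing ≥ 1 bp; the reported `shared` is
min(#A overlapping B, #B overlapping A), making the table symmetric under
swapping the sets. The Fisher 2x2 tiles the genome into bins of the pooled
median peak width and cross-tabulates bin coverage by the two sets
(two-sided p). Motif containment of the top-3000 peaks (rank: descending
narrowPeak signalValue, ties by chromosome and start) is reported overall
and in 10 rank-contiguous bins of 300 peaks, which serve as replicates for
between-library t-tests on the proportion; peak-intensity comparisons
between peaks containing exactly one of two motifs use a two-sided Welch
t-test with "*" at p ≤ 0.05, "ns" above, and "na" when a group is
degenerate.

## Synthetic genomic fixtures

`simulate_genome` builds a single-chromosome genome of evenly spaced genes
on alternating strands, optionally planting a sequence at a fixed
gene-oriented offset from every TSS; `simulate_peaks` builds toy peak calls
in which a chosen fraction of peaks carries a planted motif. Both accept an
`exclude` predicate used to rejection-sample the background, so "motif-free"
stretches are genuinely free of whatever the caller's matcher detects —
this is what makes containment proportions and density spikes exact in the
tests rather than approximate.

## What the simulations do and do not show

The simulator reproduces the features the analyses rely on: exponential
enrichment of high-affinity classes, position-pair dependence from planted
dimeric sites, methylation-dependent re-ranking of configurations, and
library-scale monomer-versus-dimer contrasts. It omits sequencing error,
PCR substitution, bead/washing kinetics, protein-concentration titration
and carryover between cycles, and its libraries are 3–4 orders of magnitude
shallower than a sequenced SELEX pool, which is why one-mismatch
arrangements rather than consensus sites carry the signal. Passing tests
therefore demonstrate that the statistics recover known truth under the
stated model, not that the model captures any particular TF's biochemistry.

## Problem sizes used by the test suite

The simulation tests run at 1e4 reads x 40-nt regions x 5 cycles (20
replicate pairs for the configuration-switch check), 3e4 reads x 3 cycles
for the k-mer skew contrast, 3000 peaks for the containment fixture and
exhaustive enumeration up to w = 8 for the PWM p-value oracle. These sizes
were chosen as the smallest at which the tested effects are stable across
seeds.
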