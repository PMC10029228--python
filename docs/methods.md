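# Methods

This note records the models behind `synteny3d`, the parameters that
matter, what the simulator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The scientific setting

Closely related plant species (the package's demo system is modeled on a
cotton-tribe trio: a fused-karyotype reference plus two relatives)
differ by chromosomal inversions, translocations and fusions/fissions.
The analyses ask three questions: (1) are synteny breaks — the junctions
between collinear ortholog blocks — non-randomly placed with respect to
A/B compartments and TAD boundaries; (2) do compartments switch state
preferentially next to breaks; (3) do rearrangements increase, and TAD
conservation buffer, ortholog expression divergence.  All statistics are
enrichments and rank tests, so the package's correctness claims are
phrased as recovery and calibration on simulated data with planted
truth.

## Forward model

Genomes are gene-centric: `genes_per_chrom` genes of fixed 2 kb length
(expression contrasts, not length effects, are under test) are placed
along chromosomes of `genes_per_chrom x gene_spacing` bp (default
spacing 10 kb).  Compartments are planted as alternating A/B runs of
6–14 bins at 50 kb; gene placement density is 2:1 in A versus B, which
is what lets gene density orient the compartment eigenvector (A =
gene-dense), mirroring the biology of plant chromosome arms.  TADs tile
each chromosome as 80–200 kb domains separated by 10–20 kb gaps — the
plant convention of domains interspersed with non-TAD intervals rather
than side by side.

Rearrangement events are expressed in gene-index coordinates and cut the
genome at midpoints between genes, so no gene straddles a junction.
Provenance is tracked exactly as origin segments and composes across
rounds; a planted breakpoint is emitted at every junction between
segments of distinct ancestry or flipped orientation (a pure fission
creates chromosome ends, not internal junctions, and therefore plants no
breakpoint).  By default the pipeline snaps event cut points (by at most
8 genes) to the nearest inter-TAD gap of the ancestral architecture:
breakpoints in real genomes arise preferentially in open chromatin at
fragile domain boundaries, and this bias is precisely the co-localization
signal the downstream statistics measure.

Contacts are Poisson draws around

    mu_ij = depth * d^(-alpha) * P_ij * T_ij * b_i * b_j

with `d` the distance in bins (the diagonal treated as distance 1),
`P_ij` the compartment plaid factor (default contrast 1.6 when two bins
share a label), `T_ij` the TAD factor (2.0 within one true domain), and
`b` lognormal bin biases (sd 0.25), optionally modulated by simulated
effective-length/GC/mappability covariates so the Poisson-regression
normalization has something real to remove.  The plaid factor ramps in
linearly with distance and reaches full strength at 100 kb: short-range
contacts are decay-dominated and compartment-blind in real maps, and a
full-strength plaid at 5 kb resolution would corrupt insulation
structure that no real map shows.  Default `depth` is 80 expected counts
at one-bin distance.  In `ancestral_preserving` mode, pairs spanning
segments of different chromosomal origin within one fused chromosome are
dampened by 0.3 (the study system reports the phenomenon, not a
magnitude; 0.3 gives an unmistakable same-origin > different-origin
contrast at every distance).

Expression: each ortholog pair shares a baseline log10 expression
`N(1.0, 0.6)` (RPKM ~ 10); a divergence factor `f` splits the species
symmetrically by `log10(f)` with random sign, so |e1 − e2| grows with
`f`.  Counts are Poisson with mild lognormal replicate depth factors.
The pipeline plants factor 2.0 on orthologs near breaks and 1.5 on
orthologs in rearranged TADs — except inside conserved TADs, which is
the buffering the proximal-vs-distal contrast is designed to show as
non-significant.

What the simulator does **not** emulate: nucleotide sequence,
restriction-fragment structure, read-level noise, mappability shadows,
copy-number variation, trans compartment structure, or realistic
chromosome-length heterogeneity.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under a faithful
binned-count model, not robustness to every artifact of real Hi-C
libraries.

## Normalization

ICE balancing masks bins with zero marginal plus the lowest 2% of
positive marginals (a HiC-Pro-like convention), then iterates a
square-root-damped correction (`b *= sqrt(s/mean(s))`) until the row-sum
CV drops below 1e−5 (default; 200 iterations max).  The damped update is
used because the plain division update oscillates on symmetric matrices.
Masked bins propagate as NaN, never as zero.  The balanced matrix agrees
with an independent two-sided Sinkhorn scaling to better than 1e−8
relative when both are run to convergence.

The Poisson-regression normalization fits, per chromosome on cis pairs,
`value ~ log(len_i len_j) + log(gc_i gc_j) + log(map_i map_j)` with
distance-decile fixed effects absorbed, subsampling pairs above 200 000
for the fit.  Values are divided by the exponentiated covariate part
only — the decile effects estimate decay and are deliberately not
divided out, so the normalized matrix still decays and remains usable
for the distance-decay analyses.  The order is fixed ICE → Poisson
regression.

## Compartments

Per chromosome, O/E rows (NaN filled with the neutral value 1) are
correlated (Pearson), the leading eigenvector of the correlation matrix
extracted, and the sign oriented so that correlation with gene density
is non-negative; A = positive loading.  Chromosomes whose orientation
correlation is below 0.3 are flagged for review rather than silently
labeled; there is no PC2 fallback.  Genes map to the bin containing
their midpoint.  Switch states between species are the four-way product
of the two labels; the break-adjacency test is a two-tailed Fisher exact
test per state on {adjacent within ±10 kb vs background} × {state vs
other}, with Benjamini–Hochberg q-values reported across the four states
alongside the raw p-values.

## TADs

The insulation score of bin *i* is `log2` of the mean contact in the
`w x w` square crossing *i* (window 50 kb = 10 bins at 5 kb) over the
chromosome-wide mean of that statistic; it is invariant to global
scaling.  Boundaries are local minima with prominence ≥ 0.3 (boundary
region = minimum bin ± 10 kb).  The prominence default was co-designed
with the forward model's default depth so that planted boundaries are
recovered with headroom while Poisson noise minima inside domains are
not called; at 0.1 the caller admits noise dips and boundary precision
drops well below the recovery targets.  Candidate domains between
successive boundaries are kept only if ≥ 25 kb and the intra-domain mean
O/E exceeds the mean of equally sized flanks by ≥ 1.2; rejected spans
become inter-TAD intervals, so domains ∪ boundaries ∪ intervals tile the
chromosome.  Note that raising the prominence threshold monotonically
reduces the number of *boundaries*; the number of retained *domains* can
occasionally move either way because merging two rejected candidates may
produce one acceptable one.

Conserved TADs: a species-1 domain with more than four syntenic genes is
conserved when more than 50% of them land in the single best-covered
species-2 domain (ties break toward larger reciprocal overlap, then
leftmost); an `any-domain` counting mode is available behind a flag.
Domains with ≤ 4 syntenic genes are unassessed.

## Synteny

Anchors are retained homolog pairs (e ≤ 1e−5 and mutual top-5 by score)
in gene-rank coordinates, with consecutive tandem duplicates collapsed.
Blocks are maximal monotone chains (both orientations) extracted
greedily by dynamic programming; transitions spanning more than 30
intervening genes on either side are forbidden.  Block significance is a
seeded Monte-Carlo p-value: anchors are re-placed uniformly and the
longest increasing/decreasing subsequence inside the block's rank
windows compared to the observed anchor count; blocks at p ≥ 0.05 are
discarded.

A chain may legally bridge across a nested rearranged segment (an
inversion's flanks connect through its center) or across an excision gap
via a spurious anchor, leaving blocks whose species-1 ranges overlap or
silently span a junction.  Blocks are therefore rebuilt from the run
decomposition of anchors along species 1: isolated off-diagonal anchors
(both steps skewed ≥ 10 genes the same way) are dropped, runs are
re-split wherever the gap allowance is violated, and runs shorter than
3 anchors dissolve into their neighbours.  Breaks are emitted between
adjacent runs whose species-2 sides are discontiguous: different
chromosome (fusion/fission when both blocks reach within 5 genes of
their species-2 chromosome ends, else translocation), flipped
orientation (inversion), or a species-2 gap exceeding the species-1 gap
by more than 30 genes or out of order (unclassified; the gap *difference*
is used because a plain unanchored stretch widens both gaps alike, and an
absolute rule would manufacture breaks whenever a small block is dropped
by a higher threshold, breaking the monotonicity of the threshold
sweep).  The break interval is the bp gap between the flanking anchor
genes, a 1-bp point when empty.  The category labels are heuristics.

Detectability: a junction is only a block end if chaining cannot bridge
it.  An interior translocation of ≤ 30 genes leaves an anchor gap on one
side only, which the > 30-gene allowance bridges by design — such
junctions are undetectable under the stated rules, so the simulator's
default rearranged segments are 35–60 genes (inversions are detectable
down to the 10-gene block minimum and are simulated as small as 12).

## Co-localization statistics

Shuffling preserves the per-chromosome interval-length multiset and
forbids overlaps; placement draws sorted uniform gap positions and adds
back cumulative lengths, which samples non-overlapping arrangements
directly instead of rejection sampling.  The Fisher 2×2 uses the
bedtools-fisher convention, with `n22` estimated as genome length over
mean interval length minus the other cells; `n21` and `n22` clamp at
zero (the bedtools convention counts A intervals in `n11`, so the B-side
remainder can underflow when one B interval hits several A intervals).
The permutation p uses the +1 correction and is the recommended primary
statistic; because the overlap count is discrete, heavy null ties make
it conservative for tiny interval sets.

## Origin-stratified decay

Cis pairs are assigned same/different ancestral origin by their bins'
midpoints; curves are means per log2-spaced distance bin from 2× the
resolution upward.  The per-bin test needed three design decisions, all
driven by calibration failures of the naive approach:

1. Within a log-spaced bin the two origin groups sample different exact
   distances, so ranks are compared within each exact distance and
   combined (a van Elteren-style stratified rank sum).
2. Balancing against a decaying matrix leaves smooth position-dependent
   residuals (end bins over-corrected) and cross-origin pairs cluster
   mid-chromosome; test values are therefore O/E values with per-bin
   mean factors iteratively divided out (3 rounds).
3. Pair values sharing a bin share balancing-noise, so no analytic
   variance is trusted: the statistic is calibrated by a
   segment-permutation null that redraws the origin-junction positions
   uniformly (199 draws by default), preserving the number of runs and
   their label order.  The reported p is the rank of the observed
   statistic among the null ones, exact under exchangeability of the
   junction position.

Under the dampened (ancestral-preserving) model the same-origin mean
exceeds the different-origin mean in every populated distance bin with a
margin of ~2.5×; under the mixed model with arbitrary labels the p-values
are uniform.  When checking that uniformity, one populated bin is
sampled per replicate (the per-bin p-values within a replicate share
their null draws and junction, so pooling them would hand correlated
samples to the KS test), and bins with fewer than 50 pairs per stratum
are excluded because their permutation p-grid is too coarse to compare
to a continuous uniform.

## Expression statistics

RPKM = count · 10⁹ / (length · library size) with the library size taken
as the replicate's total counts; `e` = log10(mean replicate RPKM + 0.01)
— mean of RPKM first, then log.  Divergence is |e1 − e2| per ortholog.
Group contrasts use the Wilcoxon rank-sum test, exact for combined
n ≤ 20 without ties, normal approximation with tie correction otherwise.

## Pipeline and problem sizes

The demo system is a 4-chromosome, 300-genes-per-chromosome (3 Mb per
chromosome) ancestor and three derived species with 3–5 inversions, a
translocation each and one chromosome fusion in the reference.  Contact
maps are simulated at 50 kb (compartments) and 5 kb (TADs); synteny,
co-localization (200 permutations per mode), switches, conservation,
expression and decay stages follow.  A full run takes well under a
minute on one CPU, and the whole recovery/calibration harness a few
minutes; these sizes were chosen so the complete evidence chain is cheap
to re-run while every statistic retains comfortable power, as the
scorecard and harness verify.  Per-stage seeds derive from the single
run seed by hashing the stage name (BLAKE2), so stages are independently
reproducible and the report body is byte-identical across reruns.

The scorecard applies the recovery thresholds of the harness
(compartment agreement ≥ 95%, boundary F1 ≥ 0.9, break recall 100% at
precision ≥ 95%, Fisher co-localization p < 0.001) and demo-scale
significance checks for the per-pair switch and permutation tests
(p < 0.05), whose strict power claims are established by the dedicated
experiments at study-like sample sizes rather than by a single ~1100-
ortholog, ~19-break demo comparison.

In the scorecard's boundary F1, any called boundary inside a true
inter-TAD gap (± 1 bin) recovers that gap, and minima at compartment
transitions or rearrangement junctions are not false positives — the
forward model creates genuine insulation at both.  The dedicated
TAD-recovery experiment is stricter: plaid is neutral there, truth is
the gap-center bin, and matching is ± 1 bin.

## Known limitations

- The compartment caller is PC1-only; chromosomes with weak orientation
  evidence are flagged, not resolved.
- Break categories (inversion / translocation / fusion-fission /
  unclassified) are heuristic labels, not parsimony reconstructions.
- The Fisher `n22` cell is a capacity estimate, not a count; prefer the
  permutation p.
- The permutation p of interval co-localization is conservative for
  small interval sets (discrete ties).
- The simulator's equal-length chromosomes and uniform gene-length
  assumption are idealizations; the RPKM machinery handles variable
  lengths, but the generator does not exercise them.
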