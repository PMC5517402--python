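# Methods

## Coordinates and formats

Internal coordinates are 1-based inclusive (the GFF3 convention). BSJ tables
on disk use the BED dialect (0-based half-open) and are converted on
read/write; known-circRNA catalogues are 1-based on both sides. Library
sizes are sequencing-run totals that travel with each count matrix (an
embedded `library_size` row or a sidecar TSV) and are never recomputed from
column sums — feature sums are not sequencing totals, and the normalization
is undefined without the real ones. Whether "total reads" means sequenced
or mapped totals is left to the data provider: the pipeline uses whatever
the sidecar says.

## BSJ classification

A breakpoint *hits* an exon when it lies inside the exon interval, and is
*boundary-matched* when within `boundary_tolerance` nt (default 0) of the
appropriate edge — the acceptor edge for the transcript-upstream breakpoint
and the donor edge for the downstream one. Because the tolerance test is the
symmetric `|Δ| ≤ tol`, both strands end up comparing the left breakpoint to
the exon's genomic start and the right breakpoint to its genomic end; strand
only relabels which edge is called donor versus acceptor. At the default
tolerance 0, `EXONIC_BOTH_BOUNDARY` therefore requires exact coordinate
equality at both edges.

Host-gene candidates must contain **both** breakpoints and share the
junction's strand. Among overlapping candidates the gene with the largest
overlap with the junction interval wins; an exact tie, a cross-strand or
cross-gene configuration, or a mixed exon/intron configuration is classified
`AMBIGUOUS` rather than forced into a main category — keeping unusual cases
visible beats silently reassigning them. `INTERGENIC` means neither
breakpoint touches any gene. Per the exonic ⇔ host invariant, intronic
records do not carry a host-gene id. `exon_span` counts host-gene exons
overlapping the junction interval (0 for non-exonic records).

## Summary-table rounding

Per-category percentages use largest-remainder (Hamilton) rounding at one
decimal so the column sums to exactly 100.0, which is how summary tables of
this kind are conventionally printed: plain round-half-up would print
10/168 as 6.0 rather than the 5.9 that makes the table add up. The exonic
subtotal percentage is the sum of the three exonic rows (94.1 for
158/168); shares *of the exonic subset* (boundary-matched 84.8%, spans of
1–5 exons 89.9%) are ordinary round-half-up, where the distinction never
bites.

## Circular sequence extraction

An exonic circRNA's sequence is the concatenation of host-gene exon
sub-sequences overlapping the junction interval, clipped to it, so introns
drop out; intronic and intergenic records take the plain genomic interval;
minus-strand records are reverse-complemented. The junction window — the
last k−1 bases joined to the first k−1 (default k = 22, one more than a
typical plant miRNA) — contains every site window that crosses the
back-splice seam. This splice-and-circularize rule is the package's own
documented procedure for turning a BSJ into a scannable circular sequence.

## Expression, fold changes, DE calling

`E = (n + 1) / N × 10⁶`. The pseudocount makes E strictly positive (every
log fold change is defined) and the per-million scale is cosmetic — it
cancels in every ratio, and multiplying all library sizes by a constant
leaves every fold change unchanged (tested as an invariant).

The two stage windows deliberately overlap: days 16 and 18 belong to both,
and each stage measures fold change against its own reference day (4 or
16). A feature is DE when `|log₂ FC| ≥ 2` at **any** non-reference stage
day; the threshold is inclusive (planting `n_t = 4(n_ref + 1) − 1` with
equal library sizes gives FC = 2.0 exactly and is called DE). Direction is
the sign at the day of maximum |FC|; an exact tie across days resolves to
the latest day, weighting the senescence end of a window and keeping calls
deterministic. With one library per time point there is no replicate
structure, so no dispersion estimation, shrinkage or multiple-testing
correction is meaningful — calling is a pure fold-change rule.

"Detected" means ≥ 1 supporting read (configurable); features detected in
fewer than 2 samples are excluded from DE analysis. "More than 10 samples"
is strict (≥ 11). Stage detection sets count the shared days toward both
stages; the report also recomputes the overlap on stage-exclusive days so
the reader can see how much of it the shared days drive.

Host concordance asks, per stage, how many up-regulated DE circRNAs have a
host gene that is itself up-regulated DE under the identical normalization
and threshold (self-contained, rather than importing an external study's DE
lists), plus per-pair Spearman correlation between circRNA and host
profiles over all 14 points. circRNAs without a host are skipped and
listed.

## miRNA target scoring

One gapless penalty scheme in the psRNATarget family serves all target
kinds: position i of the miRNA (5′→3′) pairs the target base read 3′→5′;
Watson–Crick costs 0, G:U wobble 0.5, mismatch 1.0, all doubled in the seed
region (miRNA positions 2–13, configurable). S = 0 iff the window is a
perfect complement over the full miRNA. T and U are interchangeable on
input. Gaplessness is a deliberate restriction: it keeps the scorer exactly
enumerable, so a brute-force window oracle can verify the scanning code on
random instances; bulged sites are out of scope. Free-energy–ratio and
regression-score schemes from other predictors are not implemented; their
role is subsumed by the configurable cutoffs on this single scorer
(retention at S ≤ 4.0 for mRNAs, S ≤ 4.5 for circRNAs, both inclusive).

Scanning slides a miRNA-length window over the target; circular targets add
the seam windows. Ties take the smallest start coordinate, with
seam-spanning windows ordered after linear ones. The anti-correlation
filter keeps a hit when Spearman ρ(miRNA, target) ≤ −0.5 (inclusive) over
the full course, with average ranks for ties; a constant profile has no
defined rank correlation and fails the filter explicitly. A 1e-9 absolute
guard on the comparison absorbs floating-point error in the rank
correlation's normalization, so an exactly-boundary ρ passes regardless of
summation order.

## Network assembly

The fold gates "2-, 4- and 4-fold" translate literally to |log₂ FC| ≥ 1
(miRNA), ≥ 2 (circRNA), ≥ 2 (mRNA) at any day within the stage — the same
any-day rule as DE calling. Each molecule is gated independently; the gates
are not required to fire at the same time point (nothing in the design ties
them to one day, and independent gating is the weaker, better-defined
reading). A "pair" is one unique (circRNA, miRNA, mRNA) triple; output is
deduplicated and sorted for determinism. SIF export writes two `targets`
edges per triplet, deduplicated across triplets.

## Synthetic data

The generator emulates the study design, not the reads: 14 single-library
time points, mostly-exonic circRNAs in realistic category proportions
(~80/5/10/6% across the four categories), an upregulation trend toward
senescence (85% of regulated circRNAs rise), miRNAs anti-correlated with
planted targets, and a known-circRNA catalogue covering ~76% of junctions.
Counts are negative-binomial (Var = μ + φμ²; φ defaults to 0.05, chosen as
a plausible single-library overdispersion) around flat or logistic mean
trajectories; library sizes are ~10⁶ with 5% CV. Planted target sites are
exact reverse complements written into the genome inside the circRNA's exon
span and the target gene's first exon, orientation-corrected on minus
strands. BSJ coordinates are constructed against the emitted GFF3 so that
classification recovers the assigned category exactly (a round-trip tested
property). Identical parameters and seed give byte-identical files.

**Planted effects are defined on the pseudo-counted scale** the pipeline
measures: a planted fold F multiplies (μ + 1) by F on every stage day after
the reference, so the noise-free contrast is exactly log₂ F. Defining the
fold on raw means instead would place every planted feature strictly below
the nominal contrast and the recovery measurement would mostly probe
pseudocount bias.

What the generator does **not** emulate: read-level errors and mapping
artifacts, alternative back-splicing isoforms, replicate variance,
GC/length biases, and real miRNA site architecture (bulges, 3′
supplementary pairing). Passing tests therefore show the analysis logic is
correct under the stated statistical model, not that the thresholds are
well-calibrated for any particular real library.

### The deterministic fixture

`make_paper_fixture` is constraint satisfaction, not sampling: a fixed
allocation of 168 circRNAs over categories (134/8/16/10), exon spans (142
exonic records spanning 1–5 exons), organelles (3 chloroplast, all
intergenic), detection profile (104 singletons, 57 in 2–10 samples, 7 in
≥ 11; 64 retained), stage membership (66 and 144 with 42 shared), novelty
(catalogue covering 128, leaving 40 novel), DE structure (6 = 5↑+1↓ at
G-to-M, 35 = 34↑+1↓ at M-to-S, 3 shared), host concordance (9 of the 34
senescence-up circRNAs get 4-fold-up hosts) and sponge networks (2 miRNAs ×
2 circRNAs × 5 mRNAs = 20 triplets in one stage; 4 × 5 × 11 = 220 in the
other, with expression rank patterns mirrored exactly so every planted pair
has ρ = −1). The allocation is written out in the module source and
verified end-to-end by the test suite; only sequence content comes from a
fixed internal seed. The fixture ships as generating code — no data files.

## Power of the threshold rule (known limitation)

A planted effect **equal to** the calling threshold cannot be recalled
reliably, no matter how low the noise: with the plant at exactly 4-fold and
the rule at |log₂ FC| ≥ 2, each stage day clears the threshold with
probability ≈ ½, and "DE at any of the k = 7 non-reference days" misses
exactly when the reference-day noise draw exceeds all k day draws —
probability 1/(k+1) for exchangeable noise, independent of the noise scale.
Expected recall is therefore capped at k/(k+1) = 87.5%; measured recall
over 100 seeds × 8 planted features sits at ≈ 85–88%, i.e. at the ceiling.
Recall approaches 100% only for planted effects strictly beyond the
threshold. The null side is reported, not asserted: with no planted effect
the any-day rule still fires at a non-trivial rate on sparse count data,
which is why the rule is a screen, not a test.

## Problem sizes and numerical conventions

The test suite and the reproduction script run everything at desk scale:
the 168-circRNA fixture with 175 genes on 5 nuclear chromosomes (~360 kb of
synthetic genome, generated in memory at run time), random-instance oracles
at ≥ 1000 classifications and 200 scan pairs, and power measurements at
100–200 seeds — sizes chosen so the full analysis is a seconds-scale,
fully deterministic desk check. Degenerate inputs are defined, not
accidental: empty record lists give empty summaries with total 0; an
all-zero feature has detection 0 and is excluded from the retained set; a
target shorter than the miRNA yields no hit; constant profiles have
undefined ρ and fail the filter; duplicate feature ids, missing library
sizes, malformed lines and out-of-range spans raise errors naming the
offender.
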