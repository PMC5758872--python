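# Methods

This note documents the models, parameter choices, and numerical
decisions behind `dlekit`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Coordinates and I/O

All internal coordinates are 0-based half-open on the sense strand; GFF3
output converts to 1-based inclusive. FASTA input may be DNA-form
(T → U) and may carry `utr_start=N` header tags marking where the 3′UTR
begins; the sequence before that offset is trailing CDS context retained
for folding. Poly-A tails are assumed absent from supplied UTRs. There is
no reverse-strand scanning: the element lives in mRNA sense orientation.
When several transcript isoforms per gene are supplied, the one with the
longest 3′UTR is used; ties break to the lexicographically smallest
transcript id for determinism.

## The DLE grammar

A match is a contiguous decomposition
`anchor | spacer | stem5 | loop | stem3` in which every stem position is
paired (`stem5[m]` with `stem3[k−1−m]`) under Watson–Crick rules plus G·U
wobble. Wobble pairs are on by default — standard for RNA helices — and
can be disabled to emulate a strict-WC descriptor; neither behaviour is
claimed to reproduce any particular historical scanner configuration.
Two presets:

| preset  | anchor | spacer            | stem     | loop     |
|---------|--------|-------------------|----------|----------|
| relaxed | GCAC   | 2–5 nt, any       | 3–20 bp  | 3–30 nt  |
| strict  | GCAC   | 2–3 nt, U/C only  | 3–20 bp  | 5–12 nt  |

The relaxed preset's "variable loop" is bounded at 3–30 nt: 3 is the
steric minimum for a hairpin loop, 30 covers all observed DLE loops with
margin; both bounds are configurable. The relaxed stem requirement is "at
least 3 bp"; stating it as a 3–20 bp range makes every strict match
literally a relaxed match, so the strict hit set nests within the relaxed
one — an invariant the tests enforce. Some descriptions of the element
include a preceding A (AGCAC); the scanner exposes this as the optional
`require_preceding_A` flag rather than changing the default anchor.

One anchor position usually admits many (spacer, stem, loop)
decompositions. By default the scanner collapses them to the
maximal-stem representative per (anchor, loop-start), breaking ties
toward the shorter loop — a stable, non-redundant output; full
enumeration is available with `enumerate_all=True` and is what the
exhaustive-decomposition oracle in the tests compares against.

Mutant edits (`apply_mutant`) are defined against a located match: ΔG
deletes the anchor, ΔSL the stem-loop, ΔGSL both; SM rewrites the 5′ arm
so that no position can pair (not even by wobble) with its partner; SR
swaps the two arm strings, which preserves pairing because
complementarity is symmetric; LM rewrites the loop to an alternating UC
pattern of the same length, leaving the pair set untouched.

## Thermodynamic model

The built-in (`simple`) energy model assigns one free energy per base
pair — GC −3.0, AU −2.0, GU −1.0 kcal/mol — with no stacking, loop, or
dangle terms, a minimum hairpin loop of 3 nt, and
R = 1.9872×10⁻³ kcal/(mol·K). Its virtue is provability: the partition
function over all nested structures, the hard-constrained partition
function (all required pairs present), and the full base-pair probability
matrix are each computed by dynamic programming and verified against
exhaustive enumeration of the ensemble to 1×10⁻¹⁰ relative error on short
sequences. The stem-loop formation probability is defined as all
descriptor stem pairs required simultaneously; requiring only the
innermost 3 pairs is available as an option.

Numerics: all dynamic programs run in log space (log-sum-exp), so long
UTRs cannot overflow; the outside (base-pair probability) recursion is
O(n⁴) with vectorized inner sums, adequate for the ≤ ~100 nt rows the
conservation analysis folds. Impossible constraints (non-complementary,
crossing, or sterically forbidden pairs) raise validation errors — they
are distinct from a legal constraint whose probability happens to be 0.

The optional `turner` backend computes the same constrained/total ratio
with ViennaRNA's nearest-neighbour parameters (temperature passed
through, constraints enforced as required base pairs). Quantitative
fidelity to published fold-change numbers requires this backend; the
simple backend is used wherever a result must be checkable against
enumeration. The two backends agree qualitatively (e.g. masked <
unmasked) but not numerically, and no test asserts cross-backend values.

### Temperature grid

Context analyses default to 25–28 °C in 1 °C steps — the range at which
zebrafish are commonly reared — and report per-temperature fold changes
plus the min/max over the grid.

## CA-repeat masking

`find_repeats` reports maximal runs of a repeat unit (default CA) with at
least 4 copies; the threshold is a package default (the biologically
relevant run is long and unambiguous) and is configurable.
`masking_analysis` requires the deletion not to overlap the element,
computes p(stem) before and after the in-silico deletion, and reports
p_after/p_before per temperature. After deletion the element is
re-located by re-scanning when a descriptor is supplied (robust to
deletions 5′ of the motif), otherwise by coordinate shift; either way the
re-located element must carry the identical local sequence or the
analysis aborts.

To reproduce the published *cyc* ΔCA comparison, supply the Ensembl
*ndr2/cyc* transcript as `data/external/cyc_ndr2.fa` with a `utr_start`
tag; the analysis then folds the last 50 nt of CDS plus the 3′UTR with
the `turner` backend and deletes the CA run. The sequence is external
data and is not redistributed here; without it the corresponding
acceptance test reports the missing input explicitly.

## Conservation analysis

Orthologue transcripts are scanned with the strict preset over the 3′UTR
plus up to 100 nt of trailing CDS (all available context is used, with a
log note, when the CDS is shorter). Matched element regions ± 10 nt
flanks (configurable) are aligned by progressive profile
Needleman–Wunsch (match +2, mismatch −1, gap open −4, gap extend −1,
guide order = input order — deterministic). A curated alignment can be
supplied with `--alignment` instead; this mirrors practice, where
cross-species element alignments are often hand-adjusted, and is also how
the synthetic benchmark isolates consensus scoring from aligner jitter in
low-complexity flanks.

The consensus structure is a deliberately transparent surrogate for
tree-aware consensus predictors: per-row base-pair probability matrices
(simple backend) are mapped through alignment columns and averaged over
rows, a row contributing 0 to any column pair where it has a gap. The
consensus dot-bracket is the greedy maximum-reliability nested matching
over column pairs with averaged reliability ≥ 0.5. Phylogenetic
weighting, expected-accuracy scoring, and evolutionary tree input are
intentionally out of scope; "reliability" here means ensemble-averaged
pair probability, not a tree-corrected posterior.

## Reporter quantification

Pipeline per embryo: (1) the in-focus block is the contiguous window of
4 optical sections (configurable, `--slices` overrides) maximizing total
tracer intensity — an automated stand-in for choosing sharp slices by
eye; (2) maximum-intensity projection of that window in both channels;
(3) ROI = largest connected component above an Otsu threshold of the
tracer projection (fixed-value override available); (4) background =
mean channel intensities of un-injected control embryos run through the
same pipeline (controls with no segmentable signal fall back to a fixed
central rectangle; whole-image control means are available by flag);
(5) ratio = (GFP − bg) / (RFP − bg). Embryos with empty ROIs or
non-positive denominators are flagged and excluded, never silently
dropped. Statistics: two-way ANOVA (type II) on ratio with factors
group, stage and their interaction, then per-stage two-sample t contrasts
with Bonferroni adjustment over all contrasts, α = 0.05.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under (seed, config) and write ground
truth beside their outputs.

**Planted UTR cohorts** (default 200 sequences × 200 nt, GC 0.4 — the
AU-rich composition typical of 3′UTRs) embed one strict element in an
i.i.d. background, rejection-screened so that every scanner hit falls at
the planted anchor; recall and precision are therefore exact quantities.
The screening makes backgrounds slightly non-i.i.d. — the documented cost
of exact truth.

**Masked constructs** plant a strict DLE whose U/G-containing stem arm
can alternatively pair into an adjacent (CA)₈ run
(`AAGCACUU·UGU·AAAAA·ACA·G(CA)₈AA`, 38 nt — within the enumeration
budget). Deleting the run frees the arm, so the stem-formation fold
change exceeds 1 at every temperature; the effect size under the simple
backend (~1.06×) is smaller than nearest-neighbour models give for real
sequences, because single AU/GU pairs carry much less relative weight
without stacking. The inert control construct contains no U at all, so
its deletable poly-A run has zero pairing potential and the fold change
is exactly 1 — an exact invariance, used as the negative control.

**Orthologue families** (7 members, divergence 0.2/site, star phylogeny,
no indels) descend from an ancestor carrying a deliberately strong
element: a 6-bp G/C stem (arm sampled without shift-register
self-similarity, so no offset pairing register is fully complementary),
an adenosine loop and tri-C spacer, in an adenosine background. These
choices make the planted hairpin thermodynamically dominant in every row
under the stacking-free model — a planted "conserved structure" that did
not fold would be no ground truth at all. The tri-C spacer specifically
splits the anchor-G's unavoidable legal pairing partners three ways so no
single spurious column pair accumulates reliability. Under compensatory
evolution the helix-end pairs stay G/C (an A·U boundary pair would leak
into the A-rich background), interior pairs swap over the full
Watson–Crick set, the anchor is frozen, and spacer sites stay pyrimidine —
the purifying-selection signature of a real sequence/structure element.
With compensation off, every site mutates freely and elements die. What
passing benchmarks show: the scanner, folding engine, and consensus
scoring recover exactly what was planted. What they do not show:
performance on real UTRs with indels, heterogeneous composition,
tree-structured divergence, or marginal thermodynamic stability.

**Image cohorts** emulate the geometry of the assay (15 sections, one
4-section in-focus block, a bright blastoderm disc, fixed tracer
amplitude, GFP = ratio × tracer + background, multiplicative Gaussian
noise), not its optics: no PSF, attenuation, or morphology. ANOVA
calibration cohorts are generated at measurement level (per-embryo ratios
with CV 20%, n = 34 per cell, stage scales 1.0/1.25/1.5) so that 100-cohort
type-I-error and power studies run in seconds.

## Known limitations

- The simple energy model is not quantitative; all absolute probabilities
  it reports are model-internal quantities, meaningful relative to each
  other and exactly checkable, but not comparable to nearest-neighbour
  predictions.
- The consensus surrogate underweights covariation evidence relative to
  true phylogenetic methods: two rows related by many compensatory swaps
  count the same as two nearly identical rows.
- The progressive aligner places gaps arbitrarily among equal-scoring
  paths in low-complexity regions; curated alignments are preferred for
  column-resolved claims.
- Focus-window selection by summed intensity can differ from human
  judgement for embryos with bright debris; the manual override exists
  for exactly that case.
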