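# dlekit

Analysis toolkit for the **dorsal localization element (DLE)**, a composite
3′UTR RNA element of the zebrafish Nodal pathway: a short GCAC-anchored
sequence motif followed, after a 2–5 nt spacer, by a hairpin. The DLE
directs maternal RNA localization and Ybx1-mediated translational
repression of the Nodal ligands (*ndr1/sqt*, *ndr2/cyc*) and their
inhibitors (*lefty1*, *lefty2*), with a conserved counterpart in human
*NODAL*. `dlekit` is for RNA biologists who want to scan transcripts for
such composite sequence/structure elements and quantify how sequence
context and evolution act on them.

## What it computes

**Motif scanning.** A DLE descriptor is a small grammar
`anchor – spacer – stem5 – loop – stem3` with two presets: *relaxed*
(GCAC, 2–5 nt spacer of any composition, ≥3 bp stem, 3–30 nt loop) and
*strict* (GCAC, 2–3 pyrimidines, 3–20 bp stem, 5–12 nt loop). Stems pair
by Watson–Crick rules plus G·U wobble (configurable).

**Stem-loop formation probability.** For a hairpin with pair set
*S* = {(i₁,j₁), …, (i_k,j_k)} inside a sequence, the probability that the
hairpin forms in context is the ratio of two partition functions over
nested secondary structures,

    p(S | seq, T) = Z_constrained / Z_total,
    Z = Σ_structures exp(−E / RT),  E = Σ_pairs e(pair),

computed by a McCaskill-style dynamic program in log space, with hard
constraints forcing the pairs of *S*. The built-in energy model assigns
e(GC) = −3, e(AU) = −2, e(GU) = −1 kcal/mol per pair (no stacking or loop
terms, minimum hairpin loop 3 nt) and is verified against exhaustive
enumeration of the ensemble; an optional `turner` backend delegates the
same two-partition-function ratio to ViennaRNA's nearest-neighbour model.

**Context (CA-repeat masking).** A (CA)ₙ repeat near a DLE can pair
against the stem arm and sequester it. `masking_analysis` deletes a
chosen interval in silico and reports p_after / p_before per temperature
across the zebrafish rearing range (25–28 °C) — the computational analogue
of comparing wild-type *cyc* with *cyc*ΔCA.

**Conservation.** Orthologue 3′UTRs (plus up to 100 nt of CDS context)
are scanned with the strict preset, the matched regions aligned, and a
consensus structure scored by averaging per-sequence base-pair
probabilities through alignment columns (a transparent surrogate for
tree-aware consensus predictors). Compensatory substitutions — paired
mutations that preserve base-pairing — keep planted stem columns reliable
while chance pairings decay.

**Reporter quantification.** Two-channel z-stacks (GFP reporter +
rhodamine tracer) are max-projected over the in-focus block, the
blastoderm ROI segmented by Otsu thresholding of the tracer, backgrounds
taken from un-injected controls run through the same pipeline, and each
embryo summarized by the background-subtracted GFP/RFP ratio. Groups are
compared by two-way ANOVA (genotype × stage) with Bonferroni-adjusted
per-stage contrasts at α = 0.05.

**Synthetic data.** Every input class can be generated with known ground
truth: planted-DLE UTRs (rejection-screened so recall/precision are
exact), masked/unmasked construct pairs, compensatory orthologue
families, and embryo-like image cohorts with planted ratios.

## Worked example

Generate the masked-DLE construct (a strict DLE whose UGU stem arm can
also pair into an adjacent (CA)₈ repeat) and quantify the effect of
deleting the repeat:

```bash
dlekit simulate masked --seed 1 --out sim
dlekit repeats --fasta sim/constructs.fa --mask-analysis \
       --delete auto --temps 25:28:1 --out mask.tsv
```

`mask.tsv`:

```
transcript_id  temperature_C  p_before  p_after   fold_change
masked_dle     25.0           0.137871  0.146216  1.060527
masked_dle     26.0           0.137474  0.145957  1.061703
masked_dle     27.0           0.137076  0.145697  1.062894
masked_dle     28.0           0.136677  0.145438  1.064101
```

With the repeat present the stem forms with probability ≈ 0.137 at 25 °C;
deleting it raises the probability at every temperature (fold change > 1),
because the repeat no longer competes for the stem arm.

For a seven-member orthologue family with compensatory stem evolution:

```bash
dlekit simulate family --seed 17 --out fam
dlekit conserve --fasta fam/family.fa --cds-context 0 --out consensus.txt
```

```
sp0            AAAAAAAAAAGCACCCCGCCCGCAAAAAAAGCGGGCAAA
sp1            AAAACCAGAAGCACCCCCCCCGCAACAAAAGCGGGGAAA
...
structure      ..................(((((.......)))))....
conservation   898778888899998787988798978787978897977
reliab_paired  000000000000000000556760000000676550000
```

The `structure` track is the consensus dot-bracket; tracks print one
digit per column (value × 10, capped at 9). The planted stem columns
carry the paired-column reliability; the frozen GCAC anchor shows as a
block of high sequence conservation with no pairing reliability.

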