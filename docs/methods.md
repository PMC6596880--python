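# Methods

## Motif models

A splice-site model assigns `score(x) = log2(P_signal(x) / P_background(x))`
to a fixed-length motif: 9 nt for donors (3 exonic + 6 intronic, GT at
offsets 3–4), 23 nt for acceptors (20 intronic + 3 exonic, AG at offsets
18–19). Both components are represented as products of signed factor tables
over position subsets, which uniformly covers:

* independent per-position models (a PWM),
* first-order Markov chains — the exact maximum-entropy solution under
  first-order plus adjacent-pair marginal constraints, in closed form
  `P(x) = ∏ p(x_i, x_{i+1}) / ∏ p(x_i)` over interior positions,
* full-joint tables fitted by iterative proportional fitting (IPF) under
  arbitrary marginal constraints, for enumerable motif lengths (≤ 12 nt;
  the 4^23 acceptor joint is deliberately out of reach, hence the chain).

**Fitting.** Empirical marginal tables are computed per constraint subset,
floored at 1e-9 (so unseen cells never produce infinite scores) and
renormalized. First-order-only constraint sets use the product-of-marginals
closed form; first-order + adjacent pairs use the chain closed form with
singletons marginalized out of the pair tables (exact consistency);
anything else goes through IPF from a uniform start, sweeping multiplicative
updates `P ← P · target/marginal` until the maximum absolute marginal
deviation falls below the tolerance (default 1e-6) or `max_iter` (default
1000) is reached — non-convergence warns and reports the achieved
deviation rather than failing. Defaults: donors fit with all pairwise
constraints, acceptors with adjacent pairs. Backgrounds are first-order
(uniform when no background sequences are given).

**Sampling** draws i.i.d. motifs from the signal component (exact:
per-factor draws, sequential chain sampling, or enumeration), reproducible
from a seed.

**Serialization.** Two text formats: a single JSON document (factors
inline, format tag `mesplice-model/1`) and a factorized table directory —
a JSON manifest naming per-factor value files (one probability per line,
lexicographic ACGT order, tag `mesplice-maxent-tables/1`), shaped after
the classical factorized splice-model table distributions. The loader
validates value counts, per-factor normalization and site type, and names
file and line on parse errors.

**Bundled models.** The default donor/acceptor models are *synthetic*:
independent per-position models whose PWMs are shaped after the human
consensus (near-invariant GT/AG ≈ 0.997, A/G-rich donor intron positions,
a pyrimidine tract ahead of the acceptor AG) over a uniform background.
They produce realistic score ranges (consensus donor 12.74; sampled native
sites mostly 4–13, straddling the 6.2/8.5 cut-offs) but are not fitted to
any published table — conclusions about real human data require loading or
training real models.

## Transcripts, windows and variants

Internal coordinates are 0-based half-open; GTF/GFF3 and VCF keep their
native 1-based conventions at the boundary. All scoring happens on the
transcript sense strand; reverse-complementing occurs exactly once, at
sequence extraction. A transcript with E exons has E−1 donor and E−1
acceptor sites; sites whose exonic/intronic context does not fit (intron
< 20 nt for acceptors, < 6 nt for donors, exon < 3 nt) are omitted with a
warning.

Variants are decomposed per alt allele, validated against the genome,
parsimony-trimmed and left-aligned (checked against `bcftools norm` in the
tests). Because left-alignment is an arbitrary convention inside repeat
runs, each variant also carries a **repeat-aware edit zone** derived from
the longest common prefix/suffix of the local ref/alt haplotypes: the
substituted or inserted block, or — when prefix and suffix meet, as in a
pure deletion — the bases flanking every repeat-equivalent placement of
the junction. Overlap tests (native-site routing, region labels) and
window enumeration use this zone, which makes every downstream result
independent of the alignment convention and exactly symmetric under
reverse-complementing the whole genome. The local context grows adaptively
(flank doubling) when a repeat widens the zone beyond the initial window.

**Sliding-window search (MES-SWA).** All k-mers in which the edit zone
occupies at least one window position are scored on both haplotypes, with
frames numbered by the zone's first sense-strand base (an SNV yields
exactly k frames, k…1). Ties take the 5'-most frame. The comparison score:
for SNVs, the reference window at the best alternate frame; for
length-changing variants, the alternate window at the best *reference*
window's frame (frame matching rather than coordinate projection — the
projection is ill-defined across repeats; both raw maxima are retained so
users can audit). `diff` is uniformly reference-side minus alternate-side:
positive ⇔ loss direction, negative ⇔ gain direction.

**Native-site scoring.** Length-preserving variants score the same genomic
motif span on both haplotypes. Indels re-anchor the alternate motif at the
biological boundary (exon end for donors, exon start for acceptors)
projected through the edit via the same prefix/suffix logic; a boundary
landing strictly inside a deleted block is flagged
(`native_boundary_removed`) and the loss assessment falls to the sliding
window, which is also the routing for all indels overlapping native sites.

**MES-NCSS.** For each of (upstream, downstream) × (donor, acceptor) in
transcript orientation: the nearest native site whose motif span lies
entirely on that side of the variant, scored on the reference haplotype;
absence is a value, not an error.

## Classification

Loss (diff > 0, variant overlapping a native motif): alt < 6.2 high,
6.2 ≤ alt ≤ 8.5 moderate, alt > 8.5 low; diff < 1.15 (strict) downgrades
high→moderate and moderate→low. Gain (diff < 0, variant outside native
motifs): alt > 8.5 high; 6.2 ≤ alt ≤ 8.5 moderate only if the best
alternate window strictly out-scores the nearest native site of the same
type (vacuously true, flagged, when none exists); otherwise low. Failed
competition demotes to low, not none; the competition test never applies
to the high tier. Boundary semantics are boundary-inclusive for moderate
(≤/≥) and strict for the downgrade and the loss/gain split (diff exactly 0
is neither). Donor and acceptor channels are both evaluated; the reported
call is the higher priority (tie → donor). All cut-offs live in a
`Thresholds` object (defaults are the ENIGMA consortium values) and are
settable per run via CLI flags or a JSON thresholds file; flag > file >
default.

Region labels for stratified evaluation: `donor_dinucleotide` /
`acceptor_dinucleotide` (the edit zone touches the GT/AG),
`donor_other` / `acceptor_other` (elsewhere in a native motif), `exonic`,
`intronic_other`.

## Synthetic data generator

`generate_fixture` builds a uniform-background genome carrying multi-exon
genes on both strands whose junction motifs are sampled from the signal
models (consensus dinucleotide enforced), then spikes six variant
categories with truth assigned by construction and verified at generation
time by direct scoring:

* GT/AG dinucleotide hits (SNVs, plus 25% small deletions) — aberrant;
* native-motif weakening SNVs, accepted only when the mutated motif scores
  below 5.9 with a drop above 1.45 (0.3-unit margins inside the high tier)
  — aberrant;
* deep-intronic and exonic planted gains: a sampled motif scoring > 9.5 is
  written into clear sequence with one non-consensus mismatch, and the
  variant restores it; accepted only if the completed motif exceeds 8.5
  and out-scores the mismatched same-frame reference — aberrant;
* neutral SNVs and 1–3 bp deletions, accepted only when every donor and
  acceptor window on both haplotypes scores below 6.2 — normal.

Defaults (500 variants: 90/90/80/70/70/100 over 12 genes, exons 130–260 nt,
introns 150–400 nt, half minus-strand, genome ≈ 20 kb) are sized so the
recipe is feasible on any seed; infeasible recipes raise a
`GenerationError` naming the category. Generation is fully reproducible
from the seed.

What the generator does *not* emulate: real splice-site dependency
structure beyond the sampled models, branch points, exonic splicing
enhancers/silencers, GC-content heterogeneity, repeat families, multiple
transcripts per locus, and assay noise in the truth labels. Passing the
fixture criteria therefore demonstrates that the scoring, window, and
classification machinery is self-consistent and separable under the
stated conditions — not that the bundled models predict real human
splicing outcomes.

The evaluator joins calls to truth on (chrom, pos, ref, alt, transcript),
counts predictions in the high/moderate tier as positive, and reports
TP/FP/TN/FN with sensitivity and specificity per region label and overall;
empty denominators are reported as undefined rather than zero. Evaluating
a published assay panel requires only its truth TSV, the matching genome
FASTA and annotation, and real model tables.

## Numerical choices and limitations

* Log base 2 everywhere; outputs render to 2 decimals, internals stay full
  precision; missing is encoded distinctly from zero (`.` in VCF, `NA` in
  TSV).
* Probability floor 1e-9; IPF tolerance 1e-6, max 1000 sweeps, uniform
  start.
* Ambiguous bases: the scorer refuses N; the assessment layer skips
  N-containing windows and flags `windows_skipped_N`; an all-skipped
  search yields an assessment-unavailable result, not an exception.
* Window ties → 5'-most frame; call ties → donor channel.
* Variants are assessed per overlapping transcript independently; no
  cross-transcript aggregation. A variant must overlap
  [transcript start, transcript end]; windows may extend into flanking
  genomic sequence.
* The non-SNV comparison frame is clamped to the nearest available
  alternate frame when a long deleted block outruns the junction zone
  (flagged `comparison_frame_clamped`).
* Known limitations: no branch-point or ESE/ESS models; no protein-level
  consequence calling; complex substitutions with length change use the
  whole replaced block as their edit zone (mirror symmetry is not
  guaranteed for them); the bundled models are synthetic stand-ins, not
  the published human tables.
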