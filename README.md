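# mesplice

Maximum-entropy splice-site scoring and variant spliceogenicity assessment
for VCF variants.

Most annotation pipelines flag variants that hit the GT/AG dinucleotides of
a splice site and overlook everything else, yet deeper intronic and exonic
variants can abolish a native splice site or activate a cryptic one.
`mesplice` assesses *any* variant overlapping a transcript — SNV, insertion
or deletion, either strand — and classifies its splice-altering potential.
It is aimed at variant-curation and rare-disease/cancer-gene analysis
workflows that need transparent, score-based splice evidence rather than a
black-box prediction.

## The model and the three score sets

A splice-site motif is scored with a **maximum-entropy model**: the signal
distribution P_signal is the maximum-entropy distribution matching empirical
marginal frequencies over subsets of motif positions, and a motif *x* gets a
log-likelihood ratio

```
score(x) = log2( P_signal(x) / P_background(x) )
```

Donor (5') sites are 9-mers — the last 3 exonic plus first 6 intronic bases,
with near-invariant GT at intron positions +1/+2; acceptor (3') sites are
23-mers — the last 20 intronic plus first 3 exonic bases, with AG at intron
positions −2/−1. Three score sets are computed per (variant, transcript):

1. **Native-site scores** — ref and alt motif scores for each native site
   the variant overlaps, and `diff = ref − alt` (positive ⇔ predicted loss).
2. **MES-SWA** (sliding-window assessment) — the allele slides from window
   position *k* down to 1 on both haplotypes; the best alternate window is
   the fittest potential site, compared against a frame-matched reference
   score (negative diff ⇔ predicted gain).
3. **MES-NCSS** (nearest canonical splice sites) — the nearest native donor
   and acceptor upstream and downstream of the variant, the competition
   baseline for gain calls.

Calls use configurable log2-score cut-offs (defaults: the ENIGMA consortium
values). Loss (diff > 0): alt < 6.2 → high, 6.2 ≤ alt ≤ 8.5 → moderate,
alt > 8.5 → low; diff < 1.15 downgrades high→moderate, moderate→low.
Gain (diff < 0): alt > 8.5 → high; 6.2 ≤ alt ≤ 8.5 → moderate only if the
candidate out-scores the nearest native site of the same type, else low.

The package bundles **synthetic** donor/acceptor models (PWM-shaped after
the human consensus; see `docs/methods.md`). For production use, load your
own tables (`--donor-table/--acceptor-table`, the factorized manifest layout
in `mesplice.models`) or fit models from motif FASTAs with `mesplice train`.

## Worked example

Score candidate donor 9-mers (log2 units, 2 decimals):

```
$ printf 'CAGGTAAGT\nCAGGCAAGT\n' | mesplice score --type donor -
CAGGTAAGT       12.74
CAGGCAAGT       2.78
```

The consensus donor scores 12.74; breaking the GT (T→C at intron +2) drops
it to 2.78 — a 9.96-unit loss, far beyond the 1.15 downgrade cut.

Generate a seeded synthetic genome with known-truth variants, annotate it,
and evaluate the calls:

```
$ mesplice simulate --seed 11 --out-dir demo --n-genes 6 \
    --counts "donor_dinucleotide_loss=3,acceptor_dinucleotide_loss=3,\
native_weakening=2,deep_intronic_gain=2,exonic_gain=2,neutral=4"
$ mesplice annotate --vcf demo/variants.vcf --gtf demo/genes.gtf \
    --fasta demo/genome.fa --out-vcf demo/ann.vcf --out-tsv demo/ann.tsv
annotated 16 (variant, transcript) pairs
$ head -3 demo/ann.tsv | cut -f1-11,25-26
# mesplice 0.1.0 thresholds: high_alt_cut=6.2 low_alt_cut=8.5 downgrade_diff_cut=1.15
chrom  pos  ref  alt  transcript_id  variant_class  region_label  native_site_type  native_ref  native_alt  native_diff  mechanism  priority
chr1   470  T    A    TX001          SNV            acceptor_dinucleotide  acceptor  3.81  -6.15  9.96  native_loss  high
```

The T>A at chr1:470 hits an acceptor AG: the native acceptor drops from
3.81 to −6.15 (diff 9.96 > 0, alt < 6.2) → a high-priority native-loss
call. The same panel is written into the VCF as `MES_*` INFO keys,
pipe-delimited per transcript in parallel with `MES_TX`.

```
$ mesplice evaluate --calls demo/ann.tsv --truth demo/truth.tsv
...
overall sensitivity 100.0% specificity 100.0% (16 records evaluated, 0 unmatched)
```

`evaluate` joins calls to any truth TSV (columns: chrom, pos, ref, alt,
transcript_id, region_label, assay_outcome) — predictions in the
high/moderate tier count as positive — and reports TP/FP/TN/FN with
sensitivity and specificity per region label and overall, leaving cells
with empty denominators undefined.

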