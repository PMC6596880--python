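"""Seeded synthetic genomes with known-truth spliceogenic variants, and the
sensitivity/specificity evaluator.

The generator builds a small multi-gene genome on both strands whose native
donor/acceptor motifs are sampled from the splice-site signal models
(GT/AG enforced) on a uniform-background sequence, then spikes variants of
six categories with truth labels assigned by construction and verified at
generation time by direct scoring:

* ``donor_dinucleotide_loss`` / ``acceptor_dinucleotide_loss`` — SNVs (and a
  fraction of small deletions) hitting the near-invariant GT / AG; aberrant.
* ``native_weakening`` — SNVs elsewhere in a native motif chosen so the
  mutated motif scores below the high cut with a comfortable drop; aberrant.
* ``deep_intronic_gain`` / ``exonic_gain`` — a strong motif is planted one
  mismatch away from completion and the SNV completes it; aberrant only
  because the completed motif verifiably scores above the low cut and
  out-scores the same-frame reference.
* ``neutral`` — SNVs and small deletions placed outside native motifs where
  every scoring window on both haplotypes stays below the high cut; normal.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._sequences import reverse_complement
from .annotation import (
    Interval,
    NativeSpliceSite,
    NormalizedVariant,
    TranscriptModel,
    native_sites,
    normalize_variant,
)
from .classify import Thresholds
from .models import CONSENSUS_BASES, CONSENSUS_OFFSETS, SpliceSiteModel

# Position weight matrices (A, C, G, T) for the bundled SYNTHETIC models.
# Shaped after the human donor/acceptor consensus (near-invariant GT / AG,
# A/G-rich donor intron positions, pyrimidine tract before the acceptor AG)
# but not fitted to any published table; see docs/methods.md.
DONOR_PWM = np.array([
    [0.33, 0.36, 0.19, 0.12],   # exon -3
    [0.60, 0.13, 0.14, 0.13],   # exon -2
    [0.08, 0.04, 0.81, 0.07],   # exon -1
    [0.001, 0.001, 0.997, 0.001],  # intron +1 (G)
    [0.001, 0.001, 0.002, 0.996],  # intron +2 (T)
    [0.58, 0.08, 0.27, 0.07],   # intron +3
    [0.70, 0.08, 0.12, 0.10],   # intron +4
    [0.07, 0.05, 0.82, 0.06],   # intron +5
    [0.16, 0.17, 0.22, 0.45],   # intron +6
])

_TRACT = [0.10, 0.30, 0.10, 0.50]
ACCEPTOR_PWM = np.array(
    [_TRACT] * 14 + [
        [0.08, 0.35, 0.07, 0.50],   # intron -6
        [0.08, 0.35, 0.07, 0.50],   # intron -5
        [0.23, 0.29, 0.25, 0.23],   # intron -4
        [0.05, 0.65, 0.01, 0.29],   # intron -3
        [0.997, 0.001, 0.001, 0.001],  # intron -2 (A)
        [0.001, 0.001, 0.997, 0.001],  # intron -1 (G)
        [0.25, 0.14, 0.50, 0.11],   # exon +1
        [0.25, 0.25, 0.25, 0.25],   # exon +2
        [0.25, 0.25, 0.25, 0.25],   # exon +3
    ]
)

BASES = "ACGT"


def default_models() -> dict[str, SpliceSiteModel]:
    """The bundled synthetic donor/acceptor models (uniform background)."""
    return {
        "donor": SpliceSiteModel.from_pwm("donor", DONOR_PWM),
        "acceptor": SpliceSiteModel.from_pwm("acceptor", ACCEPTOR_PWM),
    }


DEFAULT_COUNTS = {
    "donor_dinucleotide_loss": 90,
    "acceptor_dinucleotide_loss": 90,
    "native_weakening": 80,
    "deep_intronic_gain": 70,
    "exonic_gain": 70,
    "neutral": 100,
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic genome + variant set."""

    seed: int = 0
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (2, 4)
    # sized so the default recipe's planted motifs (plus their clearance
    # margins) reliably fit into exon/intron interiors on any seed
    exon_length: tuple[int, int] = (130, 260)
    intron_length: tuple[int, int] = (150, 400)
    minus_strand_fraction: float = 0.5
    spacer_length: int = 300
    chrom: str = "chr1"
    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("variant counts must be >= 0")
        if self.intron_length[0] < 30:
            raise ValueError("introns must be at least 30 nt")


class GenerationError(RuntimeError):
    """A variant recipe could not be satisfied by the genome layout."""


@dataclass
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    region_label: str
    assay_outcome: str  # aberrant | normal
    category: str


@dataclass
class Fixture:
    """In-memory generated fixture (see :func:`write_fixture` for files)."""

    spec: FixtureSpec
    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    truth: list[TruthRecord]

    @property
    def variants(self) -> list[NormalizedVariant]:
        genome = _DictGenome(self.sequences)
        return [
            normalize_variant(t.chrom, t.pos, t.ref, t.alt, genome)
            for t in self.truth
        ]


class _DictGenome(dict):
    """Minimal genome object over plain strings (fetch-compatible)."""


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _sample_motif(model: SpliceSiteModel, rng: np.random.Generator) -> str:
    seq = model.sample(1, random_state=rng)[0]
    o1, o2 = CONSENSUS_OFFSETS[model.site_type]
    c = CONSENSUS_BASES[model.site_type]
    return seq[:o1] + c + seq[o2 + 1:]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _build_gene(rng, models, n_exons, exon_lens, intron_lens):
    """Sense-strand gene sequence with model-sampled junction motifs.

    Returns (sequence, exon sense-intervals)."""
    parts = []
    exon_iv = []
    pos = 0
    for i in range(n_exons):
        parts.append(_random_seq(rng, exon_lens[i]))
        exon_iv.append(Interval(pos, pos + exon_lens[i]))
        pos += exon_lens[i]
        if i < n_exons - 1:
            parts.append(_random_seq(rng, intron_lens[i]))
            pos += intron_lens[i]
    seq = list("".join(parts))
    # overwrite donor/acceptor motifs at every junction
    for i in range(n_exons - 1):
        e_end = exon_iv[i].end
        donor = _sample_motif(models["donor"], rng)
        seq[e_end - 3:e_end + 6] = donor
        e_next = exon_iv[i + 1].start
        acceptor = _sample_motif(models["acceptor"], rng)
        seq[e_next - 20:e_next + 3] = acceptor
    return "".join(seq), exon_iv


def _layout_genome(spec: FixtureSpec, models, rng):
    chrom_parts = [_random_seq(rng, spec.spacer_length)]
    offset = spec.spacer_length
    transcripts = []
    for g in range(spec.n_genes):
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(*spec.exon_length)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(*spec.intron_length)) for _ in range(n_exons - 1)]
        gene_seq, exon_iv = _build_gene(rng, models, n_exons, exon_lens, intron_lens)
        L = len(gene_seq)
        if strand == "-":
            genomic_seq = reverse_complement(gene_seq)
            exons = [Interval(offset + L - e.end, offset + L - e.start)
                     for e in exon_iv]
        else:
            genomic_seq = gene_seq
            exons = [Interval(offset + e.start, offset + e.end) for e in exon_iv]
        chrom_parts.append(genomic_seq)
        offset += L
        chrom_parts.append(_random_seq(rng, spec.spacer_length))
        offset += spec.spacer_length
        transcripts.append(
            TranscriptModel(f"TX{g + 1:03d}", spec.chrom, strand, exons)
        )
    return "".join(chrom_parts), transcripts


# ---------------------------------------------------------------------------
# variant recipes
# ---------------------------------------------------------------------------

def _sense_to_plus(site_or_span: Interval, strand: str, sense_offset: int,
                   k: int) -> int:
    """Plus-strand genomic position of sense-offset within a motif span."""
    if strand == "+":
        return site_or_span.start + sense_offset
    return site_or_span.start + (k - 1 - sense_offset)


def _plus_allele(base: str, strand: str) -> str:
    return base if strand == "+" else reverse_complement(base)


class _Generator:
    def __init__(self, spec: FixtureSpec, models, thresholds: Thresholds):
        self.spec = spec
        self.models = models
        self.t = thresholds
        self.rng = np.random.default_rng(spec.seed)
        seq, self.transcripts = _layout_genome(spec, models, self.rng)
        self.seq = list(seq)
        self.sites = {tx.transcript_id: native_sites(tx) for tx in self.transcripts}
        self.reserved: list[Interval] = [
            s.span for sl in self.sites.values() for s in sl
        ]
        self.truth: list[TruthRecord] = []

    # -- helpers -----------------------------------------------------------
    def genome(self) -> _DictGenome:
        return _DictGenome({self.spec.chrom: "".join(self.seq)})

    def _is_reserved(self, start: int, end: int, margin: int = 0) -> bool:
        probe = Interval(start - margin, end + margin)
        return any(probe.overlaps(r) for r in self.reserved)

    def _multi_exon(self) -> list[TranscriptModel]:
        txs = [tx for tx in self.transcripts if len(tx.exons) > 1]
        if not txs:
            raise GenerationError("no multi-exon transcripts in the layout")
        return txs

    def _pick_site(self, site_type: str) -> tuple[TranscriptModel, NativeSpliceSite]:
        txs = self._multi_exon()
        for _ in range(200):
            tx = txs[self.rng.integers(len(txs))]
            cands = [s for s in self.sites[tx.transcript_id]
                     if s.site_type == site_type]
            if cands:
                return tx, cands[self.rng.integers(len(cands))]
        raise GenerationError(f"no native {site_type} sites available")

    def _add(self, tx, pos, ref, alt, region, outcome, category):
        v = normalize_variant(self.spec.chrom, pos, ref, alt, self.genome())
        self.truth.append(
            TruthRecord(v.chrom, v.pos, v.ref, v.alt, tx.transcript_id,
                        region, outcome, category)
        )

    def _site_sense_seq(self, site: NativeSpliceSite) -> str:
        plus = "".join(self.seq[site.span.start:site.span.end])
        return reverse_complement(plus) if site.strand == "-" else plus

    # -- categories ---------------------------------------------------------
    def dinucleotide_loss(self, site_type: str, n: int):
        k = 9 if site_type == "donor" else 23
        o1, _ = CONSENSUS_OFFSETS[site_type]
        for i in range(n):
            tx, site = self._pick_site(site_type)
            region = f"{site_type}_dinucleotide"
            if self.rng.random() < 0.25:
                # deletion removing the consensus dinucleotide
                d_span = site.dinucleotide_span()
                anchor = d_span.start - 1
                ref = "".join(self.seq[anchor:d_span.end])
                alt = ref[0]
                self._add(tx, anchor + 1, ref, alt, region, "aberrant",
                          f"{site_type}_dinucleotide_loss")
                continue
            off = o1 + int(self.rng.integers(2))  # one of the two consensus bases
            motif = self._site_sense_seq(site)
            old = motif[off]
            new = BASES[(BASES.index(old) + 1 + int(self.rng.integers(3))) % 4]
            gpos = _sense_to_plus(site.span, site.strand, off, k)
            self._add(tx, gpos + 1, _plus_allele(old, site.strand),
                      _plus_allele(new, site.strand), region, "aberrant",
                      f"{site_type}_dinucleotide_loss")

    def native_weakening(self, n: int):
        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 60 * n:
                raise GenerationError("native_weakening: recipe infeasible")
            site_type = "donor" if self.rng.random() < 0.5 else "acceptor"
            tx, site = self._pick_site(site_type)
            model = self.models[site_type]
            motif = self._site_sense_seq(site)
            ref_score = model.score_seq(motif)
            o1, o2 = CONSENSUS_OFFSETS[site_type]
            off = int(self.rng.integers(site.k))
            if off in (o1, o2):
                continue
            old = motif[off]
            best = None
            for b in BASES:
                if b == old:
                    continue
                cand = motif[:off] + b + motif[off + 1:]
                s = model.score_seq(cand)
                if best is None or s < best[1]:
                    best = (b, s)
            alt_score = best[1]
            diff = ref_score - alt_score
            # require a comfortable margin inside the high tier
            if alt_score < self.t.high_alt_cut - 0.3 and diff > self.t.downgrade_diff_cut + 0.3:
                gpos = _sense_to_plus(site.span, site.strand, off, site.k)
                self._add(tx, gpos + 1, _plus_allele(old, site.strand),
                          _plus_allele(best[0], site.strand),
                          f"{site_type}_other", "aberrant", "native_weakening")
                made += 1

    def _regions_for_planting(self, tx: TranscriptModel, kind: str):
        if kind == "exonic":
            return [e for e in tx.exons]
        return tx.introns()

    def planted_gain(self, kind: str, n: int):
        """Plant a one-mismatch-from-strong motif; the SNV completes it."""
        made = 0
        attempts = 0
        category = "deep_intronic_gain" if kind == "intronic" else "exonic_gain"
        while made < n:
            attempts += 1
            if attempts > 120 * n:
                raise GenerationError(f"{category}: recipe infeasible "
                                      "(not enough clear sequence)")
            txs = self._multi_exon()
            tx = txs[self.rng.integers(len(txs))]
            site_type = "donor" if self.rng.random() < 0.6 else "acceptor"
            model = self.models[site_type]
            k = model.motif_length
            regions = self._regions_for_planting(tx, kind)
            region = regions[self.rng.integers(len(regions))]
            margin = 26  # keep scoring windows clear of native motifs/plants
            lo, hi = region.start + margin, region.end - margin - k
            if hi <= lo:
                continue
            gstart = int(self.rng.integers(lo, hi))
            if self._is_reserved(gstart, gstart + k, margin=margin):
                continue
            # sample a strong motif (sense strand of the host transcript)
            strong = None
            for _ in range(200):
                m = _sample_motif(model, self.rng)
                if model.score_seq(m) > self.t.low_alt_cut + 1.0:
                    strong = m
                    break
            if strong is None:
                continue
            o1, o2 = CONSENSUS_OFFSETS[site_type]
            off = int(self.rng.integers(k))
            if off in (o1, o2):
                continue
            pwm_row = (DONOR_PWM if site_type == "donor" else ACCEPTOR_PWM)[off]
            weak_base = BASES[int(np.argmin(pwm_row))]
            if weak_base == strong[off]:
                continue
            mismatched = strong[:off] + weak_base + strong[off + 1:]
            # generation self-check by direct scoring
            if not (model.score_seq(strong) > self.t.low_alt_cut
                    and model.score_seq(strong) > model.score_seq(mismatched)):
                continue
            # write the mismatched motif into the genome (sense -> plus)
            plus_motif = mismatched if tx.strand == "+" else reverse_complement(mismatched)
            self.seq[gstart:gstart + k] = plus_motif
            self.reserved.append(Interval(gstart, gstart + k))
            gpos = _sense_to_plus(Interval(gstart, gstart + k), tx.strand, off, k)
            self._add(tx, gpos + 1, _plus_allele(weak_base, tx.strand),
                      _plus_allele(strong[off], tx.strand),
                      "intronic_other" if kind == "intronic" else "exonic",
                      "aberrant", category)
            made += 1

    def neutral(self, n: int):
        from .annotation import window_sequences

        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 200 * n:
                raise GenerationError("neutral: recipe infeasible")
            txs = self._multi_exon()
            tx = txs[self.rng.integers(len(txs))]
            gpos = int(self.rng.integers(tx.start + 30, tx.end - 30))
            if self._is_reserved(gpos, gpos + 4, margin=26):
                continue
            genome = self.genome()
            if self.rng.random() < 0.3:
                dlen = int(self.rng.integers(1, 4))
                ref = "".join(self.seq[gpos:gpos + 1 + dlen])
                alt = ref[0]
            else:
                ref = self.seq[gpos]
                alt = BASES[(BASES.index(ref) + 1 + int(self.rng.integers(3))) % 4]
            try:
                v = normalize_variant(self.spec.chrom, gpos + 1, ref, alt, genome)
            except ValueError:
                continue
            # verify every window on both haplotypes stays below the high cut
            ok = True
            for st in ("donor", "acceptor"):
                model = self.models[st]
                for hap in ("ref", "alt"):
                    frames, _ = window_sequences(genome, tx, v, model.motif_length,
                                                 hap, on_truncate="flag")
                    if any(model.score_seq(s) >= self.t.high_alt_cut
                           for _, s in frames):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            exonic = any(e.start <= v.start < e.end for e in tx.exons)
            self._add(tx, v.pos, v.ref, v.alt,
                      "exonic" if exonic else "intronic_other",
                      "normal", "neutral")
            made += 1

    def run(self) -> Fixture:
        c = self.spec.counts
        self.dinucleotide_loss("donor", c.get("donor_dinucleotide_loss", 0))
        self.dinucleotide_loss("acceptor", c.get("acceptor_dinucleotide_loss", 0))
        self.planted_gain("intronic", c.get("deep_intronic_gain", 0))
        self.planted_gain("exonic", c.get("exonic_gain", 0))
        # weakening and neutral variants score against the final genome,
        # after all plants are in place
        self.native_weakening(c.get("native_weakening", 0))
        self.neutral(c.get("neutral", 0))
        self.truth.sort(key=lambda t: (t.chrom, t.pos, t.ref, t.alt, t.transcript_id))
        return Fixture(self.spec, {self.spec.chrom: "".join(self.seq)},
                       self.transcripts, self.truth)


def generate_fixture(spec: FixtureSpec,
                     models: dict[str, SpliceSiteModel] | None = None,
                     thresholds: Thresholds | None = None) -> Fixture:
    """Generate a synthetic genome + known-truth variant set from a spec."""
    models = models or default_models()
    return _Generator(spec, models, thresholds or Thresholds()).run()


# ---------------------------------------------------------------------------
# mirroring (strand-symmetry checks)
# ---------------------------------------------------------------------------

def mirror_fixture(fx: Fixture) -> Fixture:
    """Reverse-complement the genome and flip all annotation accordingly.

    Every transcript keeps its biological sense (strand flips, coordinates
    reflect); every variant denotes the same edit in mirrored coordinates,
    re-normalized (left-aligned) against the mirrored genome. Scores, window
    frames and calls computed on the mirrored fixture must equal the
    originals.
    """
    lengths = {c: len(s) for c, s in fx.sequences.items()}
    sequences = {c: reverse_complement(s) for c, s in fx.sequences.items()}
    transcripts = []
    for tx in fx.transcripts:
        L = lengths[tx.chrom]
        exons = [Interval(L - e.end, L - e.start) for e in tx.exons]
        transcripts.append(
            TranscriptModel(tx.transcript_id, tx.chrom,
                            "-" if tx.strand == "+" else "+", exons)
        )
    truth = []
    for t in fx.truth:
        L = lengths[t.chrom]
        start = t.pos - 1
        m_start = L - (start + len(t.ref))
        ref = reverse_complement(t.ref)
        alt = reverse_complement(t.alt)
        v = normalize_variant(t.chrom, m_start + 1, ref, alt,
                              _DictGenome(sequences))
        truth.append(TruthRecord(t.chrom, v.pos, v.ref, v.alt, t.transcript_id,
                                 t.region_label, t.assay_outcome, t.category))
    return Fixture(fx.spec, sequences, transcripts, truth)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fixture(fx: Fixture, out_dir) -> dict[str, Path]:
    """Write FASTA (+ .fai), GTF, VCF and truth TSV for a fixture."""
    import pysam

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "genes.gtf",
        "vcf": out / "variants.vcf",
        "truth": out / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in fx.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(str(paths["fasta"]))

    with open(paths["gtf"], "w") as fh:
        for tx in fx.transcripts:
            exons = sorted(tx.exons, key=lambda e: e.start)
            span = tx.span
            attrs = f'gene_id "{tx.transcript_id}g"; transcript_id "{tx.transcript_id}";'
            fh.write(f"{tx.chrom}\tmesplice\ttranscript\t{span.start + 1}\t"
                     f"{span.end}\t.\t{tx.strand}\t.\t{attrs}\n")
            for e in exons:
                fh.write(f"{tx.chrom}\tmesplice\texon\t{e.start + 1}\t{e.end}"
                         f"\t.\t{tx.strand}\t.\t{attrs}\n")

    header = pysam.VariantHeader()
    header.add_line('##source=mesplice-simulate')
    for chrom, seq in fx.sequences.items():
        header.contigs.add(chrom, length=len(seq))
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for t in fx.truth:
            rec = vcf.new_record(contig=t.chrom, start=t.pos - 1,
                                 alleles=(t.ref, t.alt))
            vcf.write(rec)

    truth_df = pd.DataFrame([t.__dict__ for t in fx.truth])
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

JOIN_KEYS = ["chrom", "pos", "ref", "alt", "transcript_id"]


@dataclass
class PerformanceReport:
    """Confusion counts and sensitivity/specificity, per region and overall.

    ``table`` is indexed by region label (plus ``overall``) with columns
    tp, fp, tn, fn, sensitivity, specificity; cells with an empty
    denominator are NaN (undefined), mirroring assay panels where e.g. no
    true negative exists in a region.
    """

    table: pd.DataFrame
    n_evaluated: int
    n_unmatched: int

    def row(self, region: str) -> pd.Series:
        return self.table.loc[region]

    @property
    def sensitivity(self) -> float:
        return float(self.table.loc["overall", "sensitivity"])

    @property
    def specificity(self) -> float:
        return float(self.table.loc["overall", "specificity"])


def _confusion(sub: pd.DataFrame) -> dict:
    tp = int(((sub.predicted_positive) & (sub.assay_outcome == "aberrant")).sum())
    fn = int(((~sub.predicted_positive) & (sub.assay_outcome == "aberrant")).sum())
    fp = int(((sub.predicted_positive) & (sub.assay_outcome == "normal")).sum())
    tn = int(((~sub.predicted_positive) & (sub.assay_outcome == "normal")).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def evaluate_tables(calls: pd.DataFrame, truth: pd.DataFrame) -> PerformanceReport:
    """Join calls to truth on (variant, transcript) and tabulate performance.

    ``calls`` needs columns chrom,pos,ref,alt,transcript_id,priority;
    ``truth`` needs the join keys plus region_label and assay_outcome.
    A positive prediction is priority high or moderate.
    """
    calls = calls.copy()
    truth = truth.copy()
    for df in (calls, truth):
        df["pos"] = df["pos"].astype(int)
        df["chrom"] = df["chrom"].astype(str)
    calls = calls.drop_duplicates(subset=JOIN_KEYS, keep="first")
    merged = truth.merge(calls[JOIN_KEYS + ["priority"]], on=JOIN_KEYS, how="left")
    unmatched = merged["priority"].isna()
    if unmatched.any():
        rows = merged.loc[unmatched, JOIN_KEYS].head(5).to_dict("records")
        warnings.warn(
            f"{int(unmatched.sum())} truth records had no matching call and "
            f"were excluded; first few: {rows}", stacklevel=2,
        )
    merged = merged.loc[~unmatched].copy()
    merged["predicted_positive"] = merged["priority"].isin(["high", "moderate"])
    rows = {}
    for region, sub in merged.groupby("region_label", sort=True):
        rows[region] = _confusion(sub)
    rows["overall"] = _confusion(merged)
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PerformanceReport(table, len(merged), int(unmatched.sum()))


def evaluate(calls, truth) -> PerformanceReport:
    """Evaluate SpliceogenicityCall objects against TruthRecords.

    ``calls`` pairs each call with its variant: an iterable of
    ``(NormalizedVariant, SpliceogenicityCall)``.
    """
    calls_df = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "transcript_id": c.transcript_id, "priority": c.priority,
            }
            for v, c in calls
        ]
    )
    truth_df = pd.DataFrame([t.__dict__ for t in truth])
    return evaluate_tables(calls_df, truth_df)


__all__ = [
    "FixtureSpec",
    "Fixture",
    "TruthRecord",
    "PerformanceReport",
    "GenerationError",
    "generate_fixture",
    "write_fixture",
    "evaluate",
    "evaluate_tables",
    "default_models",
    "DONOR_PWM",
    "ACCEPTOR_PWM",
    "DEFAULT_COUNTS",
]
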