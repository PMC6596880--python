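"""Strand-aware transcript structure, native splice sites and scoring windows.

Coordinate conventions: all file interfaces keep their standard 1-based
inclusive conventions (GTF/GFF3, VCF); everything internal is 0-based
half-open. Scoring always happens on the transcript sense strand, and
reverse-complementing is done exactly once, at sequence extraction.

Native-site geometry: a donor site is the 9-mer spanning the last 3 exonic
and first 6 intronic bases of an exon/intron junction; an acceptor site is
the 23-mer spanning the last 20 intronic and first 3 exonic bases of an
intron/exon junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from ._sequences import has_ambiguous, reverse_complement

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3

K_BY_SITE_TYPE = {"donor": 9, "acceptor": 23}


class AnnotationError(ValueError):
    """Malformed annotation input."""


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the genome sequence."""


class UnsupportedVariantError(ValueError):
    """Symbolic, breakend or otherwise unscorable allele."""


class TruncatedWindowError(ValueError):
    """Scoring windows run past the end of the chromosome."""

    def __init__(self, message: str, missing_frames: list[int]):
        super().__init__(message)
        self.missing_frames = missing_frames


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise AnnotationError(f"inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of exons.

    ``exons`` are stored 5'->3' in transcript orientation: genomically
    ascending on '+', descending on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def span(self) -> Interval:
        return Interval(self.start, self.end)

    def introns(self) -> list[Interval]:
        """Introns in transcript orientation (genomic coordinates)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(Interval(a.end, b.start))
            else:
                out.append(Interval(b.end, a.start))
        return out


@dataclass(frozen=True)
class NativeSpliceSite:
    transcript_id: str
    chrom: str
    strand: str
    site_type: str  # donor | acceptor
    span: Interval  # genomic span of the 9-mer / 23-mer
    exon_index: int  # transcript-orientation index of the flanking exon
    # genomic coordinate of the exon/intron boundary (0-based, the first
    # intronic base for '+' donors etc.); used for indel re-anchoring
    boundary: int = 0

    @property
    def k(self) -> int:
        return K_BY_SITE_TYPE[self.site_type]

    def dinucleotide_span(self) -> Interval:
        """Genomic span of the near-invariant GT / AG dinucleotide."""
        if self.site_type == "donor":
            off = 3 if self.strand == "+" else 4
        else:
            off = 18 if self.strand == "+" else 3
        return Interval(self.span.start + off, self.span.start + off + 2)


@dataclass(frozen=True)
class NormalizedVariant:
    """Left-aligned, parsimony-trimmed variant (VCF-style 1-based pos).

    ``zone`` is the genomic 0-based half-open interval of bases the edit can
    touch under any repeat-equivalent placement (for substitutions the
    replaced block; for deletions the union of all equivalently deletable
    bases); ``zone_kind`` is ``"block"`` for those, or ``"junction"`` for
    pure insertions, where ``zone`` holds the inclusive range of equivalent
    insertion points instead. :func:`normalize_variant` fills these; when
    absent, anchor-based fallbacks are used.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zone: tuple[int, int] | None = None
    zone_kind: str | None = None

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return "insertion"
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return "deletion"
        return "complex"

    @property
    def start(self) -> int:
        """0-based start of the REF span."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the REF span."""
        return self.pos - 1 + len(self.ref)

    def _block_zone(self) -> tuple[int, int] | None:
        if self.zone is not None and self.zone_kind == "block":
            return self.zone
        if self.zone is None and self.variant_class != "insertion":
            return (self.start, self.end) if self.variant_class != "SNV" \
                else (self.start, self.end)
        return None

    def _junction_points(self) -> tuple[int, int] | None:
        if self.zone is not None and self.zone_kind == "junction":
            return self.zone
        if self.zone is None and self.variant_class == "insertion":
            j = self.start + 1
            return (j, j)
        return None

    def affected_interval(self) -> Interval:
        """Genomic interval used for overlap/side tests."""
        block = self._block_zone()
        if block is not None:
            return Interval(*block)
        j0, j1 = self._junction_points()
        return Interval(j0, j1)

    def overlaps_interval(self, iv: Interval) -> bool:
        """Does the edit touch bases of ``iv`` (or, for a pure insertion,
        can it be placed strictly inside it)?"""
        block = self._block_zone()
        if block is not None:
            return Interval(*block).overlaps(iv)
        j0, j1 = self._junction_points()
        # some equivalent insertion point strictly inside the interval
        return max(j0, iv.start + 1) <= min(j1, iv.end - 1)

    def overlaps_site(self, site: NativeSpliceSite) -> bool:
        return self.overlaps_interval(site.span)


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------

def parse_transcripts(annotation_path) -> list[TranscriptModel]:
    """Parse GTF or GFF3 exon features into transcript models."""
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tx_ids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tx_ids:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} has no "
                "transcript_id/Parent attribute"
            )
        for tx_id in tx_ids:
            entry = grouped.setdefault(
                tx_id, {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            if entry["chrom"] != feat.seqid or entry["strand"] != feat.strand:
                raise AnnotationError(
                    f"{tx_id}: exons on multiple chromosomes/strands"
                )
            # GTF/GFF3 are 1-based inclusive; internal is 0-based half-open
            entry["exons"].append(Interval(feat.start - 1, feat.end))
    transcripts = []
    for tx_id in grouped:
        entry = grouped[tx_id]
        if not entry["exons"]:
            warnings.warn(f"{tx_id}: no exons, skipped", stacklevel=2)
            continue
        transcripts.append(
            TranscriptModel(tx_id, entry["chrom"], entry["strand"], entry["exons"])
        )
    return transcripts


def native_sites(tx: TranscriptModel) -> list[NativeSpliceSite]:
    """Native donor and acceptor sites of a transcript (Fig-style geometry).

    A transcript with E exons has E-1 donors and E-1 acceptors. Sites whose
    exonic or intronic context does not fit (tiny exon, intron shorter than
    the motif's intronic reach) are omitted with a warning.
    """
    sites: list[NativeSpliceSite] = []
    for i, (up, down) in enumerate(zip(tx.exons, tx.exons[1:])):
        intron = tx.introns()[i]
        # donor at the 3' end of exon i
        if len(intron) < DONOR_INTRONIC or len(up) < DONOR_EXONIC:
            warnings.warn(
                f"{tx.transcript_id}: donor after exon {i} omitted "
                f"(intron {len(intron)} nt / exon {len(up)} nt too short)",
                stacklevel=2,
            )
        else:
            if tx.strand == "+":
                span = Interval(up.end - DONOR_EXONIC, up.end + DONOR_INTRONIC)
                boundary = up.end
            else:
                span = Interval(up.start - DONOR_INTRONIC, up.start + DONOR_EXONIC)
                boundary = up.start
            sites.append(
                NativeSpliceSite(tx.transcript_id, tx.chrom, tx.strand,
                                 "donor", span, i, boundary)
            )
        # acceptor at the 5' end of exon i+1
        if len(intron) < ACCEPTOR_INTRONIC or len(down) < ACCEPTOR_EXONIC:
            warnings.warn(
                f"{tx.transcript_id}: acceptor before exon {i + 1} omitted "
                f"(intron {len(intron)} nt / exon {len(down)} nt too short)",
                stacklevel=2,
            )
        else:
            if tx.strand == "+":
                span = Interval(down.start - ACCEPTOR_INTRONIC,
                                down.start + ACCEPTOR_EXONIC)
                boundary = down.start
            else:
                span = Interval(down.end - ACCEPTOR_EXONIC,
                                down.end + ACCEPTOR_INTRONIC)
                boundary = down.end
            sites.append(
                NativeSpliceSite(tx.transcript_id, tx.chrom, tx.strand,
                                 "acceptor", span, i + 1, boundary)
            )
    return sites


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------

def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand sequence for a 0-based half-open interval.

    ``genome`` may be a pyfaidx.Fasta, a pysam.FastaFile or a plain
    ``{chrom: sequence}`` mapping.
    """
    start = max(start, 0)
    if hasattr(genome, "fetch"):  # pysam
        return genome.fetch(chrom, start, end).upper()
    seq = genome[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        return str(seq[start:end]).upper()  # pyfaidx
    return seq[start:end].upper()


def contig_length(genome, chrom: str) -> int:
    if hasattr(genome, "get_reference_length"):
        return genome.get_reference_length(chrom)
    return len(genome[chrom])


def site_sequence(genome, site: NativeSpliceSite) -> str:
    """Sense-strand motif sequence of a native site."""
    plus = fetch(genome, site.chrom, site.span.start, site.span.end)
    return reverse_complement(plus) if site.strand == "-" else plus


# ---------------------------------------------------------------------------
# variant normalization
# ---------------------------------------------------------------------------

_SYMBOLIC = ("<", "[", "]", ".")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      genome) -> NormalizedVariant:
    """Left-align and parsimony-trim a single (ref, alt) pair.

    ``pos`` is 1-based as in VCF. REF is validated against the genome.
    Symbolic and breakend alleles are rejected with
    :class:`UnsupportedVariantError`.
    """
    if any(c in alt for c in _SYMBOLIC) or alt == "*":
        raise UnsupportedVariantError(f"{chrom}:{pos} symbolic alt {alt!r}")
    ref, alt = ref.upper(), alt.upper()
    if has_ambiguous(ref) or has_ambiguous(alt):
        raise UnsupportedVariantError(f"{chrom}:{pos} ambiguous bases in alleles")
    if ref == alt:
        raise UnsupportedVariantError(f"{chrom}:{pos} REF equals ALT ({ref})")
    observed = fetch(genome, chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {ref!r} does not match genome {observed!r}"
        )
    # right-trim shared suffix, extending left through the genome whenever an
    # allele would empty out (classical left-alignment)
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                ref, alt = ref + observed[-1], alt + observed[-1]  # cannot shift
                break
            pos -= 1
            b = fetch(genome, chrom, pos - 1, pos)
            ref, alt = b + ref, b + alt
            observed = b  # only the last base matters for the edge guard
    # left-trim shared prefix, keeping at least one base per allele
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    v = NormalizedVariant(chrom, pos, ref, alt)
    # repeat-aware edit zone: the bases (or insertion points) the edit can
    # occupy under any equivalent alignment, so overlap tests do not depend
    # on left-alignment and are symmetric under genome mirroring
    flank = 64 + max(len(ref), len(alt))
    lo, ref_local, alt_local, _ = build_local_haplotypes(genome, v, flank)
    p, s = _common_affix(ref_local, alt_local)
    n_ref = len(ref_local)
    if len(ref) == len(alt) or v.variant_class == "complex":
        zone, kind = (lo + p, lo + n_ref - s), "block"
    elif v.variant_class == "deletion":
        dlen = len(ref) - len(alt)
        zone, kind = (lo + n_ref - s - dlen, lo + p + dlen), "block"
    else:  # insertion: inclusive range of equivalent insertion points
        zone, kind = (lo + n_ref - s, lo + p), "junction"
    return NormalizedVariant(chrom, pos, ref, alt, zone=zone, zone_kind=kind)


def normalize_record(record, genome) -> list[NormalizedVariant]:
    """Decompose and normalize a pysam VariantRecord (one per alt allele).

    Unsupported alleles are skipped with a warning.
    """
    out = []
    for alt in record.alts or ():
        try:
            out.append(
                normalize_variant(record.chrom, record.pos, record.ref, alt, genome)
            )
        except UnsupportedVariantError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# sliding-window sequence extraction
# ---------------------------------------------------------------------------

def build_local_haplotypes(genome, v: NormalizedVariant, flank: int):
    """Reference and alternate plus-strand context around a variant.

    Returns ``(lo, ref_local, alt_local, a0)`` where ``lo`` is the genomic
    0-based coordinate of the first local base and ``a0`` the local offset
    of the variant's first REF base in both strings.
    """
    lo = max(v.start - flank, 0)
    hi = min(v.end + flank, contig_length(genome, v.chrom))
    ref_local = fetch(genome, v.chrom, lo, hi)
    a0 = v.start - lo
    alt_local = ref_local[:a0] + v.alt + ref_local[a0 + len(v.ref):]
    return lo, ref_local, alt_local, a0


def _common_affix(a: str, b: str) -> tuple[int, int]:
    """Longest common prefix and suffix lengths of two strings.

    The suffix is deliberately not capped by the prefix: their overlap
    measures the repeat ambiguity of where an indel sits.
    """
    limit = min(len(a), len(b))
    p = 0
    while p < limit and a[p] == b[p]:
        p += 1
    s = 0
    while s < limit and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    return p, s


def _edit_region(ref_local: str, alt_local: str, haplotype: str):
    """Plus-strand local interval of the bases 'belonging to' the edit.

    Derived purely from the two haplotype strings: the bases outside their
    longest common prefix/suffix (the substituted or inserted block), or,
    when prefix and suffix meet (a pure deletion, or an insertion seen from
    the reference side), the bases adjacent to every repeat-equivalent
    placement of the junction. This makes the window set independent of how
    the variant was left-aligned and symmetric under genome mirroring.
    """
    local = ref_local if haplotype == "ref" else alt_local
    other = alt_local if haplotype == "ref" else ref_local
    n = len(local)
    p, s = _common_affix(local, other)
    if p < n - s:
        return p, n - s  # substituted / inserted block
    # junction case: every equivalent junction lies in [n - s, p]; take the
    # bases flanking any of them
    return max(n - s - 1, 0), min(p + 1, n)


def window_sequences(genome, tx: TranscriptModel, v: NormalizedVariant,
                     k: int, haplotype: str,
                     on_truncate: str = "raise"):
    """All k-mers of the chosen haplotype in which the allele occupies a
    window position, on the transcript sense strand.

    Returns ``(frames, flags)`` where ``frames`` is an ordered list of
    ``(frame, kmer)`` pairs. ``frame`` is the 1-based window position of the
    allele's first (sense-strand) base; frames are ordered descending from
    ``k``, so an SNV yields exactly ``k`` windows with the variant base at
    positions k, k-1, ..., 1. Alleles longer than 1 nt extend the frame
    range below 1 (first base 5' of the window while later allele bases
    remain inside).

    Windows containing ambiguous bases are omitted (flag
    ``windows_skipped_N``); windows running past the chromosome end raise
    :class:`TruncatedWindowError`, or are dropped with flag ``truncated``
    when ``on_truncate="flag"``.
    """
    if k not in (9, 23):
        raise ValueError(f"window length must be 9 or 23, got {k}")
    if haplotype not in ("ref", "alt"):
        raise ValueError(f"haplotype must be 'ref' or 'alt', got {haplotype!r}")
    # the edit zone can outgrow the allele span in repeat runs, so enlarge
    # the local context until every window fits (or the contig ends)
    flank = k + max(len(v.ref), len(v.alt))
    n_contig = contig_length(genome, v.chrom)
    while True:
        lo, ref_local, alt_local, a0 = build_local_haplotypes(genome, v, flank)
        local = ref_local if haplotype == "ref" else alt_local
        es, ee = _edit_region(ref_local, alt_local, haplotype)
        need_left = es - (k - 1)
        need_right = ee + (k - 1)
        left_ok = need_left >= 0 or lo == 0
        right_ok = need_right <= len(local) or lo + len(ref_local) >= n_contig
        if left_ok and right_ok:
            break
        flank *= 2
    m = ee - es  # number of edit-zone bases

    # map to sense coordinates
    if tx.strand == "+":
        sense = local
        s_es, s_ee = es, ee
    else:
        sense = reverse_complement(local)
        s_es, s_ee = len(local) - ee, len(local) - es

    frames: list[tuple[int, str]] = []
    flags: set[str] = set()
    missing: list[int] = []
    # window start w in sense coords; frame = s_es - w + 1
    for frame in range(k, 1 - m, -1):
        w = s_es - frame + 1
        if w < 0 or w + k > len(sense):
            missing.append(frame)
            continue
        kmer = sense[w:w + k]
        if has_ambiguous(kmer):
            flags.add("windows_skipped_N")
            continue
        frames.append((frame, kmer))
    if missing:
        # distinguish a true chromosome edge from the local-context clip
        if on_truncate == "raise":
            raise TruncatedWindowError(
                f"{v.chrom}:{v.pos} windows truncated at contig edge; "
                f"missing frames {missing}",
                missing,
            )
        flags.add("truncated")
    return frames, flags


def mirror_genome(sequences: dict[str, str]) -> dict[str, str]:
    """Reverse-complement every contig (fixture mirror-symmetry checks)."""
    return {c: reverse_complement(s) for c, s in sequences.items()}


def transcripts_overlapping(transcripts: Sequence[TranscriptModel],
                            v: NormalizedVariant) -> list[TranscriptModel]:
    iv = v.affected_interval()
    s, e = iv.start, max(iv.end, iv.start + 1)
    return [
        tx for tx in transcripts
        if tx.chrom == v.chrom and s < tx.end and tx.start < e
    ]


__all__ = [
    "Interval",
    "TranscriptModel",
    "NativeSpliceSite",
    "NormalizedVariant",
    "parse_transcripts",
    "native_sites",
    "normalize_variant",
    "normalize_record",
    "window_sequences",
    "build_local_haplotypes",
    "site_sequence",
    "fetch",
    "contig_length",
    "transcripts_overlapping",
    "mirror_genome",
    "AnnotationError",
    "ReferenceMismatchError",
    "UnsupportedVariantError",
    "TruncatedWindowError",
]
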