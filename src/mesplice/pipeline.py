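"""End-to-end annotation: VCF + GTF + FASTA in, annotated VCF + TSV out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

from . import __version__
from .annotation import (
    NormalizedVariant,
    ReferenceMismatchError,
    UnsupportedVariantError,
    normalize_variant,
    parse_transcripts,
    transcripts_overlapping,
)
from .classify import SpliceogenicityCall, Thresholds, assess_variant
from .models import SpliceSiteModel

log = logging.getLogger("mesplice")

INFO_KEYS = [
    "MES_TX", "MES_REF", "MES_ALT", "MES_DIFF",
    "MES_SWA_DONOR_ALT", "MES_SWA_DONOR_REF", "MES_SWA_DONOR_REF_COMP",
    "MES_SWA_DONOR_DIFF",
    "MES_SWA_ACCEPTOR_ALT", "MES_SWA_ACCEPTOR_REF",
    "MES_SWA_ACCEPTOR_REF_COMP", "MES_SWA_ACCEPTOR_DIFF",
    "MES_NCSS_UP_DONOR", "MES_NCSS_UP_ACCEPTOR",
    "MES_NCSS_DOWN_DONOR", "MES_NCSS_DOWN_ACCEPTOR",
    "MES_CALL", "MES_PRIORITY",
]

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "transcript_id", "variant_class",
    "region_label", "native_site_type", "native_ref", "native_alt",
    "native_diff",
    "swa_donor_alt", "swa_donor_ref", "swa_donor_ref_comp", "swa_donor_diff",
    "swa_acceptor_alt", "swa_acceptor_ref", "swa_acceptor_ref_comp",
    "swa_acceptor_diff",
    "ncss_up_donor", "ncss_up_acceptor", "ncss_down_donor",
    "ncss_down_acceptor",
    "mechanism", "priority", "downgraded", "flags",
]


class ContigMismatchError(ValueError):
    """Contig names are inconsistent across VCF/GTF/FASTA inputs."""


def fmt(x, missing=".") -> str:
    """2-decimal text rendering; distinct encoding for missing values."""
    if x is None:
        return missing
    try:
        if x != x:  # NaN
            return missing
    except TypeError:
        pass
    return f"{float(x):.2f}"


@dataclass
class AnnotationRecord:
    """One (variant, transcript) row of the output panel."""

    variant: NormalizedVariant
    call: SpliceogenicityCall

    def fields(self, missing=".") -> dict[str, str]:
        v, c = self.variant, self.call
        ev = c.evidence
        natives = ev.get("native") or []
        # the native panel shows the site backing the call when there is
        # one, otherwise the first overlapped site
        native = None
        if natives:
            native = next(
                (n for n in natives
                 if c.site_type and n.site.site_type == c.site_type),
                natives[0],
            )
        swa = ev.get("swa") or {}
        ncss = ev.get("ncss")
        out = {
            "chrom": v.chrom, "pos": str(v.pos), "ref": v.ref, "alt": v.alt,
            "transcript_id": c.transcript_id or missing,
            "variant_class": v.variant_class,
            "region_label": c.region_label or missing,
            "native_site_type": native.site.site_type if native else missing,
            "native_ref": fmt(native.ref_score, missing) if native else missing,
            "native_alt": fmt(native.alt_score, missing) if native else missing,
            "native_diff": fmt(native.diff, missing) if native else missing,
            "mechanism": c.mechanism,
            "priority": c.priority,
            "downgraded": str(c.downgraded).lower(),
            "flags": ";".join(sorted(c.flags)) if c.flags else missing,
        }
        for st in ("donor", "acceptor"):
            r = swa.get(st)
            out[f"swa_{st}_alt"] = fmt(r.alt_best.score, missing) if r and r.alt_best else missing
            out[f"swa_{st}_ref"] = fmt(r.ref_best.score, missing) if r and r.ref_best else missing
            out[f"swa_{st}_ref_comp"] = fmt(r.ref_comp, missing) if r else missing
            out[f"swa_{st}_diff"] = fmt(r.diff, missing) if r else missing
        for slot in ("upstream_donor", "upstream_acceptor",
                     "downstream_donor", "downstream_acceptor"):
            s = getattr(ncss, slot) if ncss else None
            key = slot.replace("upstream", "ncss_up").replace("downstream", "ncss_down")
            out[key] = fmt(s.score, missing) if s else missing
        return out


def check_contigs(fasta_contigs: set[str], gtf_contigs: set[str],
                  vcf_contigs: set[str]) -> None:
    problems = []
    missing_gtf = gtf_contigs - fasta_contigs
    if missing_gtf:
        problems.append(f"GTF contigs absent from FASTA: {sorted(missing_gtf)}")
    if vcf_contigs:
        missing_vcf = vcf_contigs - fasta_contigs
        if missing_vcf:
            problems.append(f"VCF contigs absent from FASTA: {sorted(missing_vcf)}")
    if problems:
        raise ContigMismatchError("; ".join(problems))


def annotate_vcf(
    vcf_in,
    gtf,
    fasta,
    models: dict[str, SpliceSiteModel],
    thresholds: Thresholds | None = None,
    out_vcf=None,
    out_tsv=None,
) -> list[AnnotationRecord]:
    """Annotate every VCF record against every overlapping transcript.

    Input records are preserved (order and core fields); overlapping
    (variant, transcript) pairs gain the MES_* INFO keys, pipe-delimited in
    parallel with MES_TX. Returns the per-pair annotation records.
    """
    import pyfaidx

    thresholds = thresholds or Thresholds()
    genome = pyfaidx.Fasta(str(fasta), sequence_always_upper=True)
    transcripts = sorted(parse_transcripts(gtf), key=lambda t: t.transcript_id)

    vf = pysam.VariantFile(str(vcf_in))
    # records stay bound to the input header, so the INFO keys must be
    # declared there as well as in the output header
    for key in INFO_KEYS:
        if key not in vf.header.info:
            # one pipe-delimited string per record, parallel across MES_TX
            vf.header.info.add(key, "1", "String",
                               f"mesplice {__version__} splice assessment field")
    header = vf.header.copy()

    check_contigs(set(genome.keys()),
                  {t.chrom for t in transcripts},
                  set(vf.header.contigs))

    records: list[AnnotationRecord] = []
    stats = {"seen": 0, "annotated": 0, "skipped_alleles": 0, "passthrough": 0}
    out_handle = pysam.VariantFile(str(out_vcf), "w", header=header) if out_vcf else None
    tsv_handle = open(out_tsv, "w") if out_tsv else None
    if tsv_handle:
        tsv_handle.write(
            f"# mesplice {__version__} thresholds: high_alt_cut="
            f"{thresholds.high_alt_cut} low_alt_cut={thresholds.low_alt_cut} "
            f"downgrade_diff_cut={thresholds.downgrade_diff_cut}\n"
        )
        tsv_handle.write("\t".join(TSV_COLUMNS) + "\n")
    try:
        for rec in vf:
            stats["seen"] += 1
            if rec.chrom not in genome.keys():
                raise ContigMismatchError(
                    f"VCF record contig {rec.chrom!r} absent from FASTA"
                )
            rec_annotations: list[AnnotationRecord] = []
            multi = len(rec.alts or ()) > 1
            for alt in rec.alts or ():
                try:
                    v = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, genome)
                except (UnsupportedVariantError, ReferenceMismatchError) as exc:
                    stats["skipped_alleles"] += 1
                    log.warning("skipping allele: %s", exc)
                    continue
                for tx in transcripts_overlapping(transcripts, v):
                    call = assess_variant(v, tx, genome, models, thresholds)
                    rec_annotations.append(AnnotationRecord(v, call))
            if rec_annotations:
                stats["annotated"] += 1
                if out_handle is not None:
                    _write_info(rec, rec_annotations, multi)
            else:
                stats["passthrough"] += 1
            if out_handle is not None:
                out_handle.write(rec)
            if tsv_handle is not None:
                for a in rec_annotations:
                    f = a.fields(missing="NA")
                    tsv_handle.write("\t".join(f[c] for c in TSV_COLUMNS) + "\n")
            records.extend(rec_annotations)
    finally:
        vf.close()
        if out_handle is not None:
            out_handle.close()
        if tsv_handle is not None:
            tsv_handle.close()
    log.info(
        "annotate: %(seen)d records seen, %(annotated)d annotated, "
        "%(passthrough)d passed through, %(skipped_alleles)d alleles skipped",
        stats,
    )
    return records


def _write_info(rec, annotations: Sequence[AnnotationRecord], multi: bool) -> None:
    cols = {key: [] for key in INFO_KEYS}
    for a in annotations:
        f = a.fields(missing=".")
        tx = f["transcript_id"]
        cols["MES_TX"].append(f"{a.variant.alt}:{tx}" if multi else tx)
        cols["MES_REF"].append(f["native_ref"])
        cols["MES_ALT"].append(f["native_alt"])
        cols["MES_DIFF"].append(f["native_diff"])
        for st in ("DONOR", "ACCEPTOR"):
            lo = st.lower()
            cols[f"MES_SWA_{st}_ALT"].append(f[f"swa_{lo}_alt"])
            cols[f"MES_SWA_{st}_REF"].append(f[f"swa_{lo}_ref"])
            cols[f"MES_SWA_{st}_REF_COMP"].append(f[f"swa_{lo}_ref_comp"])
            cols[f"MES_SWA_{st}_DIFF"].append(f[f"swa_{lo}_diff"])
        cols["MES_NCSS_UP_DONOR"].append(f["ncss_up_donor"])
        cols["MES_NCSS_UP_ACCEPTOR"].append(f["ncss_up_acceptor"])
        cols["MES_NCSS_DOWN_DONOR"].append(f["ncss_down_donor"])
        cols["MES_NCSS_DOWN_ACCEPTOR"].append(f["ncss_down_acceptor"])
        cols["MES_CALL"].append(f["mechanism"])
        cols["MES_PRIORITY"].append(f["priority"])
    for key, values in cols.items():
        rec.info[key] = "|".join(values)


# ---------------------------------------------------------------------------
# batch k-mer scoring
# ---------------------------------------------------------------------------

def score_kmers(lines: Iterable[str], model: SpliceSiteModel):
    """Score a stream of uniform-length k-mers; yields (sequence, score).

    Mixed lengths raise a ValueError naming the first offending line.
    """
    expected = model.motif_length
    for i, line in enumerate(lines, start=1):
        seq = line.strip()
        if not seq:
            continue
        if len(seq) != expected:
            raise ValueError(
                f"line {i}: expected a {expected}-mer for "
                f"{model.site_type} scoring, got {len(seq)} nt ({seq!r})"
            )
        yield seq, model.score_seq(seq)


__all__ = [
    "annotate_vcf",
    "score_kmers",
    "AnnotationRecord",
    "ContigMismatchError",
    "INFO_KEYS",
    "TSV_COLUMNS",
    "fmt",
]
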