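"""Per-(variant, transcript) splice score sets.

Three score sets are computed for a variant against one transcript:

* native-site scores — reference and alternate motif scores (and their
  difference) for every native donor/acceptor site the variant overlaps;
* MES-SWA — a sliding-window search in which the variant allele occupies
  every window position in turn, on both haplotypes, with a frame-matched
  comparison score so losses and gains are read off a like-for-like
  ``diff = reference-side − alternate-side``;
* MES-NCSS — the nearest native donor and acceptor sites upstream and
  downstream of the variant (transcript orientation), scored on the
  reference haplotype, used as the competition baseline for gain calls.

Sign convention everywhere: positive diff ⇔ the reference scores higher
(loss direction); negative diff ⇔ the alternate scores higher (gain
direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._sequences import AmbiguousBaseError, reverse_complement
from .annotation import (
    NativeSpliceSite,
    NormalizedVariant,
    TranscriptModel,
    build_local_haplotypes,
    native_sites,
    site_sequence,
    window_sequences,
)
from .models import SpliceSiteModel

# plus-strand offsets of a native motif around its boundary coordinate,
# keyed by (site_type, strand): span = [boundary + left, boundary + right)
_BOUNDARY_OFFSETS = {
    ("donor", "+"): (-3, 6),
    ("donor", "-"): (-6, 3),
    ("acceptor", "+"): (-20, 3),
    ("acceptor", "-"): (-3, 20),
}


@dataclass
class NativeSiteScores:
    site: NativeSpliceSite
    ref_score: float
    alt_score: float | None
    flags: set[str] = field(default_factory=set)

    @property
    def diff(self) -> float | None:
        if self.alt_score is None:
            return None
        return self.ref_score - self.alt_score


@dataclass(frozen=True)
class Window:
    frame: int
    sequence: str
    score: float


@dataclass
class SWAResult:
    site_type: str
    alt_best: Window | None
    ref_best: Window | None
    ref_comp: float | None  # frame-matched comparison score (see module doc)
    diff: float | None
    flags: set[str] = field(default_factory=set)

    @property
    def available(self) -> bool:
        return self.alt_best is not None and self.diff is not None

    @property
    def effective_alt(self) -> float | None:
        """The alternate-side score entering the diff."""
        if not self.available:
            return None
        if "non_snv_comparison" in self.flags:
            return self.ref_comp  # mapped alt window at the ref-best frame
        return self.alt_best.score

    @property
    def effective_ref(self) -> float | None:
        if not self.available:
            return None
        if "non_snv_comparison" in self.flags:
            return self.ref_best.score
        return self.ref_comp


@dataclass
class NCSSSlot:
    site: NativeSpliceSite
    score: float | None
    distance: int


@dataclass
class NCSSResult:
    upstream_donor: NCSSSlot | None = None
    upstream_acceptor: NCSSSlot | None = None
    downstream_donor: NCSSSlot | None = None
    downstream_acceptor: NCSSSlot | None = None

    def slots(self) -> dict[str, NCSSSlot | None]:
        return {
            "upstream_donor": self.upstream_donor,
            "upstream_acceptor": self.upstream_acceptor,
            "downstream_donor": self.downstream_donor,
            "downstream_acceptor": self.downstream_acceptor,
        }

    def nearest_same_type(self, site_type: str) -> NCSSSlot | None:
        """Nearest native site of the given type over both directions."""
        cands = [
            s for name, s in self.slots().items()
            if s is not None and name.endswith(site_type)
        ]
        if not cands:
            return None
        return min(cands, key=lambda s: s.distance)


# ---------------------------------------------------------------------------
# native-site scoring
# ---------------------------------------------------------------------------

def _project_boundary(xb: int, ref_local: str, alt_local: str,
                      strand: str) -> int | None:
    """Project a local junction point through the edit into alt coordinates.

    Points inside the common prefix map to themselves, points inside the
    common suffix shift by the length difference; a point valid under both
    readings (a repeat straddling the edit) anchors to its sense-5'
    placement, which mirrors consistently. A point strictly inside a
    replaced/deleted block has no image (returns None).
    """
    from .annotation import _common_affix

    p, s = _common_affix(ref_local, alt_local)
    delta = len(alt_local) - len(ref_local)
    in_prefix = xb <= p
    in_suffix = xb >= len(ref_local) - s
    if in_prefix and in_suffix:
        return xb if strand == "+" else xb + delta
    if in_prefix:
        return xb
    if in_suffix:
        return xb + delta
    return None


def score_native_sites(v: NormalizedVariant, tx: TranscriptModel, genome,
                       models: dict[str, SpliceSiteModel],
                       sites: list[NativeSpliceSite] | None = None,
                       ) -> list[NativeSiteScores]:
    """Reference/alternate motif scores for every native site ``v`` overlaps.

    SNVs (and length-preserving MNVs) score the same genomic span on both
    haplotypes. Length-changing variants re-anchor the alternate motif at
    the biological boundary (exon end for donors, exon start for acceptors)
    projected through the edit; if the edit removes the boundary itself the
    alternate score is left to the sliding-window path and flagged.
    """
    if sites is None:
        sites = native_sites(tx)
    out: list[NativeSiteScores] = []
    delta = len(v.alt) - len(v.ref)
    for site in sites:
        if not v.overlaps_site(site):
            continue
        model = models[site.site_type]
        ref_motif = site_sequence(genome, site)
        try:
            ref_score = model.score_seq(ref_motif)
        except AmbiguousBaseError:
            out.append(NativeSiteScores(site, float("nan"), None,
                                        {"ambiguous_reference_motif"}))
            continue
        flags: set[str] = set()
        flank = 2 * site.k + max(len(v.ref), len(v.alt))
        lo, ref_local, alt_local, _ = build_local_haplotypes(genome, v, flank)
        if delta == 0:
            s, e = site.span.start - lo, site.span.end - lo
        else:
            b_alt = _project_boundary(site.boundary - lo, ref_local,
                                      alt_local, site.strand)
            if b_alt is None:
                out.append(NativeSiteScores(
                    site, ref_score, None, {"native_boundary_removed"}))
                continue
            left, right = _BOUNDARY_OFFSETS[(site.site_type, site.strand)]
            s, e = b_alt + left, b_alt + right
        if s < 0 or e > len(alt_local):
            out.append(NativeSiteScores(site, ref_score, None, {"truncated"}))
            continue
        alt_motif = alt_local[s:e]
        if site.strand == "-":
            alt_motif = reverse_complement(alt_motif)
        try:
            alt_score = model.score_seq(alt_motif)
        except AmbiguousBaseError:
            out.append(NativeSiteScores(site, ref_score, None,
                                        {"ambiguous_alt_motif"}))
            continue
        out.append(NativeSiteScores(site, ref_score, alt_score, flags))
    return out


# ---------------------------------------------------------------------------
# MES-SWA
# ---------------------------------------------------------------------------

def _best(windows: list[Window]) -> Window | None:
    """Highest-scoring window; ties resolved to the 5'-most frame (windows
    arrive ordered 5'->3' along the sense strand)."""
    best = None
    for w in windows:
        if best is None or w.score > best.score:
            best = w
    return best


def _score_windows(model, frames) -> tuple[list[Window], set[str]]:
    out = []
    flags: set[str] = set()
    for frame, seq in frames:
        try:
            out.append(Window(frame, seq, model.score_seq(seq)))
        except AmbiguousBaseError:
            flags.add("windows_skipped_N")
    return out, flags


def run_swa(v: NormalizedVariant, tx: TranscriptModel, genome,
            models: dict[str, SpliceSiteModel], site_type: str) -> SWAResult:
    """Sliding-window search for the fittest potential site around ``v``.

    The alternate allele slides from window position k to 1; the best
    alternate and best reference windows are retained together with a
    frame-matched comparison score: for SNVs the reference window at the
    best alternate frame; for length-changing variants the alternate window
    whose 5' end is the best reference window's 5' end projected through
    the edit. ``diff`` is uniformly reference-side minus alternate-side.
    """
    model = models[site_type]
    k = model.motif_length
    alt_frames, alt_flags = window_sequences(genome, tx, v, k, "alt",
                                             on_truncate="flag")
    ref_frames, ref_flags = window_sequences(genome, tx, v, k, "ref",
                                             on_truncate="flag")
    flags = alt_flags | ref_flags
    alt_windows, f1 = _score_windows(model, alt_frames)
    ref_windows, f2 = _score_windows(model, ref_frames)
    flags |= f1 | f2
    alt_best = _best(alt_windows)
    ref_best = _best(ref_windows)
    if alt_best is None or ref_best is None:
        flags.add("assessment_unavailable")
        return SWAResult(site_type, alt_best, ref_best, None, None, flags)

    if v.variant_class == "SNV":
        by_frame = {w.frame: w for w in ref_windows}
        match = by_frame.get(alt_best.frame)
        if match is None:
            flags.add("comparison_unavailable")
            return SWAResult(site_type, alt_best, ref_best, None, None, flags)
        ref_comp = match.score
        diff = ref_comp - alt_best.score
        return SWAResult(site_type, alt_best, ref_best, ref_comp, diff, flags)

    # non-SNV: the best reference window's frame picks the alternate-side
    # comparison window. Frames are indexed off the haplotypes' edit zones,
    # so this matching is invariant to left-alignment and strand. A ref
    # frame below the alternate zone's range (possible when a long deleted
    # block is wider than the junction zone) clamps to the nearest frame.
    flags.add("non_snv_comparison")
    by_frame = {w.frame: w for w in alt_windows}
    match = by_frame.get(ref_best.frame)
    if match is None and by_frame:
        nearest = min(by_frame, key=lambda f: (abs(f - ref_best.frame), -f))
        match = by_frame[nearest]
        flags.add("comparison_frame_clamped")
    if match is None:
        flags.add("comparison_unavailable")
        return SWAResult(site_type, alt_best, ref_best, None, None, flags)
    alt_comp = match.score
    diff = ref_best.score - alt_comp
    return SWAResult(site_type, alt_best, ref_best, alt_comp, diff, flags)


# ---------------------------------------------------------------------------
# MES-NCSS
# ---------------------------------------------------------------------------

def run_ncss(v: NormalizedVariant, tx: TranscriptModel, genome,
             models: dict[str, SpliceSiteModel],
             sites: list[NativeSpliceSite] | None = None) -> NCSSResult:
    """Nearest native donor/acceptor on each side of the variant.

    Sides are in transcript orientation; a slot holds the nearest native
    site of its type whose motif span lies entirely on that side, scored on
    the reference haplotype. Absent slots stay None.
    """
    if sites is None:
        sites = native_sites(tx)
    iv = v.affected_interval()
    v_start, v_end = iv.start, max(iv.end, iv.start + 1)
    result = NCSSResult()
    best: dict[tuple[str, str], tuple[int, NativeSpliceSite]] = {}
    for site in sites:
        if site.span.end <= v_start:
            side_genomic = "left"
            dist = v_start - site.span.end + 1
        elif site.span.start >= v_end:
            side_genomic = "right"
            dist = site.span.start - v_end + 1
        else:
            continue  # overlapping the variant: on neither side
        if tx.strand == "+":
            side = "upstream" if side_genomic == "left" else "downstream"
        else:
            side = "downstream" if side_genomic == "left" else "upstream"
        key = (side, site.site_type)
        if key not in best or dist < best[key][0]:
            best[key] = (dist, site)
    for (side, site_type), (dist, site) in best.items():
        try:
            score = models[site_type].score_seq(site_sequence(genome, site))
        except AmbiguousBaseError:
            score = None
        setattr(result, f"{side}_{site_type}", NCSSSlot(site, score, dist))
    return result


__all__ = [
    "NativeSiteScores",
    "SWAResult",
    "NCSSResult",
    "NCSSSlot",
    "Window",
    "score_native_sites",
    "run_swa",
    "run_ncss",
]
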