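"""Spliceogenicity classification.

Routing: a variant overlapping a native splice-site motif is assessed for
native-site loss (SNVs through the native ref/alt scores, indels through
the sliding-window search); a variant outside every native motif is
assessed for gain of a de novo or cryptic site (sliding window plus
nearest-canonical-site competition).

Loss (diff > 0): the alternate score tiers the call — high (alt < 6.2),
moderate (6.2 ≤ alt ≤ 8.5), low (alt > 8.5) — and a small difference
(diff < 1.15) downgrades high→moderate and moderate→low.

Gain (diff < 0): high (alt > 8.5); moderate (6.2 ≤ alt ≤ 8.5) only when the
candidate out-competes the nearest native site of the same type, else low;
low (alt < 6.2). All cut-offs are log2-score units and configurable; the
defaults are the ENIGMA consortium values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .annotation import (
    NativeSpliceSite,
    NormalizedVariant,
    TranscriptModel,
    native_sites,
)
from .assessment import (
    NativeSiteScores,
    NCSSResult,
    SWAResult,
    run_ncss,
    run_swa,
    score_native_sites,
)

PRIORITY_ORDER = {"none": 0, "low": 1, "moderate": 2, "high": 3}

REGION_LABELS = (
    "donor_dinucleotide",
    "donor_other",
    "acceptor_dinucleotide",
    "acceptor_other",
    "exonic",
    "intronic_other",
)


@dataclass(frozen=True)
class Thresholds:
    """Log2-score cut-offs for the loss/gain decision tree (ENIGMA defaults)."""

    high_alt_cut: float = 6.2
    low_alt_cut: float = 8.5
    downgrade_diff_cut: float = 1.15

    def __post_init__(self):
        if not self.high_alt_cut < self.low_alt_cut:
            raise ValueError(
                f"high_alt_cut ({self.high_alt_cut}) must be below "
                f"low_alt_cut ({self.low_alt_cut})"
            )
        if self.downgrade_diff_cut <= 0:
            raise ValueError("downgrade_diff_cut must be positive")


@dataclass
class SpliceogenicityCall:
    mechanism: str  # native_loss | de_novo_gain | none
    priority: str  # high | moderate | low | none
    downgraded: bool = False
    site_type: Optional[str] = None
    region_label: Optional[str] = None
    transcript_id: Optional[str] = None
    evidence: dict = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if (self.priority == "none") != (self.mechanism == "none"):
            raise ValueError("priority is 'none' iff mechanism is 'none'")

    @property
    def is_positive(self) -> bool:
        """Predicted spliceogenic (the high/moderate tier)."""
        return self.priority in ("high", "moderate")


def _none_call(**kw) -> SpliceogenicityCall:
    return SpliceogenicityCall("none", "none", **kw)


# ---------------------------------------------------------------------------
# core decision rules (pure numbers in, tier out)
# ---------------------------------------------------------------------------

def loss_priority(diff: float, alt: float, t: Thresholds) -> tuple[str, bool]:
    """Tier a predicted native-site loss. Returns (priority, downgraded)."""
    if diff <= 0:
        return "none", False
    if alt < t.high_alt_cut:
        base = "high"
    elif alt <= t.low_alt_cut:
        base = "moderate"
    else:
        base = "low"
    if diff < t.downgrade_diff_cut and base in ("high", "moderate"):
        return ("moderate" if base == "high" else "low"), True
    return base, False


def gain_priority(diff: float, alt: float, outcompetes: bool,
                  t: Thresholds) -> str:
    """Tier a predicted de novo / cryptic gain."""
    if diff >= 0:
        return "none"
    if alt > t.low_alt_cut:
        return "high"
    if alt >= t.high_alt_cut:
        return "moderate" if outcompetes else "low"
    return "low"


# ---------------------------------------------------------------------------
# evidence-level classifiers
# ---------------------------------------------------------------------------

def classify_loss(scores, t: Thresholds) -> SpliceogenicityCall:
    """Native-site loss call from NativeSiteScores or an SWAResult.

    SNVs inside a native motif supply NativeSiteScores; indels overlapping a
    native motif are routed through the sliding-window result instead.
    """
    if isinstance(scores, NativeSiteScores):
        diff, alt = scores.diff, scores.alt_score
        site_type = scores.site.site_type
        evidence = {"native": scores}
        flags = set(scores.flags)
    elif isinstance(scores, SWAResult):
        diff, alt = scores.diff, scores.effective_alt
        site_type = scores.site_type
        evidence = {"swa": scores}
        flags = set(scores.flags)
    else:
        raise TypeError(f"cannot classify {type(scores).__name__}")
    if diff is None or alt is None:
        flags.add("assessment_unavailable")
        return _none_call(site_type=site_type, evidence=evidence, flags=flags)
    priority, downgraded = loss_priority(diff, alt, t)
    if priority == "none":
        return _none_call(site_type=site_type, evidence=evidence, flags=flags)
    return SpliceogenicityCall(
        "native_loss", priority, downgraded=downgraded, site_type=site_type,
        evidence=evidence, flags=flags,
    )


def classify_gain(swa: SWAResult, ncss: NCSSResult,
                  t: Thresholds) -> SpliceogenicityCall:
    """De novo / cryptic gain call from SWA plus NCSS competition.

    The competition test applies only to the moderate tier: the candidate's
    best alternate window must strictly out-score the nearest native site of
    the same type. With no native site of that type the test passes
    vacuously (flagged).
    """
    evidence = {"swa": swa, "ncss": ncss}
    flags = set(swa.flags)
    if swa.diff is None or swa.alt_best is None:
        flags.add("assessment_unavailable")
        return _none_call(site_type=swa.site_type, evidence=evidence, flags=flags)
    alt = swa.alt_best.score
    nearest = ncss.nearest_same_type(swa.site_type)
    if nearest is None or nearest.score is None:
        outcompetes = True
        flags.add("no_native_competitor")
    else:
        outcompetes = alt > nearest.score
    priority = gain_priority(swa.diff, alt, outcompetes, t)
    if priority == "none":
        return _none_call(site_type=swa.site_type, evidence=evidence, flags=flags)
    return SpliceogenicityCall(
        "de_novo_gain", priority, site_type=swa.site_type,
        evidence=evidence, flags=flags,
    )


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def region_label(v: NormalizedVariant, tx: TranscriptModel,
                 sites: list[NativeSpliceSite] | None = None) -> str:
    """Stratification label: GT/AG dinucleotide, remainder of a native
    motif, exonic, or other intronic."""
    if sites is None:
        sites = native_sites(tx)
    overlapped = [s for s in sites if v.overlaps_site(s)]
    for s in overlapped:
        if v.overlaps_interval(s.dinucleotide_span()):
            return f"{s.site_type}_dinucleotide"
    if overlapped:
        return f"{overlapped[0].site_type}_other"
    iv = v.affected_interval()
    s0, e0 = iv.start, max(iv.end, iv.start + 1)
    for exon in tx.exons:
        if s0 < exon.end and exon.start < e0:
            return "exonic"
    return "intronic_other"


def _pick(calls: list[SpliceogenicityCall]) -> SpliceogenicityCall:
    """Highest-priority call; ties resolve to the donor channel."""

    def rank(c: SpliceogenicityCall):
        return (PRIORITY_ORDER[c.priority], 1 if c.site_type == "donor" else 0)

    return max(calls, key=rank)


def assess_variant(v: NormalizedVariant, tx: TranscriptModel, genome,
                   models: dict, t: Thresholds | None = None,
                   ) -> SpliceogenicityCall:
    """Full per-(variant, transcript) assessment.

    Computes all three score sets, routes loss vs gain by native-motif
    overlap, evaluates donor and acceptor channels and reports the
    higher-priority call (tie → donor). All raw evidence is retained on the
    returned call.
    """
    t = t or Thresholds()
    sites = native_sites(tx)
    label = region_label(v, tx, sites)
    overlapped = [s for s in sites if v.overlaps_site(s)]
    swa = {st: run_swa(v, tx, genome, models, st) for st in ("donor", "acceptor")}
    ncss = run_ncss(v, tx, genome, models, sites)
    natives = score_native_sites(v, tx, genome, models, sites) if overlapped else []

    evidence = {"native": natives, "swa": swa, "ncss": ncss}
    if overlapped:
        calls = []
        if v.variant_class == "SNV":
            calls = [classify_loss(ns, t) for ns in natives]
            # an SNV whose native alt motif was unavailable falls back to SWA
            calls += [
                classify_loss(swa[ns.site.site_type], t)
                for ns in natives if ns.alt_score is None
            ]
        else:
            for st in sorted({s.site_type for s in overlapped}):
                calls.append(classify_loss(swa[st], t))
        call = _pick(calls) if calls else _none_call()
    else:
        call = _pick([classify_gain(swa[st], ncss, t)
                      for st in ("donor", "acceptor")])
    call.region_label = label
    call.transcript_id = tx.transcript_id
    call.evidence = evidence
    return call


__all__ = [
    "Thresholds",
    "SpliceogenicityCall",
    "classify_loss",
    "classify_gain",
    "loss_priority",
    "gain_priority",
    "assess_variant",
    "region_label",
    "PRIORITY_ORDER",
    "REGION_LABELS",
]
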