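"""Primary- vs secondary-cell-wall classification of CESA-like proteins.

Two independent evidence channels are combined:

1. **ZnF dipeptide** — the two residues between the first C-X2-C pair of the
   matched zinc-finger.  ``QI`` (the CQIC motif) marks primary-wall CESAs;
   the secondary-wall lineages carry characteristic substitutions:
   ``EI`` (CesA4-like, glutamine → glutamate), ``AA`` (CesA7-like, both
   positions → alanine) and ``RA`` (CesA8-like, glutamine → arginine,
   isoleucine → alanine).

2. **TM2 motif** — the SXXCEXWF core inside the second transmembrane
   stretch.  Primary-wall proteins carry the exact SVICEXWFA form; the
   secondary-wall lineages each show one conservative change:
   SVLCEXWFA (CesA4-like, I→L), SVICEXWFG (CesA7-like, A→G) and
   SIVCEXWFA (CesA8-like, V and I swapped).  The X at core position 6 is
   variable and never used as evidence.

Concordant channels give a high-confidence call; a single informative
channel gives a low-confidence call; a conflict yields ``unknown`` with
both evidences reported rather than a priority rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import MissingDomainError
from .motifscan import (
    CXXC_SPEC,
    TM2_CORE_SPEC,
    DomainAnnotation,
    MotifHit,
    ZnfAnnotation,
    compile_pattern,
    detect_znf,
    scan,
)
from .seqio import ProteinRecord

PCW = "PCW"
SCW = "SCW"
UNKNOWN = "unknown"

DIPEPTIDE_TABLE: dict[str, tuple[str, str]] = {
    "QI": (PCW, "PCW-type"),
    "EI": (SCW, "CesA4-like"),
    "AA": (SCW, "CesA7-like"),
    "RA": (SCW, "CesA8-like"),
}

# (position 2, position 3 of the core, residue after the terminal F)
TM2_TABLE: dict[tuple[str, str, str], tuple[str, str, str]] = {
    ("V", "I", "A"): ("SVICEXWFA", PCW, "PCW-type"),
    ("V", "L", "A"): ("SVLCEXWFA", SCW, "CesA4-like"),
    ("V", "I", "G"): ("SVICEXWFG", SCW, "CesA7-like"),
    ("I", "V", "A"): ("SIVCEXWFA", SCW, "CesA8-like"),
}


@dataclass(frozen=True)
class ChannelEvidence:
    call: str  # PCW | SCW | unknown
    informative: bool
    ortholog_hint: str  # CesA4-like | CesA7-like | CesA8-like | PCW-type | none
    detail: str
    hit: Optional[MotifHit] = None


@dataclass(frozen=True)
class WallCall:
    protein_id: str
    call: str  # PCW | SCW | unknown
    confidence: str  # high | low | none
    znf_dipeptide: Optional[str]
    tm2_variant: Optional[str]
    ortholog_hint: str
    znf_evidence: Optional[ChannelEvidence] = None
    tm2_evidence: Optional[ChannelEvidence] = None

    def __post_init__(self):
        if (self.call == UNKNOWN) != (self.confidence == "none"):
            raise ValueError("call=unknown must coincide with confidence=none")


def znf_dipeptide_rule(
    annotation: DomainAnnotation | ZnfAnnotation, protein: ProteinRecord
) -> ChannelEvidence:
    """Classify by the dipeptide inside the first C-X2-C pair of the ZnF.

    Raises :class:`MissingDomainError` when the annotation carries no ZnF;
    callers must pre-check.
    """
    znf = annotation.znf if isinstance(annotation, DomainAnnotation) else annotation
    if znf.variant == "none" or znf.hit is None:
        raise MissingDomainError(
            f"protein {protein.id!r} has no detected ZnF; dipeptide rule inapplicable"
        )
    matched = znf.hit.matched
    cxxc = compile_pattern(CXXC_SPEC, "cxxc")
    inner = scan(ProteinRecord(id=protein.id, sequence=matched), cxxc)
    # the consensus begins C-X2-C, so a hit always exists at offset 0
    first = inner[0]
    dipeptide = first.matched[1:3]
    call, hint = DIPEPTIDE_TABLE.get(dipeptide, (UNKNOWN, "none"))
    return ChannelEvidence(
        call=call,
        informative=call != UNKNOWN,
        ortholog_hint=hint,
        detail=dipeptide,
        hit=MotifHit(
            pattern_name="cxxc",
            start=znf.hit.start + first.start,
            end=znf.hit.start + first.end,
            matched=first.matched,
        ),
    )


def tm2_motif_rule(protein: ProteinRecord) -> ChannelEvidence:
    """Classify by the SXXCEXWF core of the second-TMD motif.

    The first core occurrence is inspected; core absent → uninformative
    ("absent"); core present but variant unlisted → uninformative
    ("unlisted").
    """
    core = compile_pattern(TM2_CORE_SPEC, "tm2_core")
    hits = scan(protein, core)
    if not hits:
        return ChannelEvidence(
            call=UNKNOWN, informative=False, ortholog_hint="none", detail="absent"
        )
    hit = hits[0]
    seq = protein.sequence
    tail = seq[hit.end] if hit.end < len(seq) else ""
    key = (hit.matched[1], hit.matched[2], tail)
    if key in TM2_TABLE:
        variant, call, hint = TM2_TABLE[key]
        return ChannelEvidence(
            call=call, informative=True, ortholog_hint=hint, detail=variant, hit=hit
        )
    return ChannelEvidence(
        call=UNKNOWN, informative=False, ortholog_hint="none", detail="unlisted", hit=hit
    )


def classify(
    protein: ProteinRecord, annotation: DomainAnnotation | ZnfAnnotation | None = None
) -> WallCall:
    """Combine the ZnF-dipeptide and TM2-motif rules into one wall call."""
    znf = (
        annotation.znf
        if isinstance(annotation, DomainAnnotation)
        else annotation
        if annotation is not None
        else detect_znf(protein)
    )
    znf_ev: Optional[ChannelEvidence] = None
    if znf.variant != "none":
        znf_ev = znf_dipeptide_rule(znf, protein)
    tm2_ev = tm2_motif_rule(protein)

    channels = [ev for ev in (znf_ev, tm2_ev) if ev is not None and ev.informative]
    if len(channels) == 2:
        if channels[0].call == channels[1].call:
            call, confidence = channels[0].call, "high"
            hints = {channels[0].ortholog_hint, channels[1].ortholog_hint}
            hint = hints.pop() if len(hints) == 1 else "none"
        else:
            call, confidence, hint = UNKNOWN, "none", "none"
    elif len(channels) == 1:
        call, confidence, hint = channels[0].call, "low", channels[0].ortholog_hint
    else:
        call, confidence, hint = UNKNOWN, "none", "none"

    return WallCall(
        protein_id=protein.id,
        call=call,
        confidence=confidence,
        znf_dipeptide=znf_ev.detail if znf_ev is not None else None,
        tm2_variant=tm2_ev.detail,
        ortholog_hint=hint,
        znf_evidence=znf_ev,
        tm2_evidence=tm2_ev,
    )
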