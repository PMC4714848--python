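"""Degenerate motif compilation and scanning, and CESA domain detection.

Patterns follow the compact convention used throughout the cellulose-synthase
literature: fixed one-letter residues, ``X`` for "any amino acid" with an
optional repeat count (``X14`` = fourteen arbitrary residues), and ignorable
``-``/parenthesis/whitespace separators.  ``X`` matches any of the 20
canonical residues, never a gap.

Besides generic scanning this module locates the three CESA hallmarks:

* the N-terminal RING-like zinc-finger (ZnF), a 46-residue cysteine-anchored
  consensus, with an 8-residue-deleted variant carried by the CesA7 lineage;
* the D, DXD, D, QXXRW catalytic signature of processive beta-glycosyl
  transferases;
* the eight transmembrane stretches (two N-terminal, six C-terminal), via
  Kyte–Doolittle sliding-window hydropathy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import PatternSyntaxError, WindowError
from .seqio import CANONICAL_RESIDUES, ProteinRecord

# ZnF consensus of the predicted wheat CESAs (46 residues) and the
# 8-residue-deleted variant of the CesA7 lineage; plus the older
# literature consensus, kept as a fallback preset.
ZNF_FULL_SPEC = "CX2-CX14-ACX2-CX4-CX2-CX7-GX3-CX2-C"
ZNF_DELETED_SPEC = "CX2-CX6-ACX2-CX4-CX2-CX7-GX3-CX2-C"
ZNF_LITERATURE_SPEC = "(CX2-CX12-FXACX2-CX2PXCX2-CXEX5-GX3-CX2C)"

QXXRW_SPEC = "QXXRW"
CXXC_SPEC = "CXXC"
TM2_CORE_SPEC = "SXXCEXWF"

_IGNORED = set("-() \t")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern: fixed residues plus wildcard runs."""

    name: str
    elements: tuple[tuple[str, int], ...]  # ("C", 1) fixed, ("X", n) wildcard run
    source_spec: str

    @property
    def length(self) -> int:
        return sum(n for _, n in self.elements)

    def to_regex(self) -> str:
        parts = []
        for token, n in self.elements:
            if token == "X":
                parts.append(f"[{CANONICAL_RESIDUES}]{{{n}}}" if n != 1 else f"[{CANONICAL_RESIDUES}]")
            else:
                parts.append(token)
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 0-based half-open
    end: int
    matched: str


@dataclass(frozen=True)
class ZnfAnnotation:
    hit: Optional[MotifHit]
    variant: str  # full_46 | deleted_38 | literature | none
    deletion_size: int


@dataclass(frozen=True)
class CatalyticCore:
    """0-based positions of the D, DXD, D, QXXRW signature."""

    d1: int
    d2: int  # first D of the DXD triplet
    d3: int
    qxxrw_start: int

    def __post_init__(self):
        if not (self.d1 < self.d2 < self.d3 < self.qxxrw_start):
            raise ValueError("catalytic positions must satisfy D1 < D2 < D3 < QXXRW")


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    znf: ZnfAnnotation
    catalytic: Optional[CatalyticCore]
    tmds: tuple[tuple[int, int], ...]
    class_motif_hits: tuple[MotifHit, ...]


def compile_pattern(spec: str, name: str) -> MotifPattern:
    """Compile a degenerate pattern string into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` (with the character offset) on an
    illegal character or a zero repeat count.
    """
    elements: list[tuple[str, int]] = []
    i = 0
    while i < len(spec):
        char = spec[i]
        if char in _IGNORED:
            i += 1
            continue
        if char == "X":
            j = i + 1
            while j < len(spec) and spec[j].isdigit():
                j += 1
            count = int(spec[i + 1:j]) if j > i + 1 else 1
            if count == 0:
                raise PatternSyntaxError("wildcard repeat count 0", offset=i)
            elements.append(("X", count))
            i = j
        elif char.upper() in CANONICAL_RESIDUES and char != "X":
            elements.append((char.upper(), 1))
            i += 1
        else:
            raise PatternSyntaxError(f"illegal character {char!r}", offset=i)
    if not elements:
        raise PatternSyntaxError("empty pattern")
    return MotifPattern(name=name, elements=tuple(elements), source_spec=spec)


def scan(protein: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """Return all (possibly overlapping) occurrences, left to right."""
    regex = re.compile(f"(?=({pattern.to_regex()}))")
    hits = []
    for match in regex.finditer(protein.sequence):
        start = match.start()
        end = start + pattern.length
        hits.append(
            MotifHit(
                pattern_name=pattern.name,
                start=start,
                end=end,
                matched=match.group(1),
            )
        )
    return hits


def znf_presets() -> list[tuple[str, MotifPattern]]:
    """The ZnF presets tried in order: full 46-mer, deleted 38-mer, literature."""
    return [
        ("full_46", compile_pattern(ZNF_FULL_SPEC, "znf_full_46")),
        ("deleted_38", compile_pattern(ZNF_DELETED_SPEC, "znf_deleted_38")),
        ("literature", compile_pattern(ZNF_LITERATURE_SPEC, "znf_literature")),
    ]


def detect_znf(protein: ProteinRecord) -> ZnfAnnotation:
    """Locate the zinc-finger domain, preferring the full 46-residue consensus.

    The deleted variant and then the literature consensus are tried only when
    the preceding preset is absent; the most N-terminal hit is reported.
    ``deletion_size`` is 46 minus the matched length.
    """
    for variant, pattern in znf_presets():
        hits = scan(protein, pattern)
        if hits:
            hit = hits[0]
            return ZnfAnnotation(
                hit=hit,
                variant=variant,
                deletion_size=46 - pattern.length,
            )
    return ZnfAnnotation(hit=None, variant="none", deletion_size=0)


def detect_catalytic(protein: ProteinRecord) -> Optional[CatalyticCore]:
    """Locate the D, DXD, D, QXXRW signature.

    The search is anchored on QXXRW (hits tried left to right) and proceeds
    upstream by nearest-neighbor selection: the DXD triplet closest to QXXRW
    that still leaves a lone D between itself and QXXRW (D3, nearest to
    QXXRW) and a lone D upstream of itself (D1, nearest to DXD).  Returns
    ``None`` when no QXXRW admits the full ordered signature.
    """
    seq = protein.sequence
    qxxrw = compile_pattern(QXXRW_SPEC, "qxxrw")
    d_positions = [i for i, ch in enumerate(seq) if ch == "D"]
    if not d_positions:
        return None
    for q_hit in scan(protein, qxxrw):
        q_start = q_hit.start
        # DXD triplets fully upstream of QXXRW, nearest first
        dxd_starts = [
            i
            for i in range(q_start - 3, -1, -1)
            if seq[i] == "D" and i + 2 < q_start and seq[i + 2] == "D"
        ]
        for d2 in dxd_starts:
            d3_candidates = [p for p in d_positions if d2 + 3 <= p < q_start]
            d1_candidates = [p for p in d_positions if p < d2]
            if d3_candidates and d1_candidates:
                return CatalyticCore(
                    d1=max(d1_candidates),
                    d2=d2,
                    d3=max(d3_candidates),
                    qxxrw_start=q_start,
                )
    return None


def tmd_scan(
    protein: ProteinRecord, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Predict transmembrane stretches by Kyte–Doolittle hydropathy.

    Window means ≥ *threshold* seed candidate regions (each covering the
    full windows of its qualifying positions, hence at least *window* long);
    regions closer than ``window / 2`` are merged.  Returned intervals are
    0-based half-open, disjoint and sorted.
    """
    if window % 2 == 0 or window < 5:
        raise WindowError(f"window must be odd and >= 5, got {window}")
    seq = protein.sequence
    if window > len(seq):
        raise WindowError(
            f"window {window} exceeds sequence length {len(seq)}"
        )
    values = np.array([KYTE_DOOLITTLE[ch] for ch in seq])
    means = np.convolve(values, np.full(window, 1.0 / window), mode="valid")
    qualifying = np.flatnonzero(means >= threshold)  # window start positions
    if qualifying.size == 0:
        return []
    regions: list[list[int]] = []
    run_start = prev = qualifying[0]
    for pos in qualifying[1:]:
        if pos == prev + 1:
            prev = pos
            continue
        regions.append([int(run_start), int(prev) + window])
        run_start = prev = pos
    regions.append([int(run_start), int(prev) + window])
    merged = [regions[0]]
    for start, end in regions[1:]:
        if start - merged[-1][1] < window / 2:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, min(e, len(seq))) for s, e in merged]


def annotate(
    protein: ProteinRecord,
    class_patterns: list[MotifPattern] | None = None,
    window: int = 19,
    threshold: float = 1.6,
) -> DomainAnnotation:
    """Full per-protein domain annotation (ZnF, catalytic core, TMDs, extras)."""
    class_hits: list[MotifHit] = []
    for pattern in class_patterns or []:
        class_hits.extend(scan(protein, pattern))
    return DomainAnnotation(
        protein_id=protein.id,
        znf=detect_znf(protein),
        catalytic=detect_catalytic(protein),
        tmds=tuple(tmd_scan(protein, window=window, threshold=threshold)),
        class_motif_hits=tuple(class_hits),
    )
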