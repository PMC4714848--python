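"""Intron-phase computation and gene-structure statistics.

An intron's phase is its position relative to codon structure: phase 0 lies
between two consecutive codons, phase 1 between the first and second base of
a codon, phase 2 between the second and third.  For intron *i* (between
coding exons *i* and *i+1*, counting in translation order) this is simply
the cumulative coding length upstream of the intron modulo 3.

The four canonical wheat CesA phase vectors (the shared pattern of the
primary-wall genes TaCesA1/2/6 and the three secondary-wall genes TaCesA4,
7 and 8) ship as :data:`CANONICAL_PHASE_VECTORS` and serve as reference
inputs for summaries and synthetic gene construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import GeneModelError
from .seqio import GeneModel

# Per-gene intron phases of the wheat CesA genes, transcribed from the
# published per-intron assignments: PCW TaCesA1/2/6 share one 13-intron
# pattern; the SCW genes TaCesA4, 7 and 8 have 7, 12 and 9 introns.
CANONICAL_PHASE_VECTORS: dict[str, tuple[int, ...]] = {
    "TaCesA_PCW_common": (0, 1, 0, 1, 2, 2, 0, 0, 0, 0, 1, 0, 0),
    "TaCesA4": (1, 0, 1, 2, 0, 0, 0),
    "TaCesA7": (1, 0, 1, 2, 2, 0, 0, 0, 0, 1, 0, 0),
    "TaCesA8": (0, 1, 2, 0, 0, 0, 1, 0, 0),
}


@dataclass(frozen=True)
class IntronPhaseVector:
    gene_id: str
    phases: tuple[int, ...]

    def __post_init__(self):
        if any(p not in (0, 1, 2) for p in self.phases):
            raise ValueError(f"gene {self.gene_id!r}: phases must be in {{0,1,2}}")

    def __len__(self) -> int:
        return len(self.phases)


@dataclass(frozen=True)
class GeneStructureStats:
    gene_id: str
    gene_length: int
    exon_total: int
    intron_total: int
    intron_count: int
    orf_length: int
    phase_counts: tuple[int, int, int]
    phase_proportions: tuple[float, float, float]


def intron_phases(model: GeneModel) -> IntronPhaseVector:
    """Phase of each intron: cumulative upstream coding length mod 3.

    A single-exon gene yields an empty vector.
    """
    phases = []
    cumulative = 0
    for length in model.exon_lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return IntronPhaseVector(gene_id=model.gene_id, phases=tuple(phases))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _proportions(phases: tuple[int, ...]) -> tuple[float, float, float]:
    n = len(phases)
    return tuple(100.0 * phases.count(k) / n for k in (0, 1, 2))


@dataclass(frozen=True)
class PhaseSummary:
    per_gene: pd.DataFrame  # gene_id, n_introns, n0..n2, pct0..pct2, pct*_rounded
    phase_min: tuple[float, float, float]  # min across genes per phase
    phase_max: tuple[float, float, float]


def phase_summary(vectors: list[IntronPhaseVector]) -> PhaseSummary:
    """Per-gene and across-gene phase proportions.

    Percentages are kept at full precision with a round-half-up integer
    rendering alongside (so 6/9 = 66.67 renders as 67, 2/9 = 22.22 as 22).
    Genes with zero introns are excluded with a warning.
    """
    usable = []
    for vec in vectors:
        if len(vec) == 0:
            warnings.warn(
                f"gene {vec.gene_id!r} has no introns; excluded from phase summary",
                stacklevel=2,
            )
            continue
        usable.append(vec)
    if not usable:
        raise GeneModelError("no genes with introns to summarize")
    rows = []
    for vec in usable:
        pct = _proportions(vec.phases)
        rows.append(
            {
                "gene_id": vec.gene_id,
                "n_introns": len(vec),
                "n0": vec.phases.count(0),
                "n1": vec.phases.count(1),
                "n2": vec.phases.count(2),
                "pct0": pct[0],
                "pct1": pct[1],
                "pct2": pct[2],
                "pct0_rounded": _round_half_up(pct[0]),
                "pct1_rounded": _round_half_up(pct[1]),
                "pct2_rounded": _round_half_up(pct[2]),
            }
        )
    frame = pd.DataFrame(rows)
    mins = tuple(float(frame[f"pct{k}"].min()) for k in (0, 1, 2))
    maxs = tuple(float(frame[f"pct{k}"].max()) for k in (0, 1, 2))
    return PhaseSummary(per_gene=frame, phase_min=mins, phase_max=maxs)


def structure_stats(model: GeneModel, gene_span: tuple[int, int]) -> GeneStructureStats:
    """Length, exon/intron totals and ORF size over a genomic span.

    ``intron_total`` is the span length minus the exonic total; the ORF
    length in residues assumes the terminal stop codon is included in the
    CDS (standard GFF3 convention) and removes it.
    """
    span_start, span_end = gene_span
    exon_start, exon_end = model.span
    if span_start > exon_start or span_end < exon_end:
        raise GeneModelError(
            f"gene {model.gene_id!r}: span [{span_start},{span_end}) does not "
            f"cover exons [{exon_start},{exon_end})"
        )
    gene_length = span_end - span_start
    exon_total = model.coding_length
    vec = intron_phases(model)
    counts = (vec.phases.count(0), vec.phases.count(1), vec.phases.count(2))
    n_introns = len(vec)
    proportions = _proportions(vec.phases) if n_introns else (0.0, 0.0, 0.0)
    return GeneStructureStats(
        gene_id=model.gene_id,
        gene_length=gene_length,
        exon_total=exon_total,
        intron_total=gene_length - exon_total,
        intron_count=n_introns,
        orf_length=exon_total // 3 - 1,
        phase_counts=counts,
        phase_proportions=proportions,
    )


def write_phase_report(vectors: list[IntronPhaseVector], path) -> None:
    """TSV report: gene_id, intron_index (1-based), phase."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tintron_index\tphase\n")
        for vec in vectors:
            for i, phase in enumerate(vec.phases, start=1):
                handle.write(f"{vec.gene_id}\t{i}\t{phase}\n")


def write_phase_summary(summary: PhaseSummary, path) -> None:
    summary.per_gene.to_csv(path, sep="\t", index=False)
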