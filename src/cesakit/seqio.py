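"""Readers, writers and shared record types.

Internal coordinates are 0-based half-open throughout the package; all GFF3
I/O converts to/from the standard 1-based inclusive convention at the
boundary.  Protein sequences are restricted to the 20 canonical one-letter
codes; lowercase input is normalized to uppercase and a terminal stop symbol
``*`` (a common exporter artifact) is stripped before validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CountsFormatError,
    FastaFormatError,
    GeneModelError,
    SequenceAlphabetError,
)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical residue letters."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        for i, letter in enumerate(self.sequence):
            if letter not in _CANONICAL_SET:
                raise SequenceAlphabetError(self.id, i + 1, letter)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Ordered coding-exon intervals of one gene.

    ``coding_exons`` are 0-based half-open genomic intervals listed in
    translation order: ascending genomic position on the + strand,
    descending on the − strand.
    """

    gene_id: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]
    seqid: str = "."

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        exons = tuple((int(a), int(b)) for a, b in self.coding_exons)
        object.__setattr__(self, "coding_exons", exons)
        if not exons:
            raise GeneModelError(f"gene {self.gene_id!r}: no coding exons")
        for start, end in exons:
            if end - start < 1:
                raise GeneModelError(
                    f"gene {self.gene_id!r}: exon [{start},{end}) shorter than 1 nt"
                )
        ordered = sorted(exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise GeneModelError(
                    f"gene {self.gene_id!r}: overlapping coding exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        expected = ordered if self.strand == "+" else ordered[::-1]
        if exons != tuple(expected):
            raise GeneModelError(
                f"gene {self.gene_id!r}: exons not in translation order for "
                f"strand {self.strand}"
            )
        if self.coding_length < 3:
            raise GeneModelError(
                f"gene {self.gene_id!r}: total coding length < 3 nt"
            )

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.coding_exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.coding_exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent covered by the coding exons (0-based half-open)."""
        starts, ends = zip(*self.coding_exons)
        return min(starts), max(ends)


@dataclass(frozen=True)
class CountsMatrix:
    """Integer read counts, genes × samples."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountsFormatError("counts shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountsFormatError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountsFormatError("duplicate sample ids")
        if counts.size == 0:
            raise CountsFormatError("empty counts matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            raise CountsFormatError("counts must be integers")
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise CountsFormatError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if (counts.sum(axis=0) == 0).any():
            bad = int(np.argmin(counts.sum(axis=0)))
            raise CountsFormatError(
                f"sample {self.sample_ids[bad]!r} has zero library size"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountsMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def _normalize_protein(record_id: str, raw: str) -> str:
    seq = "".join(raw.split()).upper().strip("*")
    if "*" in seq:
        pos = seq.index("*") + 1
        raise SequenceAlphabetError(record_id, pos, "*")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are uppercased; terminal ``*`` is stripped.  Raises
    :class:`FastaFormatError` on an empty file and
    :class:`SequenceAlphabetError` naming the record and 1-based position of
    the first illegal residue.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=_normalize_protein(rec.id, str(rec.seq)),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file, using only CDS features.

    CDS lines are grouped by their ``Parent`` attribute (falling back to
    ``ID``), sorted into translation order and converted to the 0-based
    half-open internal convention.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, list] = {}
    seqids: dict[str, str] = {}
    strands: dict[str, set[str]] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise GeneModelError(f"CDS at {feat.seqid}:{feat.start} has no Parent/ID")
        gene_id = parents[0]
        if gene_id not in grouped:
            grouped[gene_id] = []
            strands[gene_id] = set()
            seqids[gene_id] = feat.seqid
            order.append(gene_id)
        grouped[gene_id].append((feat.start - 1, feat.end))  # to 0-based half-open
        strands[gene_id].add(feat.strand)
    if not grouped:
        raise GeneModelError(f"no CDS features in {path}")
    models = []
    for gene_id in order:
        strand_set = strands[gene_id]
        if len(strand_set) != 1 or not strand_set <= {"+", "-"}:
            raise GeneModelError(f"gene {gene_id!r}: mixed or missing strand on CDS lines")
        strand = strand_set.pop()
        exons = sorted(grouped[gene_id])
        if strand == "-":
            exons = exons[::-1]
        models.append(
            GeneModel(
                gene_id=gene_id,
                strand=strand,
                coding_exons=tuple(exons),
                seqid=seqids[gene_id],
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##gff-version 3\n")
        for model in models:
            for start, end in sorted(model.coding_exons):
                handle.write(
                    "\t".join(
                        [
                            model.seqid,
                            "cesakit",
                            "CDS",
                            str(start + 1),
                            str(end),
                            ".",
                            model.strand,
                            ".",
                            f"Parent={model.gene_id}",
                        ]
                    )
                    + "\n"
                )


def read_counts(path: str | Path) -> CountsMatrix:
    """Read a gene × sample counts TSV (first column gene id, header row)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise CountsFormatError(f"empty counts file {path}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise CountsFormatError(f"no data rows in {path}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise CountsFormatError(f"duplicate gene id {dup!r}")
    for j, col in enumerate(frame.columns):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            i = int(values.isna().to_numpy().argmax())
            raise CountsFormatError(
                f"non-numeric cell at gene {frame.index[i]!r}, sample {col!r}"
            )
        if not (values == values.astype(np.int64)).all():
            i = int((values != values.astype(np.int64)).to_numpy().argmax())
            raise CountsFormatError(
                f"non-integer cell at gene {frame.index[i]!r}, sample {col!r}"
            )
    counts = frame.to_numpy(dtype=np.int64)
    return CountsMatrix(
        gene_ids=tuple(str(g) for g in frame.index),
        sample_ids=tuple(str(s) for s in frame.columns),
        counts=counts,
    )


def write_counts(matrix: CountsMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
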