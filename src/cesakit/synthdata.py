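"""Synthetic CESA-style data with recorded ground truth.

Every generator emits both the object and a ground-truth record sufficient
to serve as the oracle for the downstream module that consumes it:

* :func:`make_cesa_protein` — a CESA-like protein with the canonical domain
  layout (N-terminal zinc-finger, two N-terminal and six C-terminal
  transmembrane stretches, the D/DXD/D/QXXRW catalytic core between TMD2
  and TMD3) and the wall-class diagnostic motifs of the requested lineage;
* :func:`evolve_family` — a substitution-only (hence gap-free,
  self-aligned) protein family evolved along a tree under the uniform
  replacement process the Poisson correction assumes;
* :func:`make_gene_model` — a gene model realizing a requested
  intron-phase vector exactly;
* :func:`make_counts` — negative-binomial two-group counts mimicking a
  stem-high secondary-wall group against a broadly expressed primary-wall
  group.

Sequence composition is chosen so that detection never depends on luck:
transmembrane fills come from strongly hydrophobic residues, linker fills
from a hydrophilic loop alphabet free of C/W/F (so no spurious zinc-finger,
TM2-core or QXXRW anchors can arise), catalytic spacers additionally
exclude D, and zinc-finger wildcard fills exclude W.  These constraints
keep every recorded ground-truth coordinate the unique answer its detector
can find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .errors import GeneratorError
from .motifscan import ZNF_DELETED_SPEC, ZNF_FULL_SPEC, compile_pattern
from .seqio import CANONICAL_RESIDUES, CountsMatrix, GeneModel, ProteinRecord

TMD_ALPHABET = "AILFVM"  # Kyte-Doolittle >= 1.8 each
LOOP_ALPHABET = "DEGHKNPQRST"  # hydrophilic; no C/W/F
CATALYTIC_SPACER_ALPHABET = "EGHKNPQRST"  # loop minus D
# The ZnF lies on the cytoplasmic face: wildcard fills use a hydrophilic
# composition (no W, no strong hydrophobics) so that no window across the
# domain can reach the transmembrane hydropathy threshold for any draw.
ZNF_FILL_ALPHABET = "DEGHKNPQRSTY"
TM2_X_ALPHABET = "LIVFM"

DIPEPTIDES = {
    "PCW-type": "QI",
    "CesA4-like": "EI",
    "CesA7-like": "AA",
    "CesA8-like": "RA",
}
TM2_MOTIFS = {
    "PCW-type": "SVICE?WFA",
    "CesA4-like": "SVLCE?WFA",
    "CesA7-like": "SVICE?WFG",
    "CesA8-like": "SIVCE?WFA",
}
SCW_TYPES = ("CesA4-like", "CesA7-like", "CesA8-like")

TMD_LENGTH = 21


@dataclass(frozen=True)
class ProteinSpecTemplate:
    """Recipe for one synthetic CESA-like protein."""

    wall_class: str  # PCW | SCW
    ortholog_type: str  # PCW-type | CesA4-like | CesA7-like | CesA8-like
    seed: int
    target_length: Optional[int] = None  # drawn from 991-1091 when None
    znf_variant: Optional[str] = None  # full_46 | deleted_38; auto when None
    protein_id: Optional[str] = None

    def __post_init__(self):
        if self.wall_class == "PCW" and self.ortholog_type != "PCW-type":
            raise GeneratorError("PCW proteins must be PCW-type")
        if self.wall_class == "SCW" and self.ortholog_type not in SCW_TYPES:
            raise GeneratorError(f"SCW ortholog_type must be one of {SCW_TYPES}")
        variant = self.znf_variant
        if variant is None:
            variant = "deleted_38" if self.ortholog_type == "CesA7-like" else "full_46"
        if self.ortholog_type == "CesA7-like" and variant != "deleted_38":
            raise GeneratorError("CesA7-like proteins carry the deleted_38 ZnF")
        object.__setattr__(self, "znf_variant", variant)


@dataclass(frozen=True)
class ProteinGroundTruth:
    wall_class: str
    ortholog_type: str
    znf_variant: str
    znf_interval: tuple[int, int]
    dipeptide: str
    tm2_interval: tuple[int, int]  # the 9-residue motif
    tm2_variant: str
    tmd_intervals: tuple[tuple[int, int], ...]
    catalytic: tuple[int, int, int, int]  # D1, D2, D3, QXXRW start
    protected_positions: frozenset[int]


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _instantiate_znf(rng: np.random.Generator, variant: str, dipeptide: str) -> str:
    spec = ZNF_FULL_SPEC if variant == "full_46" else ZNF_DELETED_SPEC
    pattern = compile_pattern(spec, f"znf_{variant}")
    parts = []
    first_wildcard = True
    for token, n in pattern.elements:
        if token == "X":
            if first_wildcard:
                assert n == 2, "consensus starts C-X2-C"
                parts.append(dipeptide)
                first_wildcard = False
            else:
                parts.append(_draw(rng, ZNF_FILL_ALPHABET, n))
        else:
            parts.append(token)
    return "".join(parts)


def make_cesa_protein(
    template: ProteinSpecTemplate,
) -> tuple[ProteinRecord, ProteinGroundTruth]:
    """Build one CESA-like protein realizing the template, with ground truth."""
    rng = np.random.default_rng(template.seed)
    target = template.target_length
    if target is None:
        target = int(rng.integers(991, 1092))

    dipeptide = DIPEPTIDES[template.ortholog_type]
    tm2_template = TM2_MOTIFS[template.ortholog_type]

    parts: list[str] = []
    pos = 0

    def emit(segment: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(segment)
        start = pos
        pos += len(segment)
        return (start, pos)

    emit(_draw(rng, LOOP_ALPHABET, int(rng.integers(40, 61))))
    znf_interval = emit(_instantiate_znf(rng, template.znf_variant, dipeptide))
    emit(_draw(rng, LOOP_ALPHABET, int(rng.integers(60, 101))))

    tmd_intervals: list[tuple[int, int]] = []
    tmd_intervals.append(emit(_draw(rng, TMD_ALPHABET, TMD_LENGTH)))
    emit(_draw(rng, LOOP_ALPHABET, int(rng.integers(30, 51))))

    # TMD2 carries the 9-residue wall-class motif at a random internal offset
    motif = tm2_template.replace("?", rng.choice(list(TM2_X_ALPHABET)))
    offset = int(rng.integers(0, TMD_LENGTH - len(motif) + 1))
    tmd2 = (
        _draw(rng, TMD_ALPHABET, offset)
        + motif
        + _draw(rng, TMD_ALPHABET, TMD_LENGTH - len(motif) - offset)
    )
    tmd2_interval = emit(tmd2)
    tmd_intervals.append(tmd2_interval)
    tm2_interval = (tmd2_interval[0] + offset, tmd2_interval[0] + offset + len(motif))

    emit(_draw(rng, LOOP_ALPHABET, int(rng.integers(40, 61))))

    cat = CATALYTIC_SPACER_ALPHABET
    d1 = emit("D")[0]
    emit(_draw(rng, cat, int(rng.integers(20, 41))))
    d2 = emit("D" + _draw(rng, cat, 1) + "D")[0]
    emit(_draw(rng, cat, int(rng.integers(20, 41))))
    d3 = emit("D")[0]
    emit(_draw(rng, cat, int(rng.integers(20, 41))))
    qxxrw_start = emit("Q" + _draw(rng, cat, 2) + "RW")[0]

    for _ in range(6):
        emit(_draw(rng, LOOP_ALPHABET, int(rng.integers(30, 46))))
        tmd_intervals.append(emit(_draw(rng, TMD_ALPHABET, TMD_LENGTH)))

    if pos > target:
        raise GeneratorError(
            f"target_length {target} too small: layout needs {pos} residues"
        )
    emit(_draw(rng, LOOP_ALPHABET, target - pos))

    sequence = "".join(parts)
    protein_id = template.protein_id or f"{template.ortholog_type}_{template.seed}"
    record = ProteinRecord(id=protein_id, sequence=sequence)

    protected = set(range(*znf_interval))
    protected.update(range(*tm2_interval))
    protected.update({d1, d2, d2 + 1, d2 + 2, d3})
    protected.update(range(qxxrw_start, qxxrw_start + 5))
    truth = ProteinGroundTruth(
        wall_class=template.wall_class,
        ortholog_type=template.ortholog_type,
        znf_variant=template.znf_variant,
        znf_interval=znf_interval,
        dipeptide=dipeptide,
        tm2_interval=tm2_interval,
        tm2_variant=tm2_template.replace("?", "X"),
        tmd_intervals=tuple(tmd_intervals),
        catalytic=(d1, d2, d3, qxxrw_start),
        protected_positions=frozenset(protected),
    )
    return record, truth


def mutate_sequence(
    sequence: str,
    branch_length: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Apply the uniform replacement process for one branch.

    Each unprotected site receives a Poisson(branch_length) number of
    substitution events; each event replaces the current residue with a
    uniformly random *different* residue.
    """
    if branch_length < 0:
        raise GeneratorError("branch length must be non-negative")
    letters = list(sequence)
    events = rng.poisson(branch_length, size=len(letters))
    for site in np.flatnonzero(events):
        if site in protected:
            continue
        for _ in range(events[site]):
            current = letters[site]
            others = [c for c in CANONICAL_RESIDUES if c != current]
            letters[site] = others[int(rng.integers(0, 19))]
    return "".join(letters)


def evolve_family(
    root: ProteinRecord,
    tree: dendropy.Tree,
    protect_motifs: bool = True,
    ground_truth: Optional[ProteinGroundTruth] = None,
    seed: Optional[int] = None,
) -> list[ProteinRecord]:
    """Evolve *root* along *tree* (edge lengths in substitutions/site).

    Substitution-only, so all leaves share the root's length and the family
    is its own alignment.  When *protect_motifs* is set and a ground truth
    is supplied, its recorded motif positions are immutable.  Leaves are
    returned in the tree's leaf order, named by their taxon labels.
    """
    rng = np.random.default_rng(seed)
    protected = (
        ground_truth.protected_positions
        if (protect_motifs and ground_truth is not None)
        else frozenset()
    )
    sequences: dict[int, str] = {id(tree.seed_node): root.sequence}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = sequences[id(node.parent_node)]
        length = node.edge.length or 0.0
        sequences[id(node)] = mutate_sequence(parent_seq, length, rng, protected)
    leaves = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else f"leaf_{len(leaves)}"
        leaves.append(ProteinRecord(id=label, sequence=sequences[id(leaf)]))
    return leaves


@dataclass(frozen=True)
class ShowcaseFamily:
    """A fixed demonstration family: 3 ortholog groups × 3 'species'."""

    records: tuple[ProteinRecord, ...]
    group_of: dict[str, str]  # leaf id -> ortholog group
    roots: dict[str, ProteinRecord]
    ground_truth: ProteinGroundTruth  # of the common ancestor (coordinates shared)


SHOWCASE_GROUPS = ("PCW-type", "CesA4-like", "CesA8-like")
SHOWCASE_SPECIES = ("spA", "spB", "spD")
SHOWCASE_DEEP_BRANCH = 0.30
SHOWCASE_SHALLOW_BRANCH = 0.05


def showcase_family(seed: int = 42) -> ShowcaseFamily:
    """The documented ortholog/paralog demonstration fixture.

    A single primary-wall ancestor (fixed length, so the family stays
    self-aligned) diverges into three ortholog groups on deep branches;
    each group ancestor's diagnostic motifs are then rewritten to its
    lineage variant and three 'species' leaves evolve on shallow branches.
    The CesA7-like group is excluded because its zinc-finger deletion would
    break the equal-length (gap-free) family invariant.
    """
    rng = np.random.default_rng(seed)
    ancestor_template = ProteinSpecTemplate(
        wall_class="PCW",
        ortholog_type="PCW-type",
        seed=int(rng.integers(0, 2**31 - 1)),
        target_length=1040,
        protein_id="ancestor",
    )
    ancestor, truth = make_cesa_protein(ancestor_template)

    records: list[ProteinRecord] = []
    group_of: dict[str, str] = {}
    roots: dict[str, ProteinRecord] = {}
    for group in SHOWCASE_GROUPS:
        diverged = mutate_sequence(
            ancestor.sequence,
            SHOWCASE_DEEP_BRANCH,
            rng,
            truth.protected_positions,
        )
        letters = list(diverged)
        znf_start = truth.znf_interval[0]
        letters[znf_start + 1:znf_start + 3] = list(DIPEPTIDES[group])
        tm2_start = truth.tm2_interval[0]
        motif = TM2_MOTIFS[group]
        for k, ch in enumerate(motif):
            if ch != "?":  # the variable X position keeps the ancestral residue
                letters[tm2_start + k] = ch
        group_root = ProteinRecord(id=f"{group}_root", sequence="".join(letters))
        roots[group] = group_root
        for species in SHOWCASE_SPECIES:
            leaf_seq = mutate_sequence(
                group_root.sequence,
                SHOWCASE_SHALLOW_BRANCH,
                rng,
                truth.protected_positions,
            )
            leaf_id = f"{group.replace('-like', '')}_{species}"
            records.append(ProteinRecord(id=leaf_id, sequence=leaf_seq))
            group_of[leaf_id] = group
    return ShowcaseFamily(
        records=tuple(records),
        group_of=group_of,
        roots=roots,
        ground_truth=truth,
    )


def make_gene_model(
    phase_vector: Sequence[int],
    intron_lengths: Optional[Sequence[int]] = None,
    seed: Optional[int] = None,
    gene_id: str = "synth_gene",
    strand: str = "+",
    seqid: str = "synth1",
) -> GeneModel:
    """Construct a gene model whose intron phases equal *phase_vector*.

    Exon lengths (≥ 30 nt) are drawn so the cumulative coding length modulo
    3 realizes each requested phase; the total coding length is a multiple
    of 3.  An empty vector yields a single-exon gene.
    """
    phases = [int(p) for p in phase_vector]
    if any(p not in (0, 1, 2) for p in phases):
        raise GeneratorError("phases must be in {0,1,2}")
    rng = np.random.default_rng(seed)
    n_exons = len(phases) + 1
    targets_mod = []
    previous = 0
    for phase in phases:
        targets_mod.append((phase - previous) % 3)
        previous = phase
    targets_mod.append((0 - previous) % 3)  # total coding length ≡ 0 mod 3
    exon_lengths = []
    for mod in targets_mod:
        base = int(rng.integers(30, 121))
        exon_lengths.append(base + ((mod - base) % 3))
    if intron_lengths is None:
        intron_lengths = [int(rng.integers(60, 301)) for _ in range(n_exons - 1)]
    elif len(intron_lengths) != n_exons - 1:
        raise GeneratorError(
            f"need {n_exons - 1} intron lengths, got {len(intron_lengths)}"
        )
    start = int(rng.integers(0, 101))
    exons = []
    cursor = start
    for i, length in enumerate(exon_lengths):
        exons.append((cursor, cursor + length))
        cursor += length
        if i < len(intron_lengths):
            cursor += int(intron_lengths[i])
    if strand == "-":
        # mirror so the translation order runs right-to-left on the genome
        total = cursor
        exons = [(total - e, total - s) for s, e in exons]
    return GeneModel(
        gene_id=gene_id, strand=strand, coding_exons=tuple(exons), seqid=seqid
    )


# Organ/stage design emulating a multi-organ developmental series:
# five organs, three stages each, in duplicate.
DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("root", "seedling"),
    ("root", "three_leaves"),
    ("root", "meiosis"),
    ("leaf", "seedling"),
    ("leaf", "three_tillers"),
    ("leaf", "anthesis_2d"),
    ("stem", "spike_1cm"),
    ("stem", "two_nodes"),
    ("stem", "anthesis"),
    ("spike", "two_nodes"),
    ("spike", "meiosis"),
    ("spike", "anthesis"),
    ("grain", "anthesis_2d"),
    ("grain", "anthesis_14d"),
    ("grain", "anthesis_30d"),
)

MATURE_STEM = ("stem", "anthesis")


def make_counts(
    n_scw_genes: int = 7,
    n_pcw_genes: int = 14,
    samples: Sequence[tuple[str, str]] = DEFAULT_SAMPLES,
    replicates: int = 2,
    seed: Optional[int] = None,
    base_mean: float = 100.0,
    scw_fold: float = 10.0,
    pcw_fold: float = 5.0,
    dispersion: float = 0.1,
) -> tuple[CountsMatrix, dict[str, str]]:
    """Two-group negative-binomial counts with recorded gene labels.

    Secondary-wall genes are *scw_fold*-elevated in mature-stem samples
    only; primary-wall genes are *pcw_fold*-elevated everywhere else.
    Dispersion follows var = m + dispersion · m²; dispersion 0 degenerates
    to Poisson.
    """
    if not any(tuple(s) == MATURE_STEM for s in samples):
        raise GeneratorError("sample design needs a mature-stem (stem, anthesis) sample")
    if not any(tuple(s) != MATURE_STEM for s in samples):
        raise GeneratorError("sample design needs at least one non-stem sample")
    rng = np.random.default_rng(seed)
    gene_ids = [f"SCW_g{i + 1}" for i in range(n_scw_genes)] + [
        f"PCW_g{i + 1}" for i in range(n_pcw_genes)
    ]
    labels = {g: ("SCW" if g.startswith("SCW") else "PCW") for g in gene_ids}
    sample_ids = []
    mature_mask = []
    for organ, stage in samples:
        for rep in range(1, replicates + 1):
            sample_ids.append(f"{organ}_{stage}_rep{rep}")
            mature_mask.append((organ, stage) == MATURE_STEM)
    mature = np.array(mature_mask)
    means = np.zeros((len(gene_ids), len(sample_ids)))
    for g, gene in enumerate(gene_ids):
        if labels[gene] == "SCW":
            means[g] = np.where(mature, base_mean * scw_fold, base_mean)
        else:
            means[g] = np.where(mature, base_mean, base_mean * pcw_fold)
    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + means)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(means)
    matrix = CountsMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        counts=counts.astype(np.int64),
    )
    return matrix, labels


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar for any generated object's ground truth."""

    def default(obj):
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    if hasattr(truth, "__dataclass_fields__"):
        truth = asdict(truth)
    Path(path).write_text(
        json.dumps(truth, indent=2, default=default, sort_keys=True),
        encoding="utf-8",
    )
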