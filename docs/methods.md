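# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the numerical details a user would need to reproduce or
extend the results.

## Coordinates and alphabets

All internal coordinates are 0-based half-open; GFF3 I/O converts to and
from 1-based inclusive at the boundary, and TSV reports print 1-based
inclusive coordinates. Protein sequences are restricted to the 20
canonical one-letter codes. Lowercase input is uppercased; a terminal `*`
(a common exporter artifact) is stripped; any other non-canonical letter
is rejected with the record id and position. Ambiguity codes are treated
as missing data, not as wildcards.

## Degenerate motif grammar and scanning

Patterns are sequences of fixed residue letters and `X` tokens with an
optional integer run length (`X14`); `-`, parentheses and whitespace are
ignored so printed consensus strings can be pasted verbatim. `X` matches
any canonical residue and never a gap. Scanning reports **all** left-to-
right occurrences, including overlapping ones; consumers that need one
occurrence take the first (most N-terminal). Pattern length is the sum of
element lengths, so length additivity under concatenation is exact.

The zinc-finger detector tries three presets in order — the 46-residue
consensus `CX2-CX14-ACX2-CX4-CX2-CX7-GX3-CX2-C`, its 8-residue-deleted
CesA7-lineage variant (`X14` → `X6`), and an older literature consensus —
and reports the most N-terminal hit of the first preset that matches,
with `deletion_size = 46 − matched length`. The literature preset's
printed tokenization is ambiguous around `CX2PXCX2`; it is compiled
literally as written.

The catalytic-core detector is anchored on QXXRW because it is the most
specific element. QXXRW occurrences are tried left to right; for each,
the DXD triplet nearest the anchor is accepted if a lone D lies between
it and the anchor (D3, the one nearest the anchor) and another lies
upstream of it (D1, the one nearest the triplet). The first anchor that
admits the full ordered signature D1 < D2 < D3 < QXXRW wins; if none
does, the core is reported absent. No inter-element spacing constraints
are imposed, since none are established for the family.

## Transmembrane prediction

Kyte–Doolittle hydropathy averaged over a sliding window; defaults are
window 19 and threshold 1.6, the standard convention for single-pass
detection of membrane-spanning helices. Positions whose window mean
reaches the threshold seed a region covering the full extent of their
windows (hence at least one window long); regions separated by less than
half a window are merged. Windows must be odd and at least 5. The caller
reports disjoint, sorted intervals; it does not attempt helix-boundary
refinement.

## Wall classification

Two independent evidence channels:

* **ZnF dipeptide** — the two residues inside the first C-X2-C pair of
  the matched zinc finger (the consensus itself begins C-X2-C, which
  makes this anchor deterministic): QI → PCW; EI → SCW/CesA4-like;
  AA → SCW/CesA7-like; RA → SCW/CesA8-like; anything else is
  uninformative.
* **TM2 motif** — the first occurrence of the conserved core SXXCEXWF;
  positions 2 and 3 of the core and the residue after the terminal F
  decide the variant: SVICE·WFA → PCW, SVLCE·WFA → CesA4-like,
  SVICE·WFG → CesA7-like, SIVCE·WFA → CesA8-like. The X at core
  position 6 is variable across the family and is never used as
  evidence. A core at the very end of a sequence (no residue after F)
  is treated as an unlisted variant.

Agreement of both informative channels gives the call at high confidence;
a single informative channel gives it at low confidence; disagreement or
no evidence yields `unknown` with confidence `none` and both evidences
reported — the two motifs are expected to be concordant in real proteins,
so a conflict is out-of-distribution and no priority rule is imposed.
When two concordant channels imply different ortholog lineages the call
stands but the lineage hint is withheld.

## Intron phases and structure statistics

The phase of intron *i* is the cumulative length of coding exons 1..*i*
modulo 3 — phases are codon-relative, so UTR exons are ignored and only
CDS features enter the computation. Single-exon genes yield an empty
vector (not an error). Summaries keep percentages at full precision and
also render them with round-half-up to integer; the published ranges for
this family appear to truncate at the upper end (6/9 prints as 66%), so
comparisons against printed ranges should use lower bounds only. ORF
length assumes the terminal stop codon is included in the CDS (standard
GFF3 practice) and subtracts it: `orf_length = exon_total // 3 − 1`.

The four canonical wheat phase vectors (the shared 13-intron PCW pattern
and the 7-, 12- and 9-intron patterns of TaCesA4/7/8) are shipped as
package data and serve as reference inputs. Which pattern applies to the
family members not covered by those four is not established, and no
pattern is invented for them.

## Phylogenetics

* **Complete deletion** — any column containing a gap or a non-canonical
  letter in any row is removed before distances are computed, and
  independently within each bootstrap replicate.
* **Poisson correction** — d = −ln(1 − p) with p the proportion of
  differing retained sites; the equal-rates, no-back-substitution
  correction. A saturated pair (p = 1) is an error, not an infinity.
* **Neighbor joining** — Saitou–Nei: join the pair minimizing
  Q(i,j) = (n−2)d(i,j) − r_i − r_j, with branch lengths
  v_i = d/2 + (r_i − r_j)/(2(n−2)) and the standard distance update.
  Ties in Q are broken by the lexicographically smallest (row, column)
  pair, making output deterministic on degenerate inputs. Negative
  branch-length estimates are clamped to zero and the total clamped
  deficit is recorded on the tree object. The final three lineages meet
  at an unrooted central vertex.
* **Bootstrap** — columns of the *input* alignment are resampled with
  replacement; complete deletion, Poisson correction and NJ run per
  replicate. Support for each internal bipartition of the full-data tree
  is the percentage of usable replicates containing it (support mapping,
  not majority-rule consensus). Replicates that become saturated or
  empty are skipped and counted; more than 50% skipped is an error.
  Supports are attached as internal node labels in the Newick output.
  The default is 1000 replicates; the test suite and acceptance script
  use 100, which is ample for the clean synthetic families they assess.

Newick output uses 6 significant digits for branch lengths and quotes
labels containing metacharacters; `read_newick(write_newick(t))`
preserves topology and path lengths.

## Expression clustering

CPM = count / library size × 1e6 per sample; log2 transform uses a 0.5
pseudocount so zeros stay finite (log2(0 CPM) = −1); z-scores are
per-gene with the population (n) standard deviation — the heat-map
scaling convention; the sample (n−1) choice would shrink all values by
the same factor and change no ordering. Constant genes are flagged and
dropped from z-scoring and clustering with a warning. Clustering uses
Pearson correlation distance d = 1 − r (signed, so anticorrelated
profiles are maximally distant at 2) and Ward linkage in the Ward.D2
convention, via scipy's implementation on the precomputed condensed
distance matrix. Heat-map rows follow the gene dendrogram's leaf order
and columns the sample dendrogram's. The published heat-map scaling
phrase is ambiguous between row z-scores and a global scaling; row
z-scores are implemented as the standard reading.

## Synthetic data

The generator produces the structures the analysis assumes, with every
coordinate recorded as ground truth:

* **Proteins** — N-terminal spacer, zinc finger, linker, TMD1, TMD2
  (carrying the class motif), the catalytic region (D1, DXD, D3, QXXRW at
  randomized spacings of 20–40 residues), six C-terminal TMDs, and a tail
  padding to the target length, drawn from 991–1091 residues as in the
  family's predicted ORF range. Composition is chosen so detection is
  deterministic, not merely probable: TMD fills come from strongly
  hydrophobic residues (every all-TMD window clears the 1.6 threshold),
  linkers from a hydrophilic loop alphabet free of C/W/F (so no spurious
  zinc-finger, TM2-core or QXXRW anchors), catalytic spacers additionally
  exclude D (so the nearest-neighbor rules recover exactly the recorded
  D1/D2/D3), the QXXRW wildcards are never D, and zinc-finger wildcard
  fills use a hydrophilic composition (the domain is cytoplasmic) so the
  domain can never present as a transmembrane window. Inter-TMD linkers
  (≥ 30 residues) keep hydropathy regions from merging.
* **Evolution** — a continuous-time uniform replacement process: each
  unprotected site receives Poisson(t) events per branch of length t,
  each replacing the residue with a uniformly random different one. Over
  a path of total length t the expected proportion of differing sites is
  (19/20)(1 − e^(−20t/19)), which the approximation 1 − e^(−19t/20)
  tracks within binomial noise at the divergences used here; the process
  matches the equal-rates assumption behind the Poisson correction. No
  indels, no rate heterogeneity, no codon structure — which is exactly
  why the family is its own alignment.
* **Showcase family** — one fixed, documented fixture: a PCW-type
  ancestor of 1040 residues diverges on deep branches (0.30
  substitutions/site) into three ortholog groups (PCW-type, CesA4-like,
  CesA8-like; CesA7-like is excluded because its zinc-finger deletion
  would break the equal-length invariant), each group's diagnostic
  motifs are rewritten to its lineage variant, and three "species"
  leaves evolve on shallow branches (0.05). Orthologs therefore cluster
  before paralogs, and with ~1000 informative sites the group
  bipartitions are expected at or near 100% bootstrap support on the
  fixed seed — asserted for that seed, not claimed universally.
* **Gene models** — exon lengths (≥ 30 nt, drawn 30–120) are adjusted
  modulo 3 so the cumulative coding length realizes any requested phase
  vector exactly; intron lengths default to 60–300 nt; total coding
  length is a multiple of 3.
* **Counts** — negative-binomial (var = m + 0.1 m²) on a 5-organ ×
  3-stage × 2-replicate design. SCW genes are 10× elevated in the
  mature-stem (stem, anthesis) samples only; PCW genes are 5× elevated
  everywhere else; baseline mean 100. Defaults are 7 SCW and 14 PCW
  genes, mirroring the group sizes seen in hexaploid families where
  homoeologs multiply each gene. This yields a cleanly separable
  two-group structure; it does not emulate homoeolog-specific expression
  differences, tissue gradients, batch effects or count overdispersion
  heterogeneity, so passing the clustering tests shows the pipeline
  recovers planted structure, not that it would resolve subtler
  real-data patterns.

All generation is seeded; the same seed reproduces byte-identical FASTA,
GFF3 and TSV outputs.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 100 labeled
proteins for classification accuracy, 50 random 5–8-taxon additive trees
for NJ recovery, 100 bootstrap replicates on the 9-leaf showcase family,
1000 random genes for the phase oracle, and the default 21-gene ×
30-sample count matrix. All randomness flows from explicit seeds; the
acceptance script derives per-stage seeds from its single `--seed`
argument via a seed sequence.

## Known limitations

* The motif scanner is exact-match over a fixed grammar; no profile
  scoring, so a single substitution in a fixed position loses the hit —
  appropriate for the diagnostic motifs here, wrong for remote homology.
* The catalytic-core detector can mislocate D1/D3 in sequences with
  additional aspartates adjacent to the true signature; on real proteins
  the positions should be sanity-checked against an alignment.
* The two-domain substructure sometimes ascribed to the CESA zinc-finger
  region is not modeled; the region is treated as one consensus unit.
* NJ is the only tree method; no ML/Bayesian inference, no rooting, no
  consensus trees.
* CPM is the only normalization; compositional (TMM-style) effects and
  differential-expression testing are out of scope.
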