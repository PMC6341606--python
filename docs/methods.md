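# Methods

## Scope and model

`paofam` classifies candidate plant polyamine oxidases (PAOs) from three
kinds of evidence: Pfam-style domain architecture, global-alignment
distance clustering, and deterministic subfamily motifs, with two
auxiliary analyses (active-site residue profiling and a homology-model
quality gate). The package consumes upstream outputs — hmmscan-style
domain hit tables, pre-computed MSAs, and SWISS-MODEL-style quality
scores — and never runs the external tools itself.

## Domain-architecture filter

Candidates must carry exactly one Amino_oxidase domain (PF01593) and no
other domain; proteins combining this domain with others (e.g. the SWIRM
domain of lysine histone demethylases) have non-PAO functions. The four
coordinate criteria are measured from a single domain hit:

| criterion | measure | threshold (default) |
|---|---|---|
| MISSING_SIDE | model positions not covered, per side: `hmm_from − 1`, `model_len − hmm_to` | ≤ 50 |
| INTERNAL_INDEL | `abs(env_span − hmm_span)` | ≤ 150 |
| FLANK | residues before/after the domain envelope | ≥ 5 |
| LENGTH | total sequence length | ≤ 700 |

Boundary semantics are literal: a value exactly at its threshold passes.
"Missing" is measured in model coordinates because it is the domain
model that is incomplete, not the sequence. The INTERNAL_INDEL measure
deserves a note: the underlying selection rule excludes sequences with a
long internal insertion/deletion inside the domain, and the absolute
difference between the sequence span and the model span of the hit is
the only proxy computable from domtblout-level coordinates without the
full HMM alignment. It is this package's interpretation, exposed as a
configurable threshold. A sequence with two copies of the target domain
fails ARCHITECTURE outright and its per-criterion values are left
unmeasured.

## Distances, UPGMA, and the 0.3 cut

The distance is the uncorrected p-distance with pairwise gap deletion:
mismatches over columns where neither sequence is gapped. `X` counts as
a comparable, always-mismatching position (including against another
`X`); a pair with zero comparable columns raises an error rather than
being assigned a silent maximum, because silent maxima corrupt the
clustering. p-distance is the minimal assumption for a "rough"
clustering stage; any externally computed `DistanceMatrix` can be
substituted.

UPGMA is the classical unweighted pair-group agglomeration: merge the
pair of active clusters with the smallest average distance, place the
new node at half that distance, update distances as size-weighted
averages. Ties are broken by the lexicographically smallest index pair
in cluster creation order, making the tree deterministic. The
implementation is O(n³) in the worst case, which is ample for
database-scale inputs (hundreds of sequences).

The cluster rule — leaves separated by accumulated branch length < 0.3
belong together — is read as the leaf-to-leaf path length through the
tree, with strict inequality. On an ultrametric tree that path equals
twice the height of the pair's most recent common ancestor, so the cut
is implemented exactly as "maximal clades with node height <
threshold/2"; tests verify it coincides with the transitive closure of
the pairwise path-length relation. A non-positive threshold yields all
singletons by construction. Whether the original procedure measured the
path between leaves or between internal nodes is not decidable from its
description; the leaf-pair reading is this package's documented choice.

## Motif engine

The pattern grammar covers uppercase literals, residue sets `[FY]`, the
wildcard `x`, and repeat suffixes `(n)` / `(n,m)` on a wildcard or set.
Matching is exact: a literal matches only itself, a set its members,
`x` any residue. The unknown residue `X` in a sequence matches only
`x` — one consistent rule everywhere (it likewise counts as a mismatch
in distances). The scanner propagates a set of reachable offsets through
the element list, so variable repeats need no backtracking; every
matching start position is reported with the *shortest* matching extent.
Shortest (rather than ScanProsite-style greedy) extent is deliberate:
classification only needs presence, and the shortest extent is the
cheapest to verify independently. Tests hold the scanner equal to an
independent regex-translation matcher on ≥ 10⁴ seeded pattern/sequence
pairs.

Classification scans all four packaged motifs: exactly one match names
the subfamily; zero is `NO_HIT`; two or more is `AMBIGUOUS`. `AMBIGUOUS`
exists because the package refuses to invent a priority order among
motifs. The motif strings ship as packaged data (`data/motifs.tsv`),
never retyped in code.

## Active-site profiler

The nine reference positions are given in ZmPAO1 (O64411) ungapped
coordinates and mapped through the alignment via the reference row; the
mapping is a strictly increasing injection, and a mismatch between the
observed and expected reference residue warns but does not abort (the
reference row may be a close homolog). Returned columns are 0-based
internally; all serialized coordinates are 1-based.

Per-clade frequency tables (reference excluded) are summarized with
explicit stand-in thresholds, since the underlying table format never
states a rule: gap frequency ≥ 0.5 prints "–"; otherwise residues with
frequency ≥ 0.2 are listed in descending frequency (ties alphabetical by
three-letter code) joined by "/". The aromatic sandwich requires
combined F/Y/W frequency ≥ 0.9 *and* gap frequency < 0.5 at both
positions 401 and 437. Reaction mode uses the modal residue at the
60-position with a 0.5 cutoff: Glu → TC, any other conserved non-gap
residue → BC, no consensus → UNKNOWN. Lys300 conservation is reported
(combined K frequency) but never gates anything. An MmAPAO-frame
position preset is shipped for display; the heuristics are defined on
the ZmPAO1 frame only.

## Model-quality gate

Low quality ⇔ |QMEAN Z| > 4.5 or GMQE < 0.6, strict, so the boundary
values are acceptable. A clade is excluded from the PAO subfamilies only
when every model of every member is low quality (the per-clade reading;
a per-sequence-majority reading would be stricter and is not what the
exclusion rule describes). "Best template" ranks GMQE first and
|QMEAN Z| second — the two scores are never ranked by the upstream
convention, so the order is this package's choice, configurable through
the record structure; the clade-level template is the per-sequence
majority with ties resolved in the fixed order 3KU9, 1XPQ, 5MBX.

## Synthetic data

The generator produces exactly the distributions its consumers' tests
need, all seeded through `numpy.random.default_rng`:

* **Motif realizations** draw uniform set members and uniform repeat
  lengths, wildcards from the background; embedding splices a
  realization into a background sequence at a recorded position.
* **Families** use a star topology: each descendant independently
  substitutes each ancestral site with probability `p`, replacing it
  with a uniformly chosen different residue. Two descendants then
  differ at a site with probability `1 − [(1−p)² + p²/19]`
  (≈ 0.0974 at p = 0.05), giving a closed-form oracle for the distance
  stage. The star (rather than a coalescent) is chosen precisely for
  that closed form — testability over realism. Background frequencies
  default to uniform (expected unrelated-pair distance 0.95).
* **Filter tables** construct coordinates violating exactly one
  criterion by exactly one unit, or passing with every measured value
  exactly at its threshold.
* **Planted alignments** put an ungapped reference row with the expected
  active-site residues (so position p maps to column p) and draw clade
  rows from planted per-column distributions, which may include gaps.

What the generator does **not** emulate: indels and alignment error
(family sequences are generated aligned), site-rate heterogeneity,
compositional bias, and realistic domain-coordinate noise. Passing tests
therefore demonstrate the correctness of the algorithms under their
stated models, not robustness to real-data artifacts such as misaligned
regions or fragmented gene models.

## Problem sizes and numerical choices

The test and acceptance workloads use 8–15-taxon matrices for the UPGMA
oracle comparisons, 10-member families of length 2,000 for distance
recovery, 100 replicates of two 5-member families (length 300) for
cluster recovery, 200 boundary filter cases, 200 planted-motif
classifications, and 10⁴ scanner/regex pairs; these sizes give the
statistical tests comfortable power while keeping each suite in seconds.
Symmetry of distance matrices is enforced to 1e-12, tree-height
comparisons to 1e-9; branch lengths are serialized with `%.10g`.

## Known limitations

* Published database-scale outcomes (a 543-sequence angiosperm database,
  thirteen clades with specific sizes) depend on a historical Pfam
  release and external services, and are not reproducible from this
  package alone; the acceptance surface is oracle equivalence, synthetic
  recovery and the documented threshold logic instead.
* The motif classifier is only as good as the four packaged patterns;
  sequences from lineages outside the patterns' training breadth
  legitimately return `NO_HIT`.
* The reaction-mode heuristic is a structural-genomics prediction, not a
  biochemical assay; clade-level calls on real data should be read as
  hypotheses.
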