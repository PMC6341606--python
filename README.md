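# paofam

Tools for defining and assigning **plant polyamine-oxidase (PAO) subfamilies**
from protein sequence data.

Plant PAOs are FAD-dependent amine oxidases that catabolize the polyamines
spermine and spermidine, either by terminal catabolism (TC, yielding
1,3-diaminopropane) or by back-conversion (BC, yielding spermidine/putrescine).
The family is heterogeneous and remote homologs are hard to assign by pairwise
similarity alone. `paofam` implements a classification pipeline built on
domain architecture and deterministic sequence motifs:

1. **Domain-architecture filter** — candidate PAOs carry exactly one
   Amino_oxidase domain (Pfam PF01593) and no other domain. Candidates are
   further screened on four coordinate-based criteria (≤ 50 model positions
   missing per side, internal indel excess ≤ 150 aa, ≥ 5 aa flanks,
   ≤ 700 aa total length).
2. **Rough clustering** — uncorrected p-distances with pairwise gap deletion
   from a global MSA, a UPGMA (average-linkage) ultrametric tree, and a cut
   into clades: leaves separated by accumulated branch length < 0.3 share a
   cluster (on an ultrametric tree, leaf-pair path length = 2 × MRCA height).
3. **Model-quality gate** — homology-model scores against the three PAO
   crystal structures (ZmPAO1 3KU9, FMS1 1XPQ, MmAPAO 5MBX) are consumed;
   a model is low quality when |QMEAN Z| > 4.5 or GMQE < 0.6, and a clade
   counts as a PAO subfamily unless every model of every member is low
   quality.
4. **Active-site profiler** — the nine ZmPAO1 active-site positions
   (Tyr437, Phe401, Glu168, Tyr296, Glu60, Tyr167, Tyr163, Asn232, Lys300)
   are mapped through the MSA; per-clade residue frequency tables drive two
   heuristics: the *aromatic sandwich* (F/Y/W dominating positions 401 and
   437) and the reaction mode (Glu at the 60-position → TC; His or another
   conserved residue → BC).
5. **Motif classifier** — four PROSITE-style motifs, one per subfamily
   (PAObc3, PAOtc, PAObc2, PAObc1), shipped as packaged data. A sequence
   matching exactly one motif is assigned to that subfamily; `NO_HIT` and
   `AMBIGUOUS` are explicit outcomes.

A synthetic-data module generates seeded fixtures with known truth for every
stage (motif realizations, star-topology families with closed-form expected
p-distance, boundary-exact filter tables, planted active-site alignments).

## Worked example

```sh
paofam simulate filtertable --seed 3 --out demo --n 12
paofam filter --fasta demo/sequences.fasta --domains demo/domains.tsv \
       --out-fasta demo/survivors.fasta --out-report demo/report.tsv
```

prints

```
2/12 sequences pass
```

Twelve boundary-constructed candidates cycle through one passing case and the
five violation classes, so exactly the two `PASS` cases survive;
`demo/report.tsv` lists per-sequence failure codes and every measured value
(missing model positions, indel excess, flank lengths, length).

Clustering a planted two-family alignment:

```sh
paofam simulate family --seed 3 --out fam --n 6
paofam cluster --msa fam/family.fasta --threshold 0.3 \
       --newick-out fam/tree.nwk --clusters-out fam/clusters.tsv
```

prints

```
7 sequences -> 1 clusters
```

(the six descendants plus their ancestor differ by an expected pairwise
p-distance of ≈ 0.097 at the default substitution rate 0.05, well inside the
0.3 cut, so they form a single clade).

Classifying sequences with the packaged motifs:

```sh
paofam simulate motifs --seed 3 --out mot --n 4
paofam classify --fasta mot/motifs.fasta --out mot/calls.tsv
```

prints

```
motif_0	SUBFAMILY_1
motif_1	SUBFAMILY_2
motif_2	SUBFAMILY_3
motif_3	SUBFAMILY_4
```

Each simulated sequence embeds one realization of a subfamily motif at a
recorded position (`mot/truth.tsv`), and the classifier recovers the planted
subfamily.

`paofam run --config run.toml` composes all stages and writes a
machine-readable `run_summary.json` recording every threshold used.

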