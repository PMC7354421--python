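# Methods

## Problem and model

`tasprof` answers a presence/absence question: which bacterial strains
(or, when strains cannot be separated, which strain groups and species)
are present in a shotgun metagenome? It answers it from a small panel
of marker genes — type II toxin–antitoxin system (TAS) loci — instead
of whole genomes. The working assumptions are:

* every catalog record is a nucleotide TAS gene variant tied to one
  (genus, species, strain) and one TAS family;
* variants of the same (genus, family) are homologous enough for global
  pairwise alignment to define positional homology between them;
* strain identity is carried by substitutions (and occasionally indels)
  at those homologous positions, not by gene content;
* a read set at a few-fold coverage of a present genome will cover its
  TAS genes nearly end-to-end.

## Marker extraction

Variants are grouped by (genus, TAS family). The grouping key is a
design choice: grouping per genus keeps cross-species markers (which
let the caller separate species) while keeping the all-vs-all cost of a
group quadratic in a small number. Within a group, every ordered pair
is globally aligned under fixed scoring — match +1, mismatch −1, gap −2
linear, with a deterministic traceback (substitution preferred over a
gap, gap in the second sequence preferred over gap in the first) — so
marker extraction has no randomness. The aligner is a bespoke
Needleman–Wunsch (vectorized row recurrence with a running-maximum
closure for the linear gap chain) because the fixed tie-break order is
part of the contract; no general-purpose aligner exposes it.

A column where the pair disagrees yields a candidate marker on the
first sequence at its own (ungapped) coordinate; a run of g consecutive
gap columns is one indel marker at the run's leftmost owner coordinate,
which prevents a g-base indel from inflating the marker count g-fold.
Candidates landing on the same (gene, position) merge. The sharing set
of a marker is computed from the owner's alignments to every other
member (the members showing the owner's allele at that position), and
uniqueness is the number of distinct *strains* in the sharing set —
two records of the same strain do not make an allele ambiguous.

A caveat found while validating against a brute-force column scan:
when two variants differ at adjacent columns that happen to form a
shifted repeat, the *optimal* global alignment places compensating
indels instead of two substitutions, and positional homology becomes
genuinely ambiguous. The column-scan equivalence therefore holds — and
is tested — for variants whose differing columns are isolated (the
"gap-free" regime); adjacent-column groups are still processed
deterministically, just not oracle-checkable.

## Read mapping and evidence

The built-in aligner indexes catalog genes by exact k-mers (k = 21,
minimum 11) and evaluates each candidate placement of a read (both
strands) by ungapped Hamming comparison over the read/gene overlap.
The single best hit per read is kept — fewest mismatches, then longest
span, then lexicographically smallest gene id — and must span
≥ 50 bp with ≥ 95 % identity. Ungapped extension is adequate because
catalog genes average ~300 bp and discriminating markers are dominated
by substitutions; reads with indels, or alignments from a production
aligner, enter through the SAM import path (pysam), which derives
intervals from the CIGAR walk and mismatches by comparing the query to
the catalog sequence at aligned positions. Coordinates are 0-based
half-open internally; all report files are 1-based.

Per gene the evidence is: breadth (union of hit intervals, in bp and %
of gene length), per-position depth, and at each marker position the
multiset of read bases (the listed mismatch base, else the reference
base). Multi-mapping is resolved winner-take-all; reads tied between
two sibling variants (i.e. avoiding every discriminating position) are
assigned to the lexicographically smaller gene id, which slightly
starves the other sibling's breadth — a visible effect at low coverage.

## Genotyping and calling

A marker position is a **significant SNP** when its depth is
≥ `min_allele_depth` (default 1 — simulated panels run at 3–7×, where
requiring duplicate observations would discard most positions) and all
observed reads agree. Only substitution markers qualify: indel alleles
cannot be observed by an ungapped mapper, and even imported gapped
alignments report them asymmetrically, so indel markers inform marker
counts but not genotypes. The strains **consistent** with a gene are
those carrying the observed allele at every significant SNP (with no
significant SNPs, the whole variant group remains consistent — no
evidence, no exclusion).

The seven thresholds act strictly downstream of this evidence:

| parameter | default | range | meaning |
| --- | --- | --- | --- |
| `uniqueness_max` | 1 | 1–15 | largest reportable strain-group size |
| `min_marker_coverage_bp` | 170 | 30–280 | breadth floor, bp |
| `min_gene_coverage_pct` | 98 | 40–100 | breadth floor, % of gene |
| `min_significant_snps` | 3 | 0–20 | SNP floor per admissible gene |
| `min_tas_species` | 5 | 2–15 | admissible genes to report a species |
| `min_tas_summary` | 1 | 1–10 | supporting genes for the summary report |
| `min_tas_short` | 2 | 1–10 | supporting genes for the short report |

A strain's reported group is the intersection of the consistent-strain
sets over its supporting genes; its size is the row's uniqueness. The
detected set is the intersection of the two reports' labels. This
composition of the three TAS-count parameters (species gate, and one
gate per report file) is the one reading under which both report files
exist, their thresholds differ at the optimum, and detection is
monotone: tightening any parameter never enlarges the detected strain
or species set (proved over randomized evidence in the test suite).

## Synthetic data

The generator emulates the benchmark that tuned the thresholds, at desk
scale:

* **catalog**: per (genus, family) a uniform random ancestor gene
  (306 bp default); each species substitutes 10 % of positions (drawn
  without replacement); each strain substitutes 3 further positions of
  its species sequence. Defaults: 3 genera × 3 species × 2 strains ×
  3 genes.
* **genomes**: a strain's genes embedded in i.i.d.-random background at
  random non-overlapping offsets (≥ one read length of flank), 6 kb
  total — a stand-in for full genomes that preserves the
  gene-recovery task while keeping run times in seconds.
* **reads**: fixed-length (100 bp), uniform start and strand,
  per-genome count `round(coverage × genome_len / read_len)` (coverage
  3–7× typical, 5× default) or a total split by abundance × length;
  each base flips to a uniformly random different base with probability
  `error_rate` (substitution-only error model, constant quality) —
  DWGSIM-like without its indel and quality machinery. Fixed seeds give
  byte-identical FASTQ.

What the simulations do *not* model: real inter-strain divergence
structure (recombination, gene loss), GC/PCR bias, quality-dependent
errors, indel sequencing errors, and real background DNA that resembles
catalog genes. Passing tests therefore demonstrate the pipeline's
internal correctness and its behavior under idealized sampling, not
field performance on real stool metagenomes.

A quantitative consequence of the 5× operating point, measured with
this package: breadth ≥ 98 % of a 306 bp embedded gene is a stochastic
event (uniform read starts leave ~5 gaps of ≥ 93 bp per 6 kb genome,
and the 50 bp minimum aligned length halves the effective redundancy at
gene edges), so per-gene admissibility is ~0.8 and a 3-gene strain is
recovered in ~85 % of runs. Mixtures are recovered exactly in roughly
half the seeds, and misses — never false positives, which were 0 in
20/20 measured runs — account for the rest. This matches the
sub-unity Jaccard indices such marker panels report at 3–7× coverage;
exact recovery on every seed is not a property of these conditions.

## Evaluation and optimization

JI = TP/(TP+FP+FN) over taxon label sets; by convention JI = 1 for an
empty truth with empty prediction and JI = 0 for an empty prediction
against a non-empty truth. FPR = 100·FP/(TP+FP) — the share of reported
taxa that are wrong (a false-discovery proportion; a classical FPR is
ill-defined without a closed universe of negative taxa). The
denominator is isolated behind one function with a `union` alternative.
At strain level a predicted "+"-group is a true positive iff it
contains a truth strain. Aggregation is the arithmetic mean with the
n−1 sample standard deviation over √n as SEM (0 when n = 1); rounding
(2 decimals) happens only at presentation.

The optimizer applies every grid configuration to *cached* per-gene
evidence — all seven thresholds act after alignment and genotyping, so
mapping runs once per sample regardless of grid size. The
(mean JI, mean FPR) cloud reduces to its Pareto front (maximize JI,
minimize FPR); a front larger than k (default 12) keeps the k highest
`JI − FPR/100` scores, and dominated points are never shortlisted. The
operating point is the shortlist member with minimal FPR among those
within `ji_slack` (default 0.1) of the best JI — ties to higher JI,
then lexicographically smaller config, keeping the whole procedure
deterministic.

## Numerical and degenerate-input choices

* Identity is matches / alignment columns (gaps count), everywhere.
* Plasmid filtering uses local alignment (Biopython `PairwiseAligner`,
  BLAST-like scores 2/−3/−5/−2) of each gene against each plasmid and
  both strands; a gene is excluded at ≥ 70 % identity over ≥ 80 % query
  coverage (both configurable). An empty plasmid set filters nothing.
* Deduplication at identity 1.0 removes exact repeats (same-taxonomy
  repeats first, then sequence-identical records); below 1.0 it runs
  greedy longest-first clustering, keeping each cluster head's
  metadata and logging removed ids to provenance. Idempotent by
  construction.
* Empty catalogs, empty hit lists, unmapped genes, singleton variant
  groups and samples with empty predictions are all legal inputs with
  defined outputs; empty sequences, duplicate gene ids, unknown SAM
  references and markers beyond a gene's length raise errors naming
  the offender.
* Report determinism: rows are keyed and ordered by label; grid
  iteration order is the Cartesian product in field order.

## Known limitations

* Winner-take-all mapping cannot share a read between indistinguishable
  variants; coverage-based admissibility is therefore conservative for
  the lexicographically larger of two near-identical variants.
* Indel markers are extracted and serialized but do not contribute to
  genotypes (see above).
* No abundance estimation: outputs are presence/absence with evidence
  counts.
* The ungapped internal aligner under-maps reads with true indels;
  use an external aligner and `import-sam`/`--sam` when that matters.
* Paired-end relationships are ignored (mates map independently).
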