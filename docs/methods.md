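# Methods notes

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Group assignment

Each of the seven LEA groups is diagnosed by one Pfam profile
(PF03760→LEA_1, PF03168→LEA_2, PF03242→LEA_3, PF02987→LEA_4,
PF00477→LEA_5, PF00257→DEHYDRIN, PF04927→SMP). The profile search itself
is out of scope: hits arrive as an hmmscan-style `domtblout` table
(whitespace-delimited; profile name/accession in columns 1–2, protein id
in column 4, full-sequence e-value/score in columns 7–8, alignment
coordinates in columns 18–19).

* **Significance cutoff** `1e-5` (configurable). Common Pfam practice; no
  single value is canonical.
* **Best hit** = lowest e-value, ties by higher bit score; an exact tie
  across different groups flags the protein `ambiguous` rather than
  picking silently.
* **Orphan rescue**: proteins with no significant hit take the majority
  group among their k = 3 nearest domain-assigned leaves by patristic
  distance in the family tree. k = 3 is the smallest odd neighbourhood
  robust to a single stray leaf. A majority tie falls back to the single
  nearest leaf; an equidistant disagreement leaves the protein
  `unassigned`.
* **Reconciliation**: domain evidence always outranks tree placement — a
  domain-assigned protein sitting in a foreign clade keeps its group and
  only gains a `tree_discordant` flag. Real surveys regularly meet such
  proteins; reclassifying them by eye is not reproducible.

## Physicochemistry

Molecular weight uses average isotopic masses (ProtParam convention):
sum of free-residue masses minus (n−1) × 18.01528 Da, via Biopython.
GRAVY is the mean Kyte–Doolittle hydropathy per residue (scale embedded
in `physchem.KYTE_DOOLITTLE`; Kyte & Doolittle 1982, J Mol Biol 157:105).
Unknown residues raise an error naming the position — silent skipping
would bias both quantities. Additivity of MW holds to the precision of
the underlying mass table (~1e-3 Da), which the property test reflects.

## Phylogeny

* **Distances**: uncorrected p-distance with *pairwise deletion* (only
  columns where neither sequence has a gap are compared); a pair with no
  comparable columns is an error, not a guess. A Poisson correction
  (−ln(1−p)) is available via a flag. The upstream tools this mirrors do
  not document their exact model; these are explicit substitutes.
* **NJ**: classic Saitou–Nei agglomeration on the Q-criterion,
  Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k). Joined-pair ties break on
  the lexicographically smallest (sorted) cluster-label pair, a cluster
  being labelled by its smallest member taxon — this makes degenerate
  matrices (all distances equal) fully deterministic. Negative branch
  estimates are clamped to 0 and counted on
  `tree.negative_branches_clamped`; Newick consumers reject negatives.
* **Bootstrap**: alignment columns resampled with replacement per
  replicate; the support of each internal edge of the point tree is the
  fraction of replicate trees containing the same bipartition. The point
  tree never depends on the seed. The pipeline default is 100 replicates
  (the classical 1000 is a flag away; on the synthetic data supports are
  saturated at ≥ 0.9 already at 100).
* Correctness is checked against a brute-force oracle that enumerates
  every unrooted topology on 5–7 taxa and fits branch lengths by least
  squares: on additive matrices NJ must return the unique zero-residual
  topology.

## Gene structure

The primary transcript of a gene is its mRNA with the longest total CDS
(ties: lexicographically smallest transcript id) — display conventions of
gene-structure figures rarely say which isoform was drawn, so the rule is
explicit here. Intron count = exons − 1, computed from exon features (not
CDS). Summary percentages round half-up to whole percent, matching the
way such headlines are printed (40/72 → 56%).

## Duplication classification

* **Similarity** is percent identity over the non-terminal-gap columns of
  a global Needleman–Wunsch alignment (BLOSUM62, gap open −10, extend
  −0.5, Biopython's deterministic first traceback). Published "similarity"
  values in family surveys are rarely defined; identity is the
  reproducible default.
* **Coverage** is the fraction of the longer protein's residues inside
  the aligned (trimmed) region — bounded [0,1] even when internal gaps
  stretch the alignment.
* **Tandem** (proximity criteria): same group, same chromosome, nearest
  gene boundaries ≤ 100 kb, and ≤ 10 spacer genes lying wholly between
  the pair, where spacers exclude family members ("nonhomologous").
  **Segmental** (homology criteria): coverage > 0.8 and similarity > 70%,
  not tandem-qualifying. Tandem takes precedence when both hold — the
  proximity criteria explicitly encode the mechanism.
* Genomic distance is measured between nearest gene boundaries (end of
  the upstream gene to start of the downstream one): the conservative
  reading of "within 100 kb of each other".
* Multi-gene tandem clusters are reported both as pairs and as connected
  components (`tandem_clusters`), since "n pairs" is ambiguous over
  clusters of ≥ 3 genes.

## Promoter scanning

The promoter is the 1 kb immediately 5′ of the translation start on the
coding strand (reverse-complemented for minus-strand genes, truncated
with a warning at contig edges). Motifs are IUPAC degenerate strings
(DRE/CRT's G-or-A lead base is encoded as R) matched with an
overlap-tolerant regex on both strands; `N` never matches. Every
occurrence counts independently: **an LTRE (CCGAC) fires inside every
DRE/CRT (RCCGAC) hit by construction** — this mirrors how cis-element
databases report each signal separately, and a `forward_only` flag plus
the registry abstraction make both conventions testable. For a
palindromic motif the + and − hit sets coincide positionally and the
total is twice the forward count (documented behaviour of the
independence rule).

## Expression and qPCR

* log₂(RPKM + 1): the pseudocount keeps zeros at zero; figure captions in
  the literature rarely state their zero handling.
* Clustering: average linkage on 1 − Pearson correlation across tissues.
  A zero-variance gene has undefined correlation; its distances are set
  to the maximum (1.0) and the gene is flagged. Partitions are invariant
  to input order.
* ΔΔCq: log₂FC = ΔCq_target − mean(ΔCq_refs), ΔCq = mean control Cq −
  mean treated Cq, with both reference genes (GAPC2, UPL7) averaged on
  the ΔCq scale; a `--refs` flag selects a subset, since single-reference
  normalization is equally common. Amplification efficiency is fixed at
  2 — without standard curves this is an assumption, and a documented
  limitation.
* Differential call: up if log₂FC ≥ 1.0, down if ≤ −1.0, boundaries
  inclusive.

## The synthetic dataset

The generator is the package's test bed: it emulates the *statistical
structure* the pipeline assumes, not the biology of any real genome.

* **Genome**: 9 chromosomes of i.i.d. uniform A/C/G/T background. Family
  genes outside tandem clusters are separated by > 100 kb so that only
  planted clusters can satisfy the tandem criteria.
* **Proteins**: each group descends from its own random ancestor (group
  lengths 77–150 aa), carries a fixed signature (dehydrins the 15-residue
  K-segment EKKGIMDKIKEKLPG, verbatim and never mutated), and is
  composition-biased — LEA_2 from hydrophobic residues (GRAVY > 0), all
  other groups hydrophilic (GRAVY < 0). Ordinary members differ from the
  ancestor at 30% of positions (≈ 55% pairwise identity), tandem-cluster
  members at 5% from their cluster seed (≈ 90%), and segmental partners
  are point-mutated copies hitting the target identity within ±1%. An
  enforcement loop re-draws members until every unplanted same-group pair
  stays ≤ 67% identity, so nothing but planted pairs can cross the 70%
  segmental threshold. Because divergence is substitution-only, the
  emitted per-group "alignments" are exact, and the combined alignment is
  a trailing-gap padding of the group blocks (all groups share their
  leading columns, so pairwise-deletion distances are always defined).
* **Promoters**: each planted motif occurrence (strand chosen at random)
  is written with guard bases that cannot complete a registered motif
  across the junction (a background C before ACGTG would create a
  reverse-strand hit), into background that is rejection-sampled to be
  motif-free; the finished promoter is re-verified with an independent
  brute-force scan and redrawn on any mismatch, making planted counts
  exact truth. Planting DRE/CRT implies its nested LTRE, so configured
  LTRE counts must be ≥ DRE/CRT counts.
* **Expression**: five clade profiles over four tissues (callus, flower,
  leaf, fruit), assigned round-robin, with per-gene scale and 5%
  log-normal noise — within-clade correlation ≈ 1, between-clade
  correlation well below, so the 5-way dendrogram cut recovers the
  partition exactly.
* **qPCR**: Cq ~ Normal(mean, 0.05) per replicate, 3 replicates,
  treated mean = control − planted log₂FC; reference genes have zero
  shift. Planted effects are 0 or |log₂FC| ≥ 1.2, which keeps the ±1.0
  call deterministic at this noise level.
* Defaults are the study-design constants (72 genes split 4/43/5/7/3/6/4;
  40/31/1 intron counts with the three-intron gene in SMP; 7 tandem
  clusters sized 2/4/3/2/2/3/2; segmental similarities 80.4/74.6/71.3%;
  17 promoters with ≥ 10 ABREs; 9 differentially expressed genes across
  drought/PEG/NaCl in leaf and root). Custom `group_sizes` require
  explicit `promoter_plants`/`qpcr_effects`, as the defaults index the
  default census.
* **Not emulated**: codon usage, repeat content, isoform diversity, UTRs,
  read-level noise, between-library normalization. Passing tests
  demonstrate that the *pipeline logic* is correct under its stated
  assumptions; they say nothing about annotation quality or alignment
  artefacts in real genomes, where e.g. similarity values depend on the
  aligner and isoform choice.

## Problem sizes

The test suite and acceptance script run everything at the design scale
above (72 genes, ~6.5 Mb genome, 100-replicate bootstraps, 100 oracle
trials on 5–7 taxa), generated programmatically at run time; a full
pipeline run takes a few seconds on one CPU.

## Known limitations

* NJ is O(n³) in pure numpy-assisted Python — comfortable to a few
  hundred taxa, not thousands.
* The ΔΔCq caller applies the fold-change rule only; it deliberately
  performs no statistical testing across biological replicates.
* The exhaustive alignment-score oracle and topology-enumeration oracle
  are exponential and exist only for validation at tiny sizes.
* Subcellular-localization prediction and de-novo motif discovery are out
  of scope by design; localization tables can be joined onto the
  physchem output externally.
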