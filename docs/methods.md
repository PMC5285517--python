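# Methods

## The screen

`hgtscreen` asks, for every gene of one *focal* genome, whether the gene's
closest relatives in its own phylogeny sit inside or outside the focal
phylum.  The unit of inference is the **sister clade**: in the rooted gene
tree, the other daughter of the node where the focal tip(s) attach.  The
decision rule, applied per gene:

1. no usable tree, or the focal tips are the whole tree → **no_tree**;
2. the sister clade contains any genome of the focal phylum → **vertical**
   (the gene's neighborhood is compatible with vertical descent);
3. the sister clade is drawn from exactly one foreign phylum, and the
   bootstrap support of the shared node is at least `min_support` (or no
   bootstrap was run) → **interphylum_transfer**, with that phylum as the
   putative donor;
4. otherwise (sister mixes foreign phyla, or support is too low) →
   **ambiguous** — the "Other" bucket of the source breakdown.

Donor attribution is refined phylum → class → genus and each rank is filled
only when *every* sister leaf agrees at that rank.  Unanimity rather than
majority keeps the attribution conservative: a sister of *Campylobacter* +
*Helicobacter* yields a class-level donor (Epsilonproteobacteria) and no
genus.

When the focal genome carries several copies of a gene and the copies are
not monophyletic, the leaves intermingled with them inside their smallest
containing clade are used as the sister (the copies "bracket" those leaves,
which is the strongest neighborhood signal available without a
reconciliation model).

The genome-level summary reports the interphylum fraction with two
denominators: genes for which a tree could be built (the primary number)
and all genes screened.  Both are reported because the two denominators
answer different questions and the difference matters when many genes lack
sufficient homologs.

## Gene trees

Per-gene trees are built deterministically at desk scale:

* **Homolog sets** — exact global alignment (Gotoh three-state affine DP,
  no heuristic seeding) of the query against every candidate; candidates
  are kept at ≥ 30% identity over ≥ 80% of the query.  These thresholds
  are also used for the synteny comparison below.
* **Alignment** — progressive MSA: single-linkage guide clustering on
  pairwise p-distances, profiles merged by affine-gap DP over
  frequency-vector column scores.  Ungapping any output row recovers its
  input exactly.
* **Distances** — p-distances over columns where both rows have residues,
  corrected with Jukes–Cantor for nucleotides (d = −¾ ln(1 − 4p/3)) or the
  Poisson correction for proteins (d = −ln(1 − p)).  Pairs beyond the
  model's explainable range (p ≥ 0.75 for JC) are flagged saturated and
  capped at 5 substitutions/site.
* **Tree** — neighbor joining with Studier–Keppler updates.  Q-matrix ties
  are broken by the lexicographically smallest pair of cluster
  representative labels; negative branch-length estimates are clamped to
  zero with the deficit moved to the sibling branch.  NJ was chosen over
  maximum likelihood deliberately: it is deterministic, fast enough for
  hundreds of families on one CPU, and statistically consistent on additive
  distances — the tests exploit that consistency by checking exact topology
  recovery against a brute-force least-squares oracle.
* **Support** — nonparametric bootstrap (default 500 replicates when
  requested): alignment columns resampled with replacement, each replicate
  re-run through distances + NJ, support = percentage of replicates
  containing the original bipartition.  Supports ride on *edges*
  internally so they survive rerooting, and appear as integer internal-node
  labels in Newick.
* **Rooting** — midpoint: the root bisects the longest leaf-to-leaf path;
  ties go to the lexicographically smallest leaf pair.  An all-zero-length
  tree is rooted on the first edge and flagged arbitrary.

## The simulator

The simulator emulates the screen's intended setting: a focal organism in a
small, deep-branching phylum surrounded by several foreign phyla, with a
fraction of its genes acquired from those phyla.

* **Species tree** — an ultrametric pure-birth backbone on the non-focal
  taxa joined at the root with a small focal clade (`focal_clade_size`,
  default 3), so the focal phylum is monophyletic and basal.  Terminal
  branches are extended uniformly (keeping the tree ultrametric) to avoid
  the zero-length twin tips a stopped birth–death simulation produces.
  Height is normalized to `tree_depth` (default 0.5 expected
  substitutions/site root-to-tip — diverged enough to be nontrivial, shallow
  enough that a few hundred sites support reliable reconstruction).
* **Taxonomy** — phyla are the focal clade plus the `n_phyla − 1` clades
  below the earliest backbone divergences; class/order/family/genus come
  from progressively deeper depth cuts (45/60/72/84% of tree height), so
  every rank is monophyletic by construction and "interphylum" is
  well defined in truth.
* **Transfers** — with probability `p_transfer` per family, the focal tip is
  pruned and regrafted as sister to a uniformly chosen foreign-phylum leaf,
  at half the donor's terminal branch (keeping the transferred tip strictly
  inside the donor clade).  Transfer *replaces* the vertical copy; additive
  xenolog copies and donor↔donor transfers are not modeled, because the
  screen classifies each focal gene once.
* **Rates** — per-family branch-length rescaling by a lognormal factor with
  mean 1 (σ = 0.25), a mild proxy for among-gene rate variation.
* **Sequences** — root drawn uniform i.i.d.; sites evolve independently
  along each branch with exact JC69 or K2P transition probabilities
  (default JC69, `seq_length` 400).  No indels are simulated, so family
  FASTA files are pre-aligned; the MSA stage still runs on them and must
  return them unchanged modulo gaps.

What the simulator does **not** emulate — gene gain/loss, duplication,
rate heterogeneity across sites, compositional bias, indels, incomplete
homolog sampling, misannotation — bounds what passing tests mean: they
validate the *inference machinery* under the model's assumptions, not the
screen's error rate on real genomes, where unmodeled processes (notably
long-branch effects and database incompleteness) inflate ambiguity.

Every simulator output is a pure function of `SimConfig`; the dataset,
gene trees, reports and calls are byte-identical across reruns.

## Numerical and design choices

* **Alignment scoring** — default nucleotide scoring match=1, mismatch=−1,
  gap open=−2, extend=−1; a gap run of length L costs open + (L−1)·extend,
  terminal gaps included.  Identity excludes terminal-gap columns from its
  denominator; query coverage counts query residues paired with subject
  residues.  Traceback ties prefer substitution > gap-in-subject >
  gap-in-query, making alignments deterministic.
* **The 30%/80% bar and alphabets** — at protein scale random alignments
  sit near 20% identity, so the bar separates signal from noise.  Optimal
  global alignments of *random DNA* under the permissive default scoring
  average ≈ 52% identity, so for nucleotide data the identity bar alone
  does not exclude unrelated genes; nucleotide screens should rely on
  curated candidate sets (as the synthetic mode does, where each family is
  a candidate set) or stricter scoring.  Protein is the documented default
  alphabet for real screens.
* **Bootstrap defaults** — 500 replicates for the standalone tree builder;
  the end-to-end pipeline defaults to 0 replicates because its default
  `min_support` is 0 (supports would be computed and then never gate a
  call); both are configurable.
* **Acceptance-scale runs** — the false-positive and recovery studies use
  200 families, 40 taxa, 4 phyla and 400 bp under JC69; each run takes a
  few minutes on one CPU with the exact (non-heuristic) aligner.
* **Degenerate inputs** — signal-free alignments give an arbitrary NJ
  resolution flagged `uninformative` with all supports 0; empty sister
  clades become `no_tree`; zero shared synteny pairs score 0 with a logged
  warning.

## Synteny

Shared genes between two regions/genomes are reciprocal best hits (best =
highest identity, ties by coverage then id) at the same 30%/80% bar.
Order conservation is LCS(paired order in A, paired order in B)/n_pairs,
maximized over the two orientations of B; adjacency conservation is the
fraction of neighboring paired genes in A whose partners are neighbors in
B.  Both equal 1 exactly when the paired orders are identical up to
reversal; neither dominates the other in general.  Colinear blocks
(maximal ±1-step runs) are reported for display.

## Known limitations

* NJ on corrected distances is a method substitution for the per-gene
  trees; on deep or rate-heterogeneous real data it is more error-prone
  than ML, which would shift calls toward `ambiguous`.
* Donor attribution inherits the reference set's taxon sampling: an absent
  true donor lineage yields the nearest sampled relative instead.
* The transfer model is replacing and focal-directed only; reconciliation
  (DTL) approaches, composition-based signals and transfer dating are out
  of scope.
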