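# Methods

This note records the models, parameter choices and numerical conventions
behind `trucphylo`, and what the synthetic validation does and does not
demonstrate about real data.

## Presence/absence characters

The unit of analysis is a binary indicator: feature *f* (a fold
superfamily or an informational COG) is present in proteome *t* iff at
least one assignment row exists, regardless of copy number — occurrence,
not abundance. Two ingestion filters are exposed separately:

* **universal selection** keeps features detected in at least one
  archaeon, one bacterium, one eukaryote and one Megavirales member; it
  is the criterion for building a character set shared by all four groups
  from heterogeneous annotations, and feeds the 15-cell Venn
  sharing-pattern report;
* **parsimony-informative filtering** keeps characters whose both states
  are carried by ≥ 2 taxa; constants and autapomorphies cannot
  discriminate topologies under parsimony.

The two filters are deliberately independent operations (their
composition commutes), since the counts they produce answer different
questions. In the synthetic pipeline the inference stages (tree,
ordination, clustering) run on the informative set of the full simulated
matrix: simulated characters all evolve on the common truth tree, so
universality is not a precondition for usability there, whereas for real
multi-source annotation dumps it is the step that removes group-private
features before cross-group comparison.

## Parsimony machinery

**Counting.** Fitch's algorithm, vectorized over characters with 2-bit
state sets; the pass is rooted at the lowest-numbered tip, which leaves
the count invariant. Equality with an independent unit-cost Sankoff
dynamic program is asserted over a thousand random instances in the test
suite.

**Search.** Stepwise random addition followed by hill-climbing over NNI
(2(n−3) neighbors) or SPR (O(n²)) rearrangements, with a bounded number
(default 20) of sideways moves across unvisited equal-length topologies
once no neighbor improves. The sideways walk matters: random binary
matrices produce large parsimony plateaus on which pure hill-climbing
stalls, and with it the heuristic matches exhaustive enumeration on all
tested 6- and 7-taxon instances. Multiple equally parsimonious topologies
are collected (bounded, deterministic canonical order) and a strict
consensus writer is provided; supports are attached to the first best
tree by default.

**Bootstrap.** Characters are resampled as multinomial weights; each
replicate is re-searched. Replicate searches default to stepwise
addition + NNI — the usual fast-bootstrap compromise — which on the
synthetic study matrix gives supports within a point or two of full SPR
replicates at a tenth of the cost. Support of a split is the percentage
of replicate best trees containing it.

**Rooting.** Lundberg a-posteriori rooting: a hypothetical ancestor is
attached to every branch; the branch minimizing total length wins, ties
broken by the deterministic branch enumeration order and flagged. The
ancestor defaults to all-absent, which treats domain absence as the
ancestral state and reproduces a generality-criterion-style polarity;
any other ancestor vector can be supplied.

**Fit indices.** For a binary character with *a* presences and *b*
absences, the closed forms m = 1 iff both states occur (else 0) and
g = min(a, b) bound the observed steps *s*; CI = m/s (1 when s = 0),
HI = 1 − CI, RI = (g−s)/(g−m) (undefined, reported as NaN, when g = m),
RC = CI·RI, and the concave fit G = k/(k + s − m) with k configurable
(default 2; the concavity of the published plots is not recoverable from
them, so the parameter is exposed rather than guessed).

## Age-weighted ordination

Feature ages *nd* ∈ [0, 1] (0 = most ancient) weight the presence matrix
as (1 − nd) where present and 0 where absent. Absent features contribute
0 rather than missing values — Euclidean distance needs complete vectors,
and "absent" is information here, not missingness. Classical PCoA
(double-centering + symmetric eigendecomposition) embeds the distances;
axis signs are fixed by forcing the largest-magnitude loading positive,
so runs and taxon orderings are reproducible up to row order. Because the
input is Euclidean by construction, no Lingoes/Cailliez correction is
applied by default (a Lingoes correction is available for ingested
non-Euclidean matrices). Setting all ages to 0 reduces the method to
ordinary binary PCoA (tested). Group separation is reported as the mean
silhouette per group on the embedded coordinates.

## Phyletic clustering

Pearson distance d = 1 − r on raw binary profiles (profiles are centered
by the correlation itself), range [0, 2]; constant profiles are an error
naming the taxon. Agglomeration uses scipy's deterministic implementation
with average linkage by default (complete and single available); the
four-branch check cuts at four clusters and reports majority-group purity.

## Pangenome

Local alignments (BLOSUM62, gap open −11 / extend −1) are scored with
Karlin–Altschul gapped statistics (λ = 0.267, K = 0.041) to e-values over
a query-length × database-length search space. A hit passes at e ≤ 1e−3,
identity ≥ 20 % and query coverage ≥ 30 %; coverage is query-sided and an
edge requires passing hits in both directions. Families are connected
components of the reciprocal-hit graph — simpler than spectral
partitioning, exact on desk-scale data, and deterministic. Partition
classes per genome: core (families spanning all genomes), span-3,
span-2, unique; "shared with at least one other genome" is the
complement of unique. Percentages are count/genome-size to one decimal,
rounding half away from zero, so reports recompute printed tables
exactly from printed counts.

## Rhizome classification

Subject taxonomy paths are ordered superkingdom-first; by convention the
last two ranks are family and genus. Donor class is the superkingdom of
the best remaining hit (virus / eukaryota / bacteria / archaea) after
removing relatives at the exclusion rank — default `family`, which also
removes same-genus hits; `genus` and `none` are supported. Hits without
a classifiable superkingdom are skipped with a warning. Units with no
remaining hits are ORFans, so ORFan is exactly "best hit absent". Score
ties across donor classes are resolved by higher identity then
lexicographic subject id, and flagged. Fragments are 40-residue windows
every 20 residues; the trailing window is truncated at the sequence end
and dropped below 20 residues — under these defaults every residue of a
sequence ≥ 20 aa is covered and the fragment count is
⌊(L−20)/20⌋ + 1.

## Synthetic data: what it emulates, and what it does not

The generator plants the study conditions used throughout validation:

* **Character matrix** — 8 taxa per group (32 total), 200 characters,
  evolved on a fixed truth tree of four balanced group clades joined by a
  single backbone. Each character originates as a gain at one node and is
  then perturbed branch-by-branch (gain 0→1 and loss 1→0 each at 2 % per
  branch by default; ≤ 5 % keeps recovery reliable). Origins are sampled
  from a structured mixture — 45 % at the four group stems, 15 % at the
  deep backbone, the rest uniform over remaining nodes — emulating real
  phyletic profiles in which group-diagnostic and near-universal ancient
  features are both common; uniform and root-only modes are available.
  The character age is the origin depth scaled to [0, 1] plus Gaussian
  jitter (sd 0.05), clipped.
* **Genomes** — planted families (two core, two three-genome, three
  two-genome, three unique per genome by default; 120-residue proteins)
  with 30 % per-site within-family substitution, i.e. ~70 % identity,
  comfortably inside the clustering thresholds; a divergence knob lets
  tests exercise both sides of the thresholds.
* **Hit tables** — donor classes drawn per gene from the
  giant-virus-like mix (51 % virus, 11 % eukaryote, 8 % bacterium, 0.2 %
  archaeon, remainder ORFan); ORFans get no hits by default (a
  below-threshold-hit mode exists); optional top-scoring same-family
  decoys verify that self-taxon exclusion works; a chimeric gene with a
  known junction validates fragment rhizomes.

All generators are bit-reproducible for a fixed seed. What passing tests
show is that the pipeline's machinery is correct and that planted signal
of realistic strength is recovered; they do not show that real
proteome annotations satisfy the generative assumptions (independent
characters, uniform flip rates, clean clade-shaped origins, noise-free
best-hit scores), nor do they reproduce the published full-scale trees
and percentages, which depend on external proteome sets and live
databases.

## Problem sizes and numerical conventions

Validation runs use 32-taxon matrices with 200 characters, 100 bootstrap
replicates, exhaustive enumeration up to 945 topologies (7 taxa),
1,000-gene rhizome tables and 1,000 oracle instances — sizes chosen so
the full suite and the acceptance script each complete in minutes on a
single core while keeping every statistical bound comfortably testable.
Distance matrices are validated for symmetry/zero diagonal at 1e−12;
PCoA eigenvalues below −1e−9 on Euclidean input are treated as errors;
correlation distances are symmetrized and clipped at 0 against float
round-off; percentage rounding is decimal-exact (half away from zero).
Known limitations: the MP search is heuristic (no branch-and-bound
optimality certificate beyond 7-taxon cross-checks); multistate
characters, branch lengths beyond step counts, and likelihood/distance
tree methods are out of scope; the pangenome aligner is quadratic in
gene count and meant for desk-scale genome sets, with tabular hit
ingestion as the escape hatch for larger inputs.
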