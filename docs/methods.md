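# Methods

## Model and procedure

`kappaclust` classifies a gene list into soft functional modules from
nothing but a binary gene×term annotation matrix. The pipeline is the
classic agglomerative heuristic popularised by DAVID's gene functional
classification tool, reimplemented so that it runs on arbitrary
identifiers and annotation vocabularies.

**Kappa scoring.** Two genes' annotation profiles over a universe of T
terms form a 2×2 contingency table (a = co-annotated terms, b and c =
terms private to one gene, d = terms in neither). Cohen's kappa
κ = (O − E)/(1 − E) with O = (a+d)/T and
E = ((a+b)(a+c) + (c+d)(b+d))/T² measures co-annotation beyond chance.
The contingency counts are exact integers (computed from one integer Gram
matrix); only the final ratio is floating point, so results are
bit-reproducible. Profiles with 0 or T terms make E = 1 and κ undefined;
such genes are excluded during input validation with a warning, and any
degenerate profile reaching the kappa layer raises instead of silently
returning 0 — silent zeros would mask data problems.

**Term universe.** T is the number of distinct terms annotated to the
analysed gene list (recomputed over the module's members during
sub-clustering). Measuring co-occurrence within the analysed list is the
behaviour users of the web tool expect; the universe choice only shifts d,
which all genes share.

**Seeding.** Every gene g nominates the candidate {g} ∪ {h : κ(g,h) ≥ t}.
The candidate is a seed iff it has at least `initial_group_membership`
(default 4) members and *strictly more than* `membership_fraction`
(default 0.5) of its internal unordered pairs satisfy κ ≥ t. The strict
majority keeps hub genes with incoherent neighbourhoods from seeding.

**Merging.** Group pairs are scanned in a fixed order; the first pair
whose sharing fraction reaches `linkage_fraction` (default 0.5) is
replaced by its union, and the scan restarts. The agglomeration order of
this heuristic is inherently ambiguous, so determinism — identical output
for identical input — is the contract, not order-optimality. Groups
smaller than `final_group_membership` (default 4) are then dropped and
survivors are numbered by descending size (ties: lexicographically
smallest member), so "module 1" is always the largest.

**Sharing-fraction denominator.** The fraction |A∩B|/denom can be taken
over the smaller group (`min`), the larger (`max`), or the union
(`union`). The default is `union`. The decisive observation is the
low-stringency regime: real annotation data produces one giant module
holding almost all genes *together with* dozens of smaller modules whose
genes also sit inside the giant — that coexistence is what makes the
shared-gene histogram heavy at low thresholds. Under a `min` denominator
a module nested inside the giant shares 100 % of its members with it and
is always absorbed, so that regime cannot exist; under `union` the small
module survives (|S∩G|/|S∪G| ≈ |S|/|G| is tiny). Both alternatives remain
available for comparison.

**Enrichment.** Every term annotated to ≥ 1 module member (configurable
via `min_overlap`) is tested with the plain hypergeometric upper tail
P(X ≥ k) for a module of n genes, k of them carrying the term, against a
background of N genes with K term carriers. The module enrichment score
is −log10 of the geometric mean of the term p-values, computed as the
arithmetic mean of −log10 p so that tiny p-values cannot underflow the
product; score ≥ 1.3 ⇔ geometric-mean p < 0.05 defines "enriched". No
multiple-testing correction enters the score (it aggregates raw
p-values); Benjamini–Hochberg-adjusted per-term values are reported
alongside for information. The jackknifed EASE variant (test k−1) is
available behind `ease=True` for comparability with the web tool but is
not the default, since the plain hypergeometric test is the method here.
If no background is supplied the query annotation itself is the universe,
and enrichment is then only relative to the input list — supply the full
transcriptome annotation via `--background` for absolute statements.

**Sub-clustering.** A large weakly-enriched module can be re-clustered at
a strictly higher kappa threshold, over a term universe recomputed from
its members. A module whose members all share one identical profile is
returned unchanged as a single sub-module: identical annotations are
inseparable at any threshold (and, after universe reindexing, identical
profiles are formally degenerate, so the case is resolved before the
kappa layer).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kappa_threshold` | 0.35 (single run) | pair-similarity stringency; the dominant control |
| `initial_group_membership` | 4 | minimum seed size, counting the seed gene |
| `membership_fraction` | 0.5 | strict-majority internal-pair agreement for a seed |
| `linkage_fraction` | 0.5 | sharing fraction at which groups merge |
| `final_group_membership` | 4 | minimum reported module size |
| `linkage_denominator` | union | denominator of the sharing fraction |
| `sig_threshold` | 1.3 | enrichment-score cut-off (= −log10 0.05) |
| sweep grid | 0.1, 0.2, 0.3, 0.35, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9 | the conventional reporting grid; 0.35 is the web tool's suggested default |

## The synthetic-data generator

`simulate.FixtureSpec` plants partially overlapping functional groups in
an otherwise sparse annotation matrix:

* **Tight groups** own disjoint term blocks; a member carries each group
  term with probability `p_within`, optionally per group. For a group
  with annotation probability p, the typical within-group kappa is
  ≈ p/(2−p) regardless of block size, so a *spread* of p values (the
  paper-scale presets use 0.55–0.97 across groups) is what makes modules
  fragment progressively along the sweep instead of all at once.
* **Multi-function genes** (`overlap_genes`) belong to two groups and
  carry both term blocks.
* **Diffuse glue** (`DiffuseGlue`) is a block of broad, weakly-held terms
  (density ≈ 0.3) spread over a random subset of genes, modelling
  high-level ontology terms that co-annotate otherwise unrelated genes.
  The glue is what fuses the gene list into one giant module at low
  thresholds while tight groups persist as overlapping sub-modules inside
  it; it dissolves as the threshold rises. The glue vocabulary is kept
  the same size across the paper-scale presets because an ontology's
  broad layer is a property of the annotation source, not of the gene
  list.
* **Background noise**: i.i.d. per-(gene, term) annotation with
  probability `p_noise`.

`paper_scale_specs()` provides fixed-seed presets of 555, 1313 and 3340
annotated genes — the range of DEG-list sizes the method is typically
applied to — used by the sweep regression tests. The regression
assertions (percentage of genes harboured and the multi-module gene mass
non-increasing in kappa; module count rising then falling) are properties
of these packaged fixtures, not theorems about the heuristic.

What the generator does *not* model: GO DAG structure and term ancestry,
realistic term-frequency skew beyond its two annotation scales,
inter-group term correlations, or any upstream read-mapping /
differential-expression step. Passing tests on these fixtures show the
algorithmic machinery behaves as designed; they do not certify biological
conclusions on any particular real data set.

## Numerical and degenerate-input choices

* Kappa from exact integer counts; comparisons (κ ≥ t) are therefore
  stable across platforms.
* Hypergeometric p-values via `scipy.stats.hypergeom.sf`, with a
  log-survival fallback when the tail underflows to exactly 0; p is
  clamped to (0, 1].
* A query term absent from the background would make k > K; its
  background count is raised to the observed k so the table stays
  consistent (this only arises with user-supplied backgrounds that do not
  cover the query annotation).
* Genes and terms are sorted lexicographically after parsing; identifiers
  are case-sensitive opaque strings and are never translated.
* Merging scans pairs in list order and restarts after every merge;
  module numbering is descending size with lexicographic tie-break.
  Two runs on the same input produce identical reports, byte for byte.

## Known limitations and design notes

* **Chaining at lax settings is real.** With the default strict-majority
  seeding, a single gene bridging two internally complete groups of size
  a produces a bridge candidate whose qualifying-pair fraction is
  a/(2a−1) > 1/2 — the bridged groups always fuse, whatever a. This is
  the mechanism behind the giant low-kappa module users observe in
  practice. Consequently the demonstration that dual-membership genes
  land in both of their planted modules uses a slightly stricter
  membership fraction (0.6); at 0.5 the fused union is itself the
  correct, if less informative, output of the heuristic.
* In a two-group noise-free fixture whose overlap genes carry both full
  term blocks, those genes are annotated to the entire observed universe
  and are formally degenerate; overlap demonstrations therefore use ≥ 3
  groups (the packaged one uses 5, where bridge-to-group kappa is 6/11).
* The ARI recovery benchmark hardens the soft clustering by the
  largest-module rule; genes planted in two groups are excluded from that
  comparison (their single "true" label is ill-defined) and are assessed
  by the soft-membership check instead. Unclustered genes share one
  noise class with the planted background.
* Dense kappa storage is quadratic in the gene count; the tested range is
  up to ~3.5 k genes (a 3340-gene sweep over the full grid runs in a few
  minutes on one core). Lists an order of magnitude larger would need a
  thresholded sparse representation, which is out of scope here.
* No automatic "optimal kappa" selector is provided on purpose: the right
  stringency depends on the size and annotation diversity of the list,
  and the sweep report is designed to inform that judgement, not to make
  it.
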