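# kappaclust

Species-agnostic gene functional classification: Cohen's-kappa
co-occurrence scoring of gene–annotation matrices, DAVID-style fuzzy
heuristic multiple-linkage soft clustering, hypergeometric module
enrichment, and a kappa-threshold sweep engine for choosing clustering
stringency.

## Who this is for

Transcriptomics studies routinely end with a list of hundreds to thousands
of differentially expressed genes (DEGs) that needs to be organised into
functionally related modules. Web tools that do this are restricted to a
handful of model organisms, fixed identifier namespaces, and annotation
snapshots that may be outdated. `kappaclust` runs the same classification
algorithm on a plain two-column *flat matrix* — `gene_id<TAB>term_id` —
so any organism, any identifier scheme, and any annotation source (GO,
custom vocabularies, Blast2GO exports, GAF files) can be analysed locally
and reproducibly.

## The method

1. **Kappa co-occurrence.** For every gene pair, build the 2×2 contingency
   table of their binary annotation profiles over the T-term universe
   (a = terms in both, b/c = terms in one only, d = in neither) and score
   agreement beyond chance with Cohen's kappa:

       O = (a + d) / T
       E = ((a+b)(a+c) + (c+d)(b+d)) / T²
       κ = (O − E) / (1 − E)

2. **Seeding.** Each gene plus its κ ≥ t neighbours forms a candidate
   group; it qualifies as a seed if it has ≥ 4 members and a majority of
   its internal pairs also satisfy κ ≥ t.

3. **Fuzzy multiple-linkage merging.** Seeds sharing a majority of members
   are iteratively merged; surviving groups become modules. A gene may end
   up in several modules (soft clustering of multi-function genes).

4. **Enrichment.** Each term annotated to a module is tested against a
   background universe with the hypergeometric upper tail P(X ≥ k); the
   module **enrichment score** is −log10 of the geometric mean of those
   p-values, so score ≥ 1.3 ⇔ geometric-mean p < 0.05.

5. **Kappa sweep.** Because the threshold t dominates the outcome and the
   right value is data-dependent, `sweep` reruns the whole pipeline over a
   grid (default 0.1 … 0.9) and reports module counts, % genes harboured,
   enriched-module statistics, largest-module behaviour and the
   shared-gene histogram, so the stringency can be chosen with evidence.
   Large non-enriched modules can be broken up by re-clustering their
   members at a higher threshold (`subcluster`).

## Worked example

Simulate a 60-gene list with three planted 15-gene functional groups,
cluster it, and sweep the threshold:

```bash
kappaclust simulate --n-genes 60 --n-terms 60 --groups 15:12,15:12,15:12 \
    --overlap-genes 0 --p-within 1.0 --p-noise 0.0 --seed 1 --out sim
kappaclust cluster --annotations sim/annotations.tsv --kappa 0.5 --out clu
kappaclust sweep --annotations sim/annotations.tsv --kappas 0.1,0.35,0.6,0.9 --out swp
```

which prints

```
45 genes x 36 terms -> sim
3 modules, 0 unclustered -> clu
swept 4 kappa values -> swp
```

(15 of the 60 genes are background genes with no annotation at zero noise,
so they are dropped by validation and 45 genes enter the analysis). The
cluster report `clu/clusters.txt` starts

```
Module 1  size=15  kappa=0.5  enrichment_score=11.5377
g00
g01
...
```

— the three planted groups are recovered exactly, and each module's
enrichment score of 11.54 means the geometric mean of its term p-values is
10^−11.54 against the self-background. `swp/sweep.tsv` holds one row per
threshold:

```
kappa  module_count  pct_genes_harbored  enriched_module_count  pct_genes_in_enriched_modules
0.1    3             100                 3                      100
0.35   3             100                 3                      100
0.6    3             100                 3                      100
0.9    3             100                 3                      100
```

(noise-free blocks are stable at every stringency; on real data these
columns fall as kappa rises — see `docs/methods.md`). Each output
directory also contains `run_manifest.json` with parameters and input
hashes; reruns are byte-identical.

The same operations are available as a library:

```python
import kappaclust as kc

matrix = kc.read_flat_annotation("annotations.tsv")
result = kc.cluster(matrix, kc.ClusteringParams(kappa_threshold=0.35))
report = kc.run_sweep(matrix, kappas=kc.DEFAULT_SWEEP_GRID)
```

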