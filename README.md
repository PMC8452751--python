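# markerqc

Diagnostic SNP panel selection and validation for genebank quality-control
genotyping.

Given biallelic SNP genotypes for a multi-species germplasm collection,
`markerqc` reproduces the full QC-marker workflow as a tested, reusable
pipeline:

1. **genotype_io** — read/write genotype tables (two-letter calls with
   IUPAC heterozygote codes, 0/1/2 dosages, or a HapMap-like layout) into
   an allele-dosage matrix, and join per-sample taxon labels.
2. **marker_stats** — per-marker MAF, gene diversity (He), polymorphism
   information content (PIC), heterozygosity and missingness, plus the
   quality-filter cascade (defaults: remove MAF < 5%, PIC < 18%,
   het > 9%, missing > 24%).
3. **diagnostic_panel** — minor-allele concordance scoring of markers
   against taxon-group contrasts (a marker passes when >97% of every
   taxon's accessions carry the expected homozygous state), rescue of
   contrasts via jointly-diagnostic marker pairs, greedy minimal-panel
   reduction with redundancy, per-accession classification against the
   panel's expected haplotypes, and haplotype-pattern reports.
4. **popgen_validation** — from-scratch validation battery: squared
   distance matrices with pairwise-complete missing-data rescaling,
   one-level AMOVA with PhiPT and permutation p-values, pairwise PhiPT,
   PCA, neighbor-joining trees with locus-bootstrap supports (newick
   output), and DAPC-style cluster-number selection (k-means on
   principal components, BIC + silhouette).
5. **synthetic_data** — a fully seeded generator of collections with
   planted diagnostic structure (five taxa, six group contrasts,
   configurable fixation/heterozygosity/missingness, hybrid accessions)
   plus ground truth, so every stage is testable without external data.
6. **cli** — subcommands tying the stages together.

## Command line

```bash
# generate a synthetic collection (genotypes, metadata, ground truth)
markerqc simulate --seed 1 --out-dir sim/

# marker statistics and the quality filter
markerqc stats sim/genotypes.tsv --out summary.tsv
markerqc filter sim/genotypes.tsv --out filter.json

# concordance scoring and panel assembly
markerqc score sim/genotypes.tsv sim/metadata.tsv --out scores.json
markerqc select-panel sim/genotypes.tsv sim/metadata.tsv --reduce --out panel.json

# validation battery on a labeled matrix
markerqc validate sim/genotypes.tsv sim/metadata.tsv --out-dir validation/

# everything end to end, with a manifest of headline numbers
markerqc pipeline sim/genotypes.tsv sim/metadata.tsv --out-dir report/
```

`report/manifest.json` records the filter counts, panel composition,
PhiPT (overall and pairwise minimum), PCA variance fractions, the chosen
cluster number and full provenance (inputs, parameters, seed).

## Library use

```python
from markerqc import (
    CollectionConfig, labeled_collection, build_panel, minimal_panel,
    classify_all, squared_distance_matrix, amova, dapc,
)

ds, truth = labeled_collection(CollectionConfig(seed=0))
panel = build_panel(ds)                      # 6 contrasts, pair rescue
reduced = minimal_panel(panel, ds)           # greedy cover, r=2
res = amova(squared_distance_matrix(ds.genotype.subset_loci(panel.loci)),
            ds.taxa, n_perm=999, seed=0)
print(res.phipt, res.p_value)
```
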