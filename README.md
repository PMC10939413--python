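# gcnkit

Condition-independent **gene coexpression networks** (GCNs) from bulk
RNA-seq compendia, with built-in performance evaluation and subnetwork
mining. `gcnkit` is aimed at researchers working in crop or non-model
species who want to pool all public RNA-seq libraries for their organism
into a single reusable network for gene-function prediction — the setting
where genetic validation is slow and guilt-by-association is often the
best available lead generator.

## What it computes

Starting from a gene-level fragment-count matrix, gene lengths, and a
sample-to-study (bioproject) table:

1. **Normalization and filtering.** Counts are FPKM-normalized,
   `FPKM(g,s) = counts(g,s)·10⁹ / (len_bp(g)·total(s))`, and genes with
   FPKM < 0.5 in at least half of the libraries are removed (as are
   zero-variance genes, whose correlation is undefined).
2. **HRR networks (non-aggregated).** For every gene pair, partners are
   ranked by descending Pearson correlation and scored by the highest
   reciprocal rank, `HRR(x,y) = max(rank(x,y), rank(y,x))`. The network
   at sparsity *k* (100 stringent, 300 relaxed) is the undirected union of
   each gene's *k* best partners, so minimum degree equals *k* while hubs
   can greatly exceed it.
3. **COO networks (aggregated).** Libraries are grouped by bioproject
   (groups with fewer than 6 libraries are dropped, and filtering is redone
   within each group); per-group HRR networks are aggregated by counting in
   how many groups each edge occurs, and every gene keeps its *k* partners
   with the highest co-occurrence frequency. Aggregation admits genes and
   edges expressed only under specific conditions, which pooled correlation
   dilutes.
4. **Evaluation.** Neighbor-voting guilt-by-association: per annotation
   term (20–1000 member genes in the network), annotated genes are split
   into 3 folds; each gene is scored by the fraction of its neighbors
   carrying the training annotation, held-out genes are ranked, and the
   ROC area is computed by the Mann–Whitney rank-sum identity. AUROC 0.5
   is chance; 0.7 is the usual bar for a usefully predictive network.
5. **Mining.** Gene-centered subnetworks (first neighbors), neighborhood
   intersections, and hypergeometric gene-set enrichment with
   Benjamini–Hochberg control (enriched at q < 0.1) against GO-, Pfam-,
   KEGG-, PANTHER- or MapMan-style annotation collections (GMT or
   two-column TSV).

A synthetic-data module simulates multi-bioproject count data with planted
coexpression modules and matching annotations, so the entire pipeline is
exercisable — and its statistical behavior checkable — without any
download.

## Worked example

Simulate a 4-study compendium with five planted 25-gene modules, build the
aggregated network, and evaluate it:

```sh
gcnkit simulate --genes 600 --groups 4 --samples-per-group 8 \
    --modules 5 --module-size 25 --seed 7 --out inputs
gcnkit network coo --counts inputs/counts.tsv --lengths inputs/gene_lengths.tsv \
    --samples inputs/samples.tsv --k 50 --out coo50.tsv
gcnkit topology coo50.tsv --out topo.tsv
gcnkit evaluate --network coo50.tsv --annotations inputs/annotations.gmt \
    --name synthetic --seed 7 --out auroc.tsv
```

which prints

```
COO50: 600 nodes, 16221 edges -> coo50.tsv
nodes=600 degree(min/mean/max)=50/54.1/70
synthetic	mean_auroc=0.745
average	0.745
```

The minimum degree (50) is pinned by the sparsity threshold, as it should
be for a union-of-top-*k* network. The dataset mean AUROC of 0.745 averages
five planted module terms (AUROC ≈ 1.0 each — the network recovers the
planted coexpression almost perfectly) with five random decoy terms
(AUROC ≈ 0.49, i.e. chance), which `auroc.tsv` breaks out per term. The
same chain is available as a single `gcnkit run --config cfg.yaml` with
byte-reproducible outputs at a fixed seed.

The library API mirrors the CLI (`gcnkit.simulate_dataset`,
`gcnkit.hrr_network_from_fpkm`, `gcnkit.build_coo_network`,
`gcnkit.neighbor_voting_auroc`, `gcnkit.hypergeometric_enrichment`, …);
see `docs/methods.md` for the modeling details and design choices.

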