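# domainsnp

Tools for asking what a missense SNP does to the protein domain it lands
in, and what that does to the protein's interaction neighbourhood.

Hereditary disorders are often traced to single amino-acid substitutions.
Many of those substitutions fall inside *protein domains* — the recurring
sequence/structure units that mediate binding between signalling proteins.
`domainsnp` implements, as a tested pipeline on synthetic or user-supplied
data, the full chain of reasoning from sequence to network:

1. **Domain annotation** (`domain_scan`). Proteins are scanned with
   PROSITE-style signatures of two kinds: *patterns* (restricted regular
   expressions over amino acids, e.g. `[AC]-x-V-x(4)-{ED}.`) and
   *profiles* (an L x 20 position score matrix with affine gap penalties
   and a presence cutoff). A profile's best local alignment score is its
   *matching score* MS; the domain is present iff MS ≥ cutoff.
2. **Variant impact** (`variant_impact`). Each SNP is applied to its
   protein and the affected domains are re-evaluated. An SNP inside a
   matched domain is a **D-SNP**. It is a **DA-SNP** (domain-altering)
   when the mutated sequence no longer matches the pattern at any span
   covering the SNP, or when the *domain distortion*

   DD = (MS_ref − MS_alt) / MS_ref

   reaches a cutoff (default 0.10, inclusive), or when MS_alt drops below
   the profile's presence cutoff altogether. DD is clamped at 0 for
   score-improving substitutions.
3. **Disease enrichment** (`enrichment`). Exact one-tailed hypergeometric
   tests P(X ≥ k), computed in log space: enrichment of SNP classes in a
   disease-annotation set, a sweep of DA counts and p-values across DD
   cutoffs, and generic term enrichment with Benjamini–Hochberg q-values.
4. **Edgetic network impact** (`network_impact`). For each domain d that a
   SNP can alter, the pipeline counts how often d on one side of a PPI
   edge co-occurs with each signature s (domain or linear motif) on the
   partner, tests the count against a random-partner background, filters
   enriched pairs by reference domain–domain / domain–motif interaction
   lists, and calls an edge **broken** when the partner of a DA-SNP
   protein carries an admitted enriched signature for the altered domain.
   Connectivity reports give per-protein broken/intact totals.
5. **Synthetic universes** (`synthetic_data`). A seeded generator plants
   domain instances, stratified SNPs with known intended classes, disease
   labels with a controllable odds ratio for DA-SNPs, and a PPI network
   wired by planted (domain, signature) binding rules — ground truth for
   every downstream stage.

## Worked example

```
domainsnp simulate --seed 1 --out universe/
domainsnp run --config config.yaml --seed 1 --out run/
```

where `config.yaml` points at the files written into `universe/`. The run
prints (and writes to `run/summary.json`):

```
{
 "n_broken_edge_calls": 30,
 "n_d_snp": 120,
 "n_da_snp": 6,
 "n_enriched_pairs": 32,
 "n_snps": 600,
 "seed": 1,
 "sweep": [
  {"dd_cutoff": 0.05, "n_da_snp": 6, "n_da_snp_diseased": 1, "p_value": 0.41363...},
  {"dd_cutoff": 0.1,  "n_da_snp": 6, "n_da_snp_diseased": 1, "p_value": 0.41363...},
  {"dd_cutoff": 0.15, "n_da_snp": 6, "n_da_snp_diseased": 1, "p_value": 0.41363...},
  {"dd_cutoff": 0.2,  "n_da_snp": 5, "n_da_snp_diseased": 0, "p_value": 1.0}
 ]
}
```

Reading: of 600 simulated missense SNPs, 120 fall inside matched domains
(D-SNPs) and 6 distort a domain past DD ≥ 0.10 (DA-SNPs); the DA count is
monotone non-increasing as the cutoff rises. One of the 6 DA-SNPs carries
a disease label, which at these sample sizes is not significant (p = 0.41)
— the default universe plants only a weak disease association. In the
network stage 32 signature pairs are enriched across the PPI edges and 30
edge–domain combinations are called broken. Stage tables (`matches.tsv`,
`calls.tsv`, `sweep.tsv`, `pairs_scored.tsv`, `broken.tsv`,
`connectivity.tsv`, `histogram.tsv`) land next to the summary.

All stages are also importable directly:

```python
from domainsnp import GeneratorConfig, generate_universe, classify_all, dd_sweep
u = generate_universe(GeneratorConfig(seed=1))
```

## Input formats

FASTA proteome; tab-separated tables with a header row (`snps.tsv`,
`edges.tsv`, `disease.tsv`, `pairs.tsv`, `motifs.tsv`); and a line-oriented
`domains.txt` holding pattern (`PA=`) and profile (`MA=` matrix with
`GAP_OPEN`/`GAP_EXT`/`CUTOFF`) definitions. All coordinates are 1-based
with inclusive spans. See `docs/methods.md` for the model details and
design choices.
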