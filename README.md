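# enhancerkit

Enhancers transcribe short, unstable eRNAs, so nascent-transcription assays
(GRO-seq and relatives) can locate active enhancers directly: any actively
transcribed region that is not explained by a gene is a putative enhancer.
`enhancerkit` implements an enhancer-centric analysis pipeline built on that
idea, for computational biologists working with interval calls from run-on
sequencing plus cohort multi-omics (expression, chromatin accessibility,
DNA methylation, eRNA expression):

1. **Enhancer calling** — per-cell-line transcript interval calls are
   filtered by an RPKM cutoff (mean ≥ 1 for replicated cell lines, ≥ 2
   otherwise), stripped of calls within 5 kb of gene 5′/3′ termini or
   overlapping gene bodies, merged across cell lines with a 500 bp gap
   tolerance, and classified *specific* (active in one cell line),
   *common* (active in all) or *intermediate*.
2. **Enhancer–gene (EG) pairing** — candidate pairs are all (enhancer,
   gene) combinations within 500 kb (optionally extended by an external
   pair list). Each pair is scored per cancer type by the Pearson
   correlation *r* between enhancer activity and gene expression, using
   three activity modalities (ATAC signal, methylation β — expected
   negative, eRNA expression). Benjamini–Hochberg FDR is applied within
   each (cancer type × modality) family; a pair is **functional** when
   q < 0.05 and |r| ≥ 0.3.
3. **Enhancer effect score (EES)** — for a gene set *G* and sample *s*:

   EES_s = (−log₂ p_enrich) · Σᵢ RPKMᵢ(s)·|Cor_max|ᵢ / Σᵢ RPKMᵢ(s)

   where p_enrich is the hypergeometric upper-tail enrichment of enhancer
   target genes in *G*, and |Cor_max|ᵢ is the largest absolute correlation
   among gene *i*'s functional pairs. The EES is then correlated against
   per-sample immune-infiltration scores (significance at raw p < 0.05).
4. **Modulator search** — for a chosen EG pair, every gene is tested as a
   conditional modulator: samples are split into bottom/top expression
   quartiles of the candidate, the pair correlation is recomputed within
   each group, and Diffcor = |r_high − r_low| ≥ 0.5 flags candidates.

A synthetic-data module generates every input with planted truth (enhancer
classes, pair correlations via a shared latent factor, expression-gated
correlations, infiltration coupled to an immune gene set), so the full
pipeline is testable end-to-end without external downloads.

## Worked example

```python
import enhancerkit as ek
from enhancerkit import workflow

cfg = ek.demo_config(seed=11, n_cancer_types=3, samples_per_type=150, n_pairs=12,
                     n_genes=300, immune=True, infiltration_coupling=0.8)
sim = ek.simulate.simulate_all(cfg)          # calls, cohort, truth
run = workflow.run_pairing(sim)              # catalog -> candidates -> EG screen

print(len(run.catalog.regions))              # 42 putative enhancers
rec = workflow.pair_recovery(sim, run)
profile, report = workflow.immune_ees(sim, run, "CT1")
```

Output for this seed:

```
catalog: 42 putative enhancers {specific: 21, common: 11, intermediate: 10}
planted pair recovery: 87/96 (90.6%), realized FDR 1.14%
IMMUNE_EVASION enrichment p = 4.21e-19; median EES = 40.192
top infiltration correlate: NK (r = 0.568, p = 3.57e-14)
```

The 42 catalog entries are the 32 planted enhancers plus the planted
"singleton" noise calls, which legitimately survive filtering as
cell-line-specific entries. Recovery below 100% reflects the deliberately
weak (|r| = 0.35) immune pairs sitting near the 0.3 magnitude gate; the
realized false-discovery proportion stays near the BH target. The immune
gene set is strongly enriched among enhancer targets, so the EES is large,
and the infiltration columns coupled to the immune program (here NK) come
out as its top correlates.

The same stages are exposed on the command line (`enhancerkit simulate`,
`call-enhancers`, `pair`, `ees`, `modulators`); see `enhancerkit --help`.

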