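# ttrnet

Coding/non-coding regulatory network inference for three-arm glucose /
transthyretin (TTR) transcriptome designs.

## The problem

Diabetic retinopathy is driven by glucose-induced dysfunction of retinal
endothelial cells, and TTR — a thyroxine/retinol transport protein that is
depleted in patients — represses the resulting neovascularization. Given
transcript-level FPKM from cells cultured under low glucose (LG), high
glucose (HG) and high glucose plus TTR (HG+TTR), three replicates each,
the analysis asks: which transcripts does glucose deregulate and TTR push
back, and through which lncRNA–mRNA regulatory wiring?

`ttrnet` implements that inference chain as a tested library with thin
analysis drivers:

1. **Differential expression** — per-transcript Student's *t* with
   fold-change filtering; a transcript is deregulated when
   FC ≥ 2 (or ≤ 0.5), *P* ≤ 0.05 and Benjamini–Hochberg FDR ≤ 0.05, with
   BH applied jointly across all transcripts of a contrast. Transcript
   calls aggregate to genes.
2. **Converse-trend (TTR-DEG) filter** — a transcript whose log2 fold
   changes in (HG vs LG) and (HG+TTR vs HG) satisfy
   sign(log2FC₁)·sign(log2FC₂) < 0, significant in both contrasts
   (strict mode), is a TTR-related DEG: glucose moves it, TTR moves it
   back.
3. **Co-expression modules** — soft-threshold power β chosen by
   scale-free fit of the |cor|^β network (fallback β = 10), topological
   overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
   average-linkage tree cut, module eigengenes (first PC of the
   standardised member submatrix), and Pearson module–trait correlation
   against binary glucose/TTR traits; the hub module maximises
   min(|r_glucose|, |r_TTR|).
4. **lncRNA target networks** — *cis*: coding genes within 10 kb
   (boundary inclusive) up/downstream of, or overlapping, a lncRNA;
   *trans*: pairs with |Pearson r| ≥ 0.95 on log2(FPKM+1); *ceRNA*:
   lncRNA–miRNA–mRNA triads sharing canonical seed sites (6mer core,
   7mer-A1, 7mer-m8, 8mer). Hub lncRNAs rank by trans-network degree.
5. **Dense sub-networks** — MCODE-style k-core vertex weighting and
   seed-and-grow complex detection (score = density × size) on a scored
   interaction edge list filtered at score > 0.4.
6. **Synthetic data** — a generator that plants DE transcripts,
   trend reversals, trait-linked modules, cis neighbours and seed-site
   triads with full ground truth, so every stage is testable offline.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_coexpression_modules.py
python analysis/04_lncrna_networks.py
python analysis/05_dense_subnetworks.py --seed 1
```

Step 02 prints (seed 1):

```
hg_vs_lg: 45 up, 39 down of 450 transcripts
ttr_vs_hg: 76 up, 40 down of 450 transcripts
TTR-DEGs (strict): 30 (28 mRNA, 2 lncRNA)
  recovery of planted reversals: sensitivity 1.000, precision 1.000
worked examples:
  tube area HG/LG       = 1.48
  tube area HG+TTR/HG   = 0.73
  2^-ddCt for ddCt=-4   = 16.0
```

The 30 strict TTR-DEGs are exactly the 30 planted trend reversals. The
two ratios are the tube-formation worked example recomputed from the
printed group-mean areas (13,843.2 / 9,347.6 and 10,121.2 / 13,843.2):
high glucose enlarges tube area 1.48-fold and TTR co-treatment shrinks it
to 0.73 of the HG level. Step 03 then reports the soft threshold
(β = 10 by fallback on this 9-sample design), module sizes and
module–trait correlations with the hub module; step 04 recovers all 8
planted cis pairs and all 5 planted ceRNA triads and ranks hub lncRNAs by
trans degree; step 05 finds the three planted cliques (sizes 6, 5, 4) as
complexes with density 1.

Outputs land under `results/` as tab-separated tables plus SIF/GraphML
network exports. `ttrnet.pipeline.run_pipeline(PipelineConfig(...))` runs
the same chain in one call and writes a manifest with a config hash and
per-file SHA-256 digests; identical configs give byte-identical outputs.

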